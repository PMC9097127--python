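"""Synthetic FASTA generation, brute-force oracles and the scaling harness.

Two generation regimes are provided.  ``uniform_random`` draws every
base i.i.d. from {A,C,G,T}; it emulates the benchmark file sets used to
measure scaling (files of hundreds of sequences totalling tens of
thousands to millions of bases).  Because 20-mers essentially never
repeat between independent random sequences, random files exercise the
scaling path but not cluster formation, so ``family`` mode draws a few
ancestor sequences and emits mutated copies of each (i.i.d.
substitutions at a fixed per-base rate), producing the shared motifs —
and hence multi-sequence clusters — that real heterogeneous target
sets contain.

The oracles are deliberately naive re-computations used only in tests:
a direct substring multimap for candidate enumeration, greedy and
exhaustive minimum set cover for approximation quality.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fasta_io import SequenceRecord, write_fasta
from .pipeline import Config, run_pipeline

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic FASTA file; same spec + seed => same file."""

    n_sequences: int
    bases_per_sequence: int
    mode: str = "uniform_random"  # or "family"
    n_ancestors: int = 1
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.bases_per_sequence < 1:
            raise ValueError("n_sequences and bases_per_sequence must be >= 1")
        if self.mode not in ("uniform_random", "family"):
            raise ValueError(f"unknown mode: {self.mode}")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must lie in [0, 1]")
        if self.mode == "family" and self.n_ancestors < 1:
            raise ValueError("family mode needs n_ancestors >= 1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hits):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def make_records(spec: FixtureSpec) -> list[SequenceRecord]:
    """Generate the records of a fixture in memory, ids 1..n."""
    rng = np.random.default_rng(spec.seed)
    seqs: list[str] = []
    if spec.mode == "uniform_random":
        seqs = [_random_seq(rng, spec.bases_per_sequence)
                for _ in range(spec.n_sequences)]
    else:
        ancestors = [_random_seq(rng, spec.bases_per_sequence)
                     for _ in range(spec.n_ancestors)]
        for i in range(spec.n_sequences):
            seqs.append(_mutate(rng, ancestors[i % spec.n_ancestors],
                                spec.substitution_rate))
    return [
        SequenceRecord(i + 1, f"synthetic_{spec.mode}_{i + 1}", s)
        for i, s in enumerate(seqs)
    ]


def synthesize_fasta(spec: FixtureSpec, out: str | Path) -> Path:
    """Write a synthetic FASTA file; reproducible from the spec's seed."""
    out = Path(out)
    write_fasta(make_records(spec), out)
    return out


def naive_candidate_multimap(
    records: Sequence[SequenceRecord], k: int
) -> dict[str, frozenset[int]]:
    """Direct substring extraction, no indexing tricks; test oracle only."""
    acc: dict[str, set[int]] = {}
    for rec in records:
        for i in range(len(rec.sequence) - k + 1):
            sub = rec.sequence[i : i + k]
            if set(sub) <= set("ACGT"):
                acc.setdefault(sub, set()).add(rec.seq_id)
    return {kmer: frozenset(v) for kmer, v in acc.items()}


def greedy_cover_size(
    universe: frozenset[int], families: Iterable[frozenset[int]]
) -> int:
    """Classic greedy set cover (largest marginal gain first); oracle only."""
    fams = list(families)
    covered: set[int] = set()
    picked = 0
    target = frozenset().union(*fams) & universe if fams else frozenset()
    while covered < target:
        best = max(fams, key=lambda f: len(f - covered))
        if not best - covered:
            break
        covered |= best
        picked += 1
    return picked


def exact_min_cover(
    universe: frozenset[int], families: Sequence[frozenset[int]]
) -> int:
    """Minimum number of families whose union is the coverable universe.

    Exhaustive search by increasing subset cardinality over the distinct
    family sets; intended for instances of at most ~20 distinct
    families (tiny test fixtures).
    """
    if not families:
        if universe:
            raise ValueError("cannot cover a non-empty universe with no families")
        return 0
    distinct = sorted(set(families), key=lambda f: (-len(f), sorted(f)))
    coverable = frozenset().union(*distinct)
    target = coverable & universe if universe else coverable
    if not target:
        return 0
    for size in range(1, len(distinct) + 1):
        for combo in itertools.combinations(distinct, size):
            u: set[int] = set()
            for f in combo:
                u |= f
            if target <= u:
                return size
    raise AssertionError("unreachable: all families together cover the target")


def scaling_harness(
    base_spec: FixtureSpec,
    multipliers: Sequence[int],
    config: Config | None = None,
    workdir: str | Path | None = None,
    repeats: int = 1,
) -> pd.DataFrame:
    """Run the full pipeline at scaled input sizes; report work and time.

    Each multiplier m scales bases_per_sequence by m (sequence count
    fixed), runs the pipeline, and records total bases, the exact
    window count Σ(L-k+1) — the deterministic witness that enumeration
    work is linear in input bases — and wall time (informational;
    hardware-bound).  With ``repeats`` > 1 each size is run that many
    times and the minimum wall time is reported, the usual way to damp
    scheduler and allocator noise in timing benchmarks.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if list(multipliers) != sorted(multipliers):
        raise ValueError("multipliers must be sorted ascending")
    config = config or Config(min_sequence_group_size=1)
    k = config.primer_length
    import tempfile

    rows = []
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir is not None else Path(tmp)
        base.mkdir(parents=True, exist_ok=True)
        # warm-up run so the first measured size does not pay one-time
        # import/allocator costs
        warm_spec = FixtureSpec(
            n_sequences=min(base_spec.n_sequences, 50),
            bases_per_sequence=base_spec.bases_per_sequence,
            seed=base_spec.seed,
        )
        warm = base / "warmup.fasta"
        write_fasta(make_records(warm_spec), warm)
        run_pipeline(warm, config, write=False)
        for m in multipliers:
            spec = FixtureSpec(
                n_sequences=base_spec.n_sequences,
                bases_per_sequence=base_spec.bases_per_sequence * m,
                mode=base_spec.mode,
                n_ancestors=base_spec.n_ancestors,
                substitution_rate=base_spec.substitution_rate,
                seed=base_spec.seed + m,
            )
            records = make_records(spec)
            fasta = base / f"scale_x{m}.fasta"
            write_fasta(records, fasta)
            total_bases = sum(len(r) for r in records)
            windows = sum(max(0, len(r) - k + 1) for r in records)
            elapsed = float("inf")
            for _ in range(repeats):
                t0 = time.perf_counter()
                run_pipeline(fasta, config, write=False)
                elapsed = min(elapsed, time.perf_counter() - t0)
            rows.append(
                {"multiplier": m, "total_bases": total_bases,
                 "window_count": windows, "wall_time": elapsed}
            )
    return pd.DataFrame(rows)
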
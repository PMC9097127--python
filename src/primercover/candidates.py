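"""Sliding-window primer-candidate enumeration and the optional GC filters.

Every k-length window of every input sequence is a primer candidate,
provided it contains only unambiguous bases (A/C/G/T).  Candidates are
indexed by their k-mer; the value is the candidate's *coverage*: the
set of sequence ids containing that k-mer anywhere.  Two optional,
independent filters then drop candidates by overall GC fraction and by
the GC-fraction difference between the two halves of the k-mer (the
latter aimed at adjacent-probe designs where the k-mer is treated as
one oligonucleotide but later split in two).

For k <= 31 the index is held in packed form — each window encoded as
a 64-bit integer (2 bits per base), grouped with one sort — so the
per-window cost stays flat as inputs grow to millions of bases; the
string mapping is materialised lazily only when a caller asks for it.
Longer k falls back to direct dictionary accumulation over string
windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fasta_io import SequenceRecord

_ACGT = frozenset("ACGT")

# base -> 2-bit code; 255 marks anything outside A/C/G/T
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_PACKABLE_K = 31  # 2k bits must fit a uint64


class ParameterError(ValueError):
    """Raised for invalid enumeration or filter parameters."""


@dataclass(frozen=True)
class GCFilterConfig:
    """Optional GC screens; unset bounds impose no constraint.

    gc_min/gc_max bound the overall GC fraction of a candidate;
    max_half_diff bounds |GC(first half) - GC(second half)|, with the
    first half taking ceil(k/2) bases for odd k.
    """

    gc_min: float | None = None
    gc_max: float | None = None
    max_half_diff: float | None = None

    def __post_init__(self) -> None:
        for name in ("gc_min", "gc_max", "max_half_diff"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if (
            self.gc_min is not None
            and self.gc_max is not None
            and self.gc_min > self.gc_max
        ):
            raise ParameterError("gc_min must not exceed gc_max")

    @property
    def is_noop(self) -> bool:
        return self.gc_min is None and self.gc_max is None and self.max_half_diff is None


@dataclass
class PackedIndex:
    """Array form of the candidate index.

    ``codes`` holds the distinct packed k-mers in ascending order;
    k-mer i covers the sequence ids ``sids[starts[i]:ends[i]]`` (sorted,
    duplicate-free).  2-bit packing is order-preserving (A<C<G<T), so
    ascending codes mean lexicographically ascending k-mers.
    """

    codes: np.ndarray  # uint64, distinct, sorted
    starts: np.ndarray  # int64, per-code slice into sids
    ends: np.ndarray
    sids: np.ndarray  # int64
    k: int


class CandidateIndex:
    """Mapping k-mer -> coverage set, plus bookkeeping.

    ``universe`` is the set of sequence ids contributing at least one
    surviving candidate; it always equals the union of the coverage
    sets.  Holds either the packed array form, a plain dict, or both;
    ``entries`` materialises the dict from the arrays on first access.
    """

    def __init__(
        self,
        entries: dict[str, frozenset[int]] | None = None,
        k: int = 0,
        n_sequences: int = 0,
        universe: frozenset[int] | None = None,
        packed: PackedIndex | None = None,
    ) -> None:
        if entries is None and packed is None:
            raise ValueError("need entries or packed arrays")
        self._entries = entries
        self.packed = packed
        self.k = k
        self.n_sequences = n_sequences
        if universe is None:
            if packed is not None:
                universe = frozenset(np.unique(packed.sids).tolist())
            else:
                u: set[int] = set()
                for cov in entries.values():
                    u |= cov
                universe = frozenset(u)
        self.universe = universe

    @property
    def entries(self) -> dict[str, frozenset[int]]:
        if self._entries is None:
            p = self.packed
            kmers = _decode_codes(p.codes, p.k)
            sids = p.sids.tolist()
            self._entries = {
                kmer: frozenset(sids[s:e])
                for kmer, s, e in zip(
                    kmers, p.starts.tolist(), p.ends.tolist()
                )
            }
        return self._entries

    def __len__(self) -> int:
        if self.packed is not None:
            return int(self.packed.codes.size)
        return len(self._entries)


def _window_codes(seq: str, k: int) -> np.ndarray:
    """2-bit packed codes of every unambiguous k-window of one sequence.

    Horner evaluation over k shifted views keeps the work at O(n*k)
    vectorised element operations; windows touching an ambiguous base
    are masked out afterwards via a cumulative bad-position count.
    """
    a = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    m = a.size - k + 1
    codes = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | a[j : j + m].astype(np.uint64)
    bad = a == 255
    if bad.any():
        c = np.concatenate(([0], np.cumsum(bad)))
        codes = codes[(c[k:] - c[:-k]) == 0]
    return codes


def _decode_codes(codes: np.ndarray, k: int) -> list[str]:
    mat = np.empty((codes.size, k), dtype=np.uint8)
    for j in range(k):
        shift = np.uint64(2 * (k - 1 - j))
        mat[:, j] = (codes >> shift).astype(np.uint8) & np.uint8(3)
    chars = np.frombuffer(b"ACGT", dtype=np.uint8)[mat]
    return chars.view(f"S{k}").ravel().astype(f"U{k}").tolist()


def _enumerate_packed(
    records: Sequence[SequenceRecord], k: int
) -> PackedIndex | None:
    code_chunks: list[np.ndarray] = []
    sid_chunks: list[np.ndarray] = []
    for rec in records:
        if len(rec.sequence) < k:
            continue
        codes = _window_codes(rec.sequence, k)
        if codes.size:
            code_chunks.append(codes)
            sid_chunks.append(np.full(codes.size, rec.seq_id, dtype=np.int64))
    if not code_chunks:
        return None
    all_codes = np.concatenate(code_chunks)
    all_sids = np.concatenate(sid_chunks)
    # sort by (code, sid) and drop duplicate pairs (a k-mer repeated
    # within one sequence counts once)
    order = np.lexsort((all_sids, all_codes))
    sc = all_codes[order]
    ss = all_sids[order]
    keep = np.empty(sc.size, dtype=bool)
    keep[0] = True
    keep[1:] = (sc[1:] != sc[:-1]) | (ss[1:] != ss[:-1])
    sc = sc[keep]
    ss = ss[keep]
    is_new = np.empty(sc.size, dtype=bool)
    is_new[0] = True
    is_new[1:] = sc[1:] != sc[:-1]
    starts = np.flatnonzero(is_new)
    ends = np.append(starts[1:], sc.size)
    return PackedIndex(codes=sc[starts], starts=starts, ends=ends, sids=ss, k=k)


def _enumerate_bigk(
    records: Sequence[SequenceRecord], k: int
) -> tuple[dict[str, frozenset[int]], frozenset[int]]:
    entries: dict[str, int | set[int]] = {}
    universe: set[int] = set()
    for rec in records:
        seq = rec.sequence
        if len(seq) < k:
            continue
        sid = rec.seq_id
        get = entries.get
        # last_bad tracks the most recent ambiguous position; a window
        # starting at i is clean iff last_bad < i.
        last_bad = -1
        for j, base in enumerate(seq):
            if base not in _ACGT:
                last_bad = j
            i = j - k + 1
            if i >= 0 and last_bad < i:
                w = seq[i : j + 1]
                universe.add(sid)
                cur = get(w)
                if cur is None:
                    entries[w] = sid
                elif type(cur) is int:
                    if cur != sid:
                        entries[w] = {cur, sid}
                else:
                    cur.add(sid)
    frozen = {
        kmer: frozenset((cov,)) if type(cov) is int else frozenset(cov)
        for kmer, cov in entries.items()
    }
    return frozen, frozenset(universe)


def enumerate_candidates(
    records: Sequence[SequenceRecord], k: int
) -> CandidateIndex:
    """Index every unambiguous k-length window of every record by coverage.

    Windows containing any non-A/C/G/T letter (including N) are skipped,
    not expanded into degenerate matches.  Records shorter than k
    contribute nothing; they surface downstream as excluded sequences.
    """
    if k < 2:
        raise ParameterError(f"primer length must be >= 2, got {k}")
    if not records:
        raise ParameterError("no input records")
    if all(len(r.sequence) < k for r in records):
        raise ParameterError(
            f"no candidates producible: primer length {k} exceeds every sequence"
        )
    if k <= _PACKABLE_K:
        packed = _enumerate_packed(records, k)
        if packed is None:
            return CandidateIndex(
                entries={}, k=k, n_sequences=len(records), universe=frozenset()
            )
        return CandidateIndex(packed=packed, k=k, n_sequences=len(records))
    entries, universe = _enumerate_bigk(records, k)
    return CandidateIndex(
        entries=entries, k=k, n_sequences=len(records), universe=universe
    )


def gc_fraction(s: str) -> float:
    """(G + C count) / length of an A/C/G/T string."""
    if not s:
        raise ParameterError("gc_fraction of an empty string is undefined")
    return (s.count("G") + s.count("C")) / len(s)


def gc_half_difference(s: str) -> float:
    """|GC(first half) - GC(second half)|; first half = ceil(len/2) bases."""
    if len(s) < 2:
        raise ParameterError("gc_half_difference needs length >= 2")
    mid = (len(s) + 1) // 2
    return abs(gc_fraction(s[:mid]) - gc_fraction(s[mid:]))


def _passes(kmer: str, cfg: GCFilterConfig) -> bool:
    if cfg.gc_min is not None or cfg.gc_max is not None:
        gc = gc_fraction(kmer)
        if cfg.gc_min is not None and gc < cfg.gc_min:
            return False
        if cfg.gc_max is not None and gc > cfg.gc_max:
            return False
    if cfg.max_half_diff is not None:
        if gc_half_difference(kmer) > cfg.max_half_diff:
            return False
    return True


def _gc_count_packed(codes: np.ndarray, k: int, lo: int, hi: int) -> np.ndarray:
    """Per-code count of G/C bases at positions [lo, hi) of the k-mer."""
    total = np.zeros(codes.size, dtype=np.int64)
    for j in range(lo, hi):
        field = (codes >> np.uint64(2 * (k - 1 - j))) & np.uint64(3)
        total += (field == 1) | (field == 2)  # C == 1, G == 2
    return total


def _packed_keep_mask(p: PackedIndex, cfg: GCFilterConfig) -> np.ndarray:
    k = p.k
    keep = np.ones(p.codes.size, dtype=bool)
    if cfg.gc_min is not None or cfg.gc_max is not None:
        gc = _gc_count_packed(p.codes, k, 0, k) / k
        if cfg.gc_min is not None:
            keep &= gc >= cfg.gc_min
        if cfg.gc_max is not None:
            keep &= gc <= cfg.gc_max
    if cfg.max_half_diff is not None:
        mid = (k + 1) // 2
        first = _gc_count_packed(p.codes, k, 0, mid) / mid
        second = _gc_count_packed(p.codes, k, mid, k) / (k - mid)
        keep &= np.abs(first - second) <= cfg.max_half_diff
    return keep


def apply_gc_filters(index: CandidateIndex, cfg: GCFilterConfig) -> CandidateIndex:
    """Drop candidates failing either GC screen; recompute the universe.

    Filtering everything out is legal; downstream then reports every
    sequence as excluded.  Both screens are computed directly on the
    packed codes when the index carries them.
    """
    if cfg.is_noop:
        return index
    if index.packed is not None:
        p = index.packed
        keep = _packed_keep_mask(p, cfg)
        counts = (p.ends - p.starts)[keep]
        pair_keep = np.repeat(keep, p.ends - p.starts)
        sids = p.sids[pair_keep]
        ends = np.cumsum(counts)
        starts = ends - counts
        packed = PackedIndex(
            codes=p.codes[keep], starts=starts, ends=ends, sids=sids, k=p.k
        )
        return CandidateIndex(
            packed=packed, k=index.k, n_sequences=index.n_sequences
        )
    surviving = {
        kmer: cov for kmer, cov in index.entries.items() if _passes(kmer, cfg)
    }
    return CandidateIndex(
        entries=surviving, k=index.k, n_sequences=index.n_sequences
    )


def window_count(records: Sequence[SequenceRecord], k: int) -> int:
    """Total windows considered: sum over records of max(0, L - k + 1).

    This closed form is the deterministic witness that enumeration work
    grows linearly with the number of input bases.
    """
    return sum(max(0, len(r) - k + 1) for r in records)
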
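"""End-to-end pipeline: FASTA in, ranked near-optimal primer cover out.

Stages: read -> enumerate k-mer candidates -> optional GC filters ->
cluster by identical coverage -> size cut-offs -> rank + cumulative
coverage -> collapse same-cumulative clusters -> assemble result ->
write files.  The pipeline is fully deterministic: identical input and
configuration produce byte-identical output files.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import candidates as _cand
from . import clusters as _clust
from .fasta_io import read_fasta
from .results import DesignResult, build_result, write_result

log = logging.getLogger("primercover")


@dataclass
class Config:
    """All user-facing parameters, with their defaults.

    primer_length is the sliding-window size k in nucleotides (20 nt is
    the conventional primer length; halve into two 10-mers for adjacent
    probes).  decimals controls the rounding of cumulative coverage and
    thereby how aggressively near-redundant clusters are collapsed:
    coarser rounding merges more clusters.
    """

    primer_length: int = 20
    min_primer_group_size: int = 1
    min_sequence_group_size: int = 2
    decimals: int = 4
    gc_min: float | None = None
    gc_max: float | None = None
    max_gc_half_diff: float | None = None
    output_dir: str | None = None
    seed: int | None = None  # used only by the fixture generators

    def __post_init__(self) -> None:
        if self.primer_length < 2:
            raise ValueError("primer_length must be >= 2")
        if self.min_primer_group_size < 1 or self.min_sequence_group_size < 1:
            raise ValueError("group size cut-offs must be >= 1")
        if self.decimals < 1:
            raise ValueError("decimals must be >= 1")
        # delegate range/order checks
        self.gc_filter_config()

    def gc_filter_config(self) -> _cand.GCFilterConfig:
        return _cand.GCFilterConfig(
            gc_min=self.gc_min, gc_max=self.gc_max, max_half_diff=self.max_gc_half_diff
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**raw)


def run_pipeline(
    fasta: str | Path, config: Config | None = None, *, write: bool = True
) -> DesignResult:
    """Run every stage on one FASTA file.

    Writes the output files to ``config.output_dir`` when ``write`` is
    true and a directory is configured; always returns the in-memory
    result bundle.  Stage counts and timings are logged at INFO level.
    """
    config = config or Config()
    t0 = time.perf_counter()
    records = read_fasta(fasta)
    log.info("read %d records (%d bases)", len(records),
             sum(len(r) for r in records))

    index = _cand.enumerate_candidates(records, config.primer_length)
    enumerated_universe = index.universe
    log.info("enumerated %d distinct candidates over %d windows",
             len(index), _cand.window_count(records, config.primer_length))

    index = _cand.apply_gc_filters(index, config.gc_filter_config())
    post_gc_universe = index.universe
    log.info("%d candidates survive GC filters", len(index))

    clusters = _clust.build_clusters(index)
    clusters = _clust.filter_clusters(
        clusters,
        min_primer_group_size=config.min_primer_group_size,
        min_sequence_group_size=config.min_sequence_group_size,
    )
    post_cutoff_universe = frozenset().union(
        *(c.sequence_group for c in clusters)
    ) if clusters else frozenset()
    log.info("%d clusters survive size cut-offs", len(clusters))

    ranked = _clust.rank_and_cumulate(
        clusters, n_sequences=len(records), decimals=config.decimals
    )
    ranked = _clust.deduplicate_by_cumulative(ranked)
    log.info("%d clusters retained after cumulative-coverage reduction",
             len(ranked))

    result = build_result(
        records,
        ranked,
        config,
        enumerated_universe=enumerated_universe,
        post_gc_universe=post_gc_universe,
        post_cutoff_universe=post_cutoff_universe,
    )
    log.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    if write and config.output_dir is not None:
        write_result(result, config.output_dir)
        log.info("outputs written to %s", config.output_dir)
    return result
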
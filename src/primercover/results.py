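"""The five-element result bundle, coverage matrix, accessors and heatmap.

The bundle mirrors the tool's tabular contract: a free-text description,
the id/header/sequence conversion table, the ranked primer-cluster
table, the excluded-sequence table (with a diagnostic ``reason`` column
as an extension; a strict serialisation mode omits it) and the boolean
primer matrix whose rows are clusters in rank order and whose columns
are all sequence ids — an all-false column marks an excluded sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import ListedColormap

from .clusters import RankedClusterList, cluster_table
from .fasta_io import SequenceRecord, conversion_table

#: exclusion reasons, in diagnosis precedence order
REASON_TOO_SHORT = "too_short"
REASON_GC = "filtered_gc"
REASON_CUTOFFS = "filtered_cluster_cutoffs"
REASON_NO_SURVIVOR = "no_shared_candidate_surviving"


class EmptyMatrixError(ValueError):
    """Raised when asked to plot a coverage matrix with no clusters."""


@dataclass
class DesignResult:
    """Five-element output bundle; every element accessible by name."""

    description: str
    conversion_table: pd.DataFrame
    primer_candidates: pd.DataFrame
    excluded_sequences: pd.DataFrame
    primer_matrix: pd.DataFrame

    def __getitem__(self, key: str) -> object:
        return getattr(self, key)


def coverage_matrix(ranked: RankedClusterList) -> pd.DataFrame:
    """Boolean cluster x sequence incidence table.

    Rows: cluster ids in rank order.  Columns: every sequence id 1..n
    ascending, so excluded sequences appear as all-false columns.
    """
    cols = list(range(1, ranked.n_sequences + 1))
    data = np.zeros((len(ranked.clusters), ranked.n_sequences), dtype=bool)
    for i, c in enumerate(ranked.clusters):
        for s in c.sequence_group:
            data[i, s - 1] = True
    return pd.DataFrame(
        data, index=[c.cluster_id for c in ranked.clusters], columns=cols
    )


def _exclusion_reason(
    rec: SequenceRecord,
    k: int,
    enumerated: frozenset[int],
    post_gc: frozenset[int],
    post_cutoffs: frozenset[int],
) -> str:
    if len(rec) < k:
        return REASON_TOO_SHORT
    if rec.seq_id not in enumerated:
        # length >= k but every window held an ambiguous base
        return REASON_NO_SURVIVOR
    if rec.seq_id not in post_gc:
        return REASON_GC
    if rec.seq_id not in post_cutoffs:
        return REASON_CUTOFFS
    return REASON_NO_SURVIVOR


def build_result(
    records: Sequence[SequenceRecord],
    ranked: RankedClusterList,
    config,
    *,
    enumerated_universe: frozenset[int],
    post_gc_universe: frozenset[int],
    post_cutoff_universe: frozenset[int],
) -> DesignResult:
    """Assemble the bundle; classify every uncovered sequence with a reason.

    The three universe arguments are the sets of sequence ids still
    represented after enumeration, after the GC filters and after the
    cluster size cut-offs; they pin down at which stage each excluded
    sequence was lost.
    """
    covered = ranked.covered_union()
    excluded_rows = [
        {
            "seq_id": r.seq_id,
            "header": r.header,
            "reason": _exclusion_reason(
                r, config.primer_length, enumerated_universe, post_gc_universe,
                post_cutoff_universe,
            ),
        }
        for r in records
        if r.seq_id not in covered
    ]
    excluded = pd.DataFrame(excluded_rows, columns=["seq_id", "header", "reason"])
    total_bases = sum(len(r) for r in records)
    final_cov = (
        ranked.clusters[-1].cumulative_coverage if ranked.clusters else 0.0
    )
    description = "\n".join(
        [
            "Multiplexed primer design summary",
            f"input sequences: {len(records)}",
            f"input bases: {total_bases}",
            f"primer clusters: {len(ranked.clusters)}",
            f"covered sequences: {len(covered)}",
            f"excluded sequences: {len(excluded_rows)}",
            f"final cumulative coverage: {final_cov}",
            "parameters:",
            f"  primer_length: {config.primer_length}",
            f"  min_primer_group_size: {config.min_primer_group_size}",
            f"  min_sequence_group_size: {config.min_sequence_group_size}",
            f"  decimals: {config.decimals}",
            f"  gc_min: {config.gc_min}",
            f"  gc_max: {config.gc_max}",
            f"  max_gc_half_diff: {config.max_gc_half_diff}",
        ]
    )
    return DesignResult(
        description=description,
        conversion_table=conversion_table(records),
        primer_candidates=cluster_table(ranked),
        excluded_sequences=excluded,
        primer_matrix=coverage_matrix(ranked),
    )


def primers(result: DesignResult) -> pd.DataFrame:
    """The ranked primer-cluster table, unchanged."""
    return result.primer_candidates


def sequences(result: DesignResult) -> pd.DataFrame:
    """Per covered sequence, the cluster ids covering it (matrix transpose)."""
    m = result.primer_matrix
    rows = []
    for seq_id in m.columns:
        covering = [int(cid) for cid in m.index[m[seq_id]]]
        if covering:
            rows.append(
                {"seq_id": int(seq_id),
                 "cluster_ids": ",".join(str(c) for c in covering)}
            )
    return pd.DataFrame(rows, columns=["seq_id", "cluster_ids"])


def plot_heatmap(matrix: pd.DataFrame, out: str | Path | None = None):
    """Render the coverage matrix as a two-colour heatmap.

    Covered cells are dark, uncovered light; x axis runs over sequence
    ids, y axis over primer clusters in rank order (rank 1 on top).
    Writes PNG or SVG depending on the extension of ``out``.
    Returns (figure, axes) so callers can inspect or embed the plot.
    """
    if matrix.size == 0:
        raise EmptyMatrixError(
            "coverage matrix is empty: all sequences were excluded; "
            "relax the filters or cut-offs"
        )
    fig, ax = plt.subplots(
        figsize=(max(4, matrix.shape[1] * 0.12), max(3, matrix.shape[0] * 0.12))
    )
    cmap = ListedColormap(["#f5f5f5", "#1a1a1a"])
    ax.imshow(
        matrix.to_numpy(dtype=int),
        cmap=cmap,
        vmin=0,
        vmax=1,
        aspect="auto",
        interpolation="none",
    )
    ax.set_xlabel("Sequence id")
    ax.set_ylabel("Primer cluster")
    xstep = max(1, matrix.shape[1] // 30)
    ystep = max(1, matrix.shape[0] // 30)
    ax.set_xticks(
        range(0, matrix.shape[1], xstep),
        labels=[str(c) for c in matrix.columns[::xstep]],
    )
    ax.set_yticks(
        range(0, matrix.shape[0], ystep),
        labels=[str(r) for r in matrix.index[::ystep]],
    )
    fig.tight_layout()
    if out is not None:
        fig.savefig(str(out), dpi=150)
    return fig, ax


def write_result(
    result: DesignResult, outdir: str | Path, *, strict: bool = False,
    heatmap: bool = True,
) -> None:
    """Write the five elements (and the heatmap) as plain-text files.

    ``strict`` drops the diagnostic reason column from the excluded
    table.  The matrix is serialised with TRUE/FALSE cells, a header
    row of sequence ids and rows led by cluster_id.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "description.txt").write_text(result.description + "\n")
    result.conversion_table.to_csv(
        outdir / "conversion_table.tsv", sep="\t", index=False
    )
    result.primer_candidates.to_csv(
        outdir / "primer_candidates.tsv", sep="\t", index=False
    )
    excluded = result.excluded_sequences
    if strict:
        excluded = excluded[["seq_id", "header"]]
    excluded.to_csv(outdir / "excluded_sequences.tsv", sep="\t", index=False)
    m = result.primer_matrix.map(lambda v: "TRUE" if v else "FALSE")
    m.index.name = "cluster_id"
    m.to_csv(outdir / "primer_matrix.tsv", sep="\t")
    if heatmap and result.primer_matrix.size > 0:
        fig, _ = plot_heatmap(result.primer_matrix, outdir / "heatmap.png")
        plt.close(fig)
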
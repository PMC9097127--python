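"""Coverage clustering: the core of the set-cover approximation.

Candidates with exactly the same coverage set are interchangeable for
covering purposes, so they are merged into one *primer cluster* whose
*sequence group* is the shared coverage set.  Clusters are filtered by
two size cut-offs, ranked by size, annotated with the rounded running
fraction of sequences covered (cumulative coverage), and finally
clusters tied on cumulative coverage are collapsed to the largest ones
— removing clusters that add no or nearly no new coverage.  The whole
chain is a linear-time alternative to solving minimum set cover
exactly (NP-hard); its output is a near-optimal cover.

Ordering convention: "size" ranks by sequence-group size first (the
quantity being maximised), then primer-group size, with a final
deterministic tie-break on the lexicographically smallest member
k-mer, so output order is reproducible across runs and platforms.
Cumulative values are round-half-away-from-zero at d decimals and are
frozen from the pre-reduction walk; they are not recomputed after the
collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
import pandas as pd

from .candidates import CandidateIndex, PackedIndex, _decode_codes


def round_half_up(x_num: int, x_den: int, decimals: int) -> float:
    """Round the exact fraction x_num/x_den half-away-from-zero to d decimals."""
    q = Decimal(x_num) / Decimal(x_den)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrimerCluster:
    """A maximal set of primer candidates sharing one coverage set."""

    cluster_id: int  # 0 before ranking; 1..m in rank order after
    primers: frozenset[str]
    sequence_group: frozenset[int]
    cumulative_coverage: float | None = None
    # cached lexicographic order of primers, when built from packed codes
    presorted: tuple[str, ...] | None = field(
        default=None, compare=False, repr=False
    )

    @property
    def primer_group_size(self) -> int:
        return len(self.primers)

    @property
    def sequence_group_size(self) -> int:
        return len(self.sequence_group)

    @property
    def sorted_primers(self) -> list[str]:
        if self.presorted is not None:
            return list(self.presorted)
        return sorted(self.primers)

    @property
    def min_primer(self) -> str:
        if self.presorted is not None:
            return self.presorted[0]
        return min(self.primers)


@dataclass
class RankedClusterList:
    """Clusters in rank order with frozen cumulative coverage values."""

    clusters: list[PrimerCluster]
    n_sequences: int
    decimals: int

    def __len__(self) -> int:
        return len(self.clusters)

    def covered_union(self) -> frozenset[int]:
        u: set[int] = set()
        for c in self.clusters:
            u |= c.sequence_group
        return frozenset(u)


def _mix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finaliser; a cheap, well-scrambled per-id hash."""
    z = x.astype(np.uint64) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _build_clusters_packed(p: PackedIndex) -> list[PrimerCluster]:
    """Group k-mers with identical coverage sets, staying in arrays.

    Coverage sets are first bucketed by (size, order-independent hash
    sum of member ids); buckets are then verified — and, on the
    vanishingly rare hash collision, split — by direct comparison of
    the id slices.  Only the final clusters materialise Python objects.
    """
    if p.codes.size == 0:
        return []
    counts = p.ends - p.starts
    hsum = np.add.reduceat(_mix64(p.sids), p.starts)
    order = np.lexsort((hsum, counts))
    oc, oh = counts[order], hsum[order]
    boundary = np.empty(order.size, dtype=bool)
    boundary[0] = True
    boundary[1:] = (oc[1:] != oc[:-1]) | (oh[1:] != oh[:-1])
    group_starts = np.flatnonzero(boundary)
    group_ends = np.append(group_starts[1:], order.size)
    sids_list = p.sids
    clusters: list[PrimerCluster] = []
    for gs, ge in zip(group_starts.tolist(), group_ends.tolist()):
        members = order[gs:ge]
        length = int(counts[members[0]])
        # gather each member's id slice into one matrix for verification
        idx = p.starts[members][:, None] + np.arange(length)
        mat = sids_list[idx]
        if members.size == 1 or (mat == mat[0]).all():
            subgroups = [(members, mat[0])]
        else:  # hash collision: split by exact slice content
            uniq, inverse = np.unique(mat, axis=0, return_inverse=True)
            subgroups = [
                (members[inverse == u], uniq[u]) for u in range(uniq.shape[0])
            ]
        for sub_members, row in subgroups:
            ordered = _decode_codes(np.sort(p.codes[sub_members]), p.k)
            clusters.append(
                PrimerCluster(
                    cluster_id=0,
                    primers=frozenset(ordered),
                    sequence_group=frozenset(row.tolist()),
                    presorted=tuple(ordered),
                )
            )
    return clusters


def build_clusters(index: CandidateIndex) -> list[PrimerCluster]:
    """Partition candidates by exact coverage-set equality.

    Each equivalence class becomes one cluster; every candidate belongs
    to exactly one cluster, and sequence groups are pairwise distinct.
    """
    if index.packed is not None:
        return _build_clusters_packed(index.packed)
    by_coverage: dict[frozenset[int], set[str]] = {}
    for kmer, cov in index.entries.items():
        by_coverage.setdefault(cov, set()).add(kmer)
    return [
        PrimerCluster(cluster_id=0, primers=frozenset(kmers), sequence_group=cov)
        for cov, kmers in by_coverage.items()
    ]


def filter_clusters(
    clusters: Iterable[PrimerCluster],
    min_primer_group_size: int = 1,
    min_sequence_group_size: int = 1,
) -> list[PrimerCluster]:
    """Drop clusters below either size cut-off (both >= 1).

    Removing every cluster is not an error; downstream reports all
    sequences as excluded.
    """
    if min_primer_group_size < 1 or min_sequence_group_size < 1:
        raise ValueError("size cut-offs must be >= 1")
    return [
        c
        for c in clusters
        if c.primer_group_size >= min_primer_group_size
        and c.sequence_group_size >= min_sequence_group_size
    ]


def _rank_key(c: PrimerCluster) -> tuple[int, int, str]:
    return (-c.sequence_group_size, -c.primer_group_size, c.min_primer)


def rank_and_cumulate(
    clusters: Iterable[PrimerCluster], n_sequences: int, decimals: int = 4
) -> RankedClusterList:
    """Sort clusters by size and attach rounded running coverage.

    Walking the sorted order, a running union of sequence groups is
    maintained; each cluster's cumulative coverage is |union|/n rounded
    half-away-from-zero to ``decimals`` places.  Cluster ids are
    assigned 1..m in rank order.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if decimals < 1:
        raise ValueError("decimals must be >= 1")
    ordered = sorted(clusters, key=_rank_key)
    out: list[PrimerCluster] = []
    union: set[int] = set()
    for i, c in enumerate(ordered, start=1):
        union |= c.sequence_group
        out.append(
            replace(
                c,
                cluster_id=i,
                cumulative_coverage=round_half_up(len(union), n_sequences, decimals),
            )
        )
    return RankedClusterList(clusters=out, n_sequences=n_sequences, decimals=decimals)


def deduplicate_by_cumulative(ranked: RankedClusterList) -> RankedClusterList:
    """Collapse runs of clusters tied on rounded cumulative coverage.

    Within each tied group only the clusters attaining the maximal
    sequence-group size — and among those the maximal primer-group size
    — are kept; further ties keep all co-maximal clusters.  Cumulative
    values stay as computed on the pre-reduction walk.  At rounding
    precision finer than 1/n this removes exactly the clusters that
    contributed no new sequence to the running union.
    """
    kept: list[PrimerCluster] = []
    group: list[PrimerCluster] = []

    def flush() -> None:
        if not group:
            return
        max_seq = max(c.sequence_group_size for c in group)
        best = [c for c in group if c.sequence_group_size == max_seq]
        max_pri = max(c.primer_group_size for c in best)
        kept.extend(c for c in best if c.primer_group_size == max_pri)
        group.clear()

    for c in ranked.clusters:
        if group and c.cumulative_coverage != group[-1].cumulative_coverage:
            flush()
        group.append(c)
    flush()
    renumbered = [replace(c, cluster_id=i) for i, c in enumerate(kept, start=1)]
    return RankedClusterList(
        clusters=renumbered, n_sequences=ranked.n_sequences, decimals=ranked.decimals
    )


def cluster_table(ranked: RankedClusterList) -> pd.DataFrame:
    """The primer-candidates table: one row per retained cluster, rank order."""
    rows = [
        {
            "cluster_id": c.cluster_id,
            "primers": ",".join(c.sorted_primers),
            "seq_ids": ",".join(str(s) for s in sorted(c.sequence_group)),
            "primer_group_size": c.primer_group_size,
            "sequence_group_size": c.sequence_group_size,
            "cumulative_coverage": c.cumulative_coverage,
        }
        for c in ranked.clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "primers",
            "seq_ids",
            "primer_group_size",
            "sequence_group_size",
            "cumulative_coverage",
        ],
    )
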
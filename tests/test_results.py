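"""Result bundle assembly, accessors, coverage matrix and heatmap."""

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import pytest

from primercover.candidates import enumerate_candidates
from primercover.clusters import (
    build_clusters,
    deduplicate_by_cumulative,
    rank_and_cumulate,
)
from primercover.pipeline import Config, run_pipeline
from primercover.results import (
    EmptyMatrixError,
    coverage_matrix,
    plot_heatmap,
    primers,
    sequences,
    write_result,
)
from primercover.synth import FixtureSpec, make_records, synthesize_fasta

from conftest import rec


def ranked_from(records, k=20, decimals=10):
    idx = enumerate_candidates(records, k)
    return deduplicate_by_cumulative(
        rank_and_cumulate(build_clusters(idx), len(records), decimals)
    )


@pytest.fixture
def family_result(tmp_path):
    spec = FixtureSpec(
        n_sequences=20, bases_per_sequence=200, mode="family",
        n_ancestors=2, substitution_rate=0.02, seed=11,
    )
    fasta = synthesize_fasta(spec, tmp_path / "fam.fasta")
    cfg = Config(min_sequence_group_size=1, decimals=10)
    return run_pipeline(fasta, cfg, write=False)


class TestCoverageMatrix:
    def test_row_sums_equal_sequence_group_sizes(self, family_records):
        ranked = ranked_from(family_records)
        m = coverage_matrix(ranked)
        for c in ranked.clusters:
            assert m.loc[c.cluster_id].sum() == c.sequence_group_size

    def test_excluded_sequences_are_all_false_columns(self):
        records = [rec(1, "ACGTACGTAA"), rec(2, "ACGTACGTAA"), rec(3, "TT")]
        ranked = ranked_from(records, k=10)
        m = coverage_matrix(ranked)
        assert list(m.columns) == [1, 2, 3]
        assert not m[3].any()
        assert m[1].any() and m[2].any()


class TestBuildResult:
    def test_all_covered_means_no_exclusions(self, family_result):
        assert family_result.excluded_sequences.empty
        covered = family_result.primer_matrix.any(axis=0)
        assert covered.all()

    def test_too_short_sequence_reported(self, tmp_path):
        (tmp_path / "mix.fasta").write_text(
            ">long1\nACGTACGTACGT\n>long2\nACGTACGTACGT\n>short\nACG\n"
        )
        cfg = Config(primer_length=12, min_sequence_group_size=1)
        result = run_pipeline(tmp_path / "mix.fasta", cfg, write=False)
        excl = result.excluded_sequences
        assert list(excl["seq_id"]) == [3]
        assert list(excl["reason"]) == ["too_short"]

    def test_gc_filter_exclusion_reason(self, tmp_path):
        (tmp_path / "gc.fasta").write_text(">a\nAAAATTTT\n>b\nAAAATTTT\n")
        cfg = Config(
            primer_length=8, min_sequence_group_size=1, gc_min=0.4, gc_max=0.6
        )
        result = run_pipeline(tmp_path / "gc.fasta", cfg, write=False)
        assert set(result.excluded_sequences["reason"]) == {"filtered_gc"}
        assert len(result.excluded_sequences) == 2

    def test_cutoff_exclusion_reason(self, tmp_path):
        (tmp_path / "cut.fasta").write_text(
            ">a\nACGTACGT\n>b\nACGTACGT\n>c\nGGTTGGCC\n"
        )
        cfg = Config(primer_length=8, min_sequence_group_size=2)
        result = run_pipeline(tmp_path / "cut.fasta", cfg, write=False)
        excl = result.excluded_sequences
        assert list(excl["seq_id"]) == [3]
        assert list(excl["reason"]) == ["filtered_cluster_cutoffs"]

    def test_partition_of_sequence_ids(self, tmp_path):
        spec = FixtureSpec(
            n_sequences=15, bases_per_sequence=120, mode="family",
            n_ancestors=3, substitution_rate=0.05, seed=3,
        )
        fasta = synthesize_fasta(spec, tmp_path / "p.fasta")
        result = run_pipeline(
            fasta, Config(min_sequence_group_size=2, decimals=10), write=False
        )
        covered = {
            int(s) for s in result.primer_matrix.columns
            if result.primer_matrix[s].any()
        }
        excluded = set(result.excluded_sequences["seq_id"])
        assert covered | excluded == set(range(1, 16))
        assert covered & excluded == set()

    def test_description_counts_are_consistent(self, family_result):
        text = family_result.description
        assert "input sequences: 20" in text
        assert f"primer clusters: {len(family_result.primer_candidates)}" in text
        assert "excluded sequences: 0" in text


class TestAccessors:
    def test_primers_returns_cluster_table_unchanged(self, family_result):
        pd.testing.assert_frame_equal(
            primers(family_result), family_result.primer_candidates
        )

    def test_sequences_is_matrix_transpose(self, family_result):
        table = sequences(family_result)
        m = family_result.primer_matrix
        assert set(table["seq_id"]) == {
            int(c) for c in m.columns if m[c].any()
        }
        for row in table.itertuples(index=False):
            expected = [int(cid) for cid in m.index[m[row.seq_id]]]
            assert [int(x) for x in row.cluster_ids.split(",")] == expected

    def test_excluded_absent_from_sequences_table(self, tmp_path):
        (tmp_path / "mix.fasta").write_text(
            ">a\nACGTACGTACGT\n>b\nACGTACGTACGT\n>short\nACG\n"
        )
        result = run_pipeline(
            tmp_path / "mix.fasta",
            Config(primer_length=12, min_sequence_group_size=1),
            write=False,
        )
        assert 3 not in set(sequences(result)["seq_id"])

    def test_element_access_by_name(self, family_result):
        for name in (
            "description", "conversion_table", "primer_candidates",
            "excluded_sequences", "primer_matrix",
        ):
            assert family_result[name] is getattr(family_result, name)


class TestHeatmap:
    def _dark_cells(self, ax):
        return int(np.asarray(ax.images[0].get_array()).sum())

    def test_identity_matrix_has_two_dark_cells(self):
        m = pd.DataFrame([[True, False], [False, True]], index=[1, 2], columns=[1, 2])
        fig, ax = plot_heatmap(m)
        assert self._dark_cells(ax) == 2
        plt.close(fig)

    def test_all_true_matrix_uniformly_dark(self):
        m = pd.DataFrame(True, index=[1, 2, 3], columns=[1, 2, 3, 4])
        fig, ax = plot_heatmap(m)
        assert self._dark_cells(ax) == 12
        plt.close(fig)

    def test_family_fixture_dark_count_equals_matrix_trues(self, family_result):
        m = family_result.primer_matrix
        fig, ax = plot_heatmap(m)
        assert self._dark_cells(ax) == int(m.to_numpy().sum())
        plt.close(fig)

    def test_empty_matrix_raises_with_advice(self):
        with pytest.raises(EmptyMatrixError, match="excluded"):
            plot_heatmap(pd.DataFrame())

    def test_writes_png_and_svg(self, tmp_path, family_result):
        for name in ("h.png", "h.svg"):
            fig, _ = plot_heatmap(family_result.primer_matrix, tmp_path / name)
            plt.close(fig)
            assert (tmp_path / name).stat().st_size > 0


class TestWriteResult:
    EXPECTED = [
        "description.txt", "conversion_table.tsv", "primer_candidates.tsv",
        "excluded_sequences.tsv", "primer_matrix.tsv", "heatmap.png",
    ]

    def test_all_files_written(self, tmp_path, family_result):
        write_result(family_result, tmp_path / "out")
        for name in self.EXPECTED:
            assert (tmp_path / "out" / name).exists()

    def test_matrix_round_trips_from_tsv(self, tmp_path, family_result):
        write_result(family_result, tmp_path / "out")
        back = pd.read_csv(
            tmp_path / "out" / "primer_matrix.tsv", sep="\t", index_col=0
        )
        assert (
            back.to_numpy() == family_result.primer_matrix.to_numpy()
        ).all()

    def test_strict_mode_omits_reason_column(self, tmp_path):
        (tmp_path / "mix.fasta").write_text(
            ">a\nACGTACGTACGT\n>b\nACGTACGTACGT\n>short\nACG\n"
        )
        result = run_pipeline(
            tmp_path / "mix.fasta",
            Config(primer_length=12, min_sequence_group_size=1),
            write=False,
        )
        write_result(result, tmp_path / "strict", strict=True)
        cols = pd.read_csv(
            tmp_path / "strict" / "excluded_sequences.tsv", sep="\t"
        ).columns
        assert list(cols) == ["seq_id", "header"]

    def test_matrix_rebuilt_from_cluster_table_is_identical(self, family_result):
        m = family_result.primer_matrix
        rebuilt = pd.DataFrame(False, index=m.index, columns=m.columns)
        for row in family_result.primer_candidates.itertuples(index=False):
            for s in row.seq_ids.split(","):
                rebuilt.loc[row.cluster_id, int(s)] = True
        assert (rebuilt.to_numpy() == m.to_numpy()).all()
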
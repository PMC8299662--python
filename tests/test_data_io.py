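import numpy as np
import pandas as pd
import pytest

from cernet import data_io
from cernet.data_io import (
    DataValidationError,
    ExpressionMatrix,
    log2_transform,
    map_feature_ids,
    read_expression_table,
    write_expression_table,
)


def _write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadExpressionTable:
    def test_paired_circ_cohort_shape(self, tmp_path):
        """A 4-tumor/4-normal table yields 8 labelled samples of kind circRNA."""
        header = "feature_id\t" + "\t".join(f"S{i}" for i in range(8))
        rows = [f"circ{j}\t" + "\t".join(str(j + i) for i in range(8)) for j in range(3)]
        path = _write_tsv(tmp_path / "e.tsv", header + "\n" + "\n".join(rows) + "\n")
        groups = {f"S{i}": "tumor" if i < 4 else "normal" for i in range(8)}
        m = read_expression_table(path, "circRNA", group_map=groups)
        assert m.n_samples == 8
        assert m.feature_kind == "circRNA"
        assert len(m.samples_in_group("tumor")) == 4
        assert len(m.samples_in_group("normal")) == 4

    def test_header_only_is_no_features(self, tmp_path):
        path = _write_tsv(tmp_path / "e.tsv", "feature_id\tS1\tS2\n")
        with pytest.raises(DataValidationError, match="no features"):
            read_expression_table(path, "mRNA")

    def test_max_mean_collapse_keeps_larger_mean_row(self, tmp_path):
        """Duplicate probe: the surviving row is the one with the larger mean.

        Hand computation: row means are (1+2+3)/3 = 2 and (4+5+6)/3 = 5,
        so the second row must survive.
        """
        text = "feature_id\tA\tB\tC\np1\t1\t2\t3\np1\t4\t5\t6\n"
        m = read_expression_table(_write_tsv(tmp_path / "e.tsv", text), "mRNA")
        assert m.n_features == 1
        assert list(m.data.loc["p1"]) == [4.0, 5.0, 6.0]

    def test_mean_collapse_averages_rows(self, tmp_path):
        text = "feature_id\tA\tB\tC\np1\t1\t2\t3\np1\t4\t5\t6\n"
        m = read_expression_table(_write_tsv(tmp_path / "e.tsv", text), "mRNA", collapse="mean")
        assert list(m.data.loc["p1"]) == [2.5, 3.5, 4.5]

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        text = "feature_id\tA\tB\nf1\t1\toops\n"
        with pytest.raises(DataValidationError, match="'f1'.*'B'"):
            read_expression_table(_write_tsv(tmp_path / "e.tsv", text), "mRNA")

    def test_unknown_sample_in_group_map_is_an_error(self, tmp_path):
        text = "feature_id\tA\nf1\t1\n"
        with pytest.raises(DataValidationError, match="unknown sample"):
            read_expression_table(
                _write_tsv(tmp_path / "e.tsv", text), "mRNA", group_map={"Z": "tumor"}
            )

    def test_round_trip_is_exact_and_order_preserving(self, tmp_path, rng):
        data = pd.DataFrame(
            rng.normal(size=(20, 6)), index=[f"f{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(6)],
        )
        m = ExpressionMatrix(data=data, feature_kind="miRNA")
        write_expression_table(m, tmp_path / "m.tsv")
        back = read_expression_table(tmp_path / "m.tsv", "miRNA")
        assert list(back.data.index) == list(data.index)
        assert list(back.data.columns) == list(data.columns)
        assert (back.data.values == data.values).all()


class TestExpressionMatrixInvariants:
    def test_pair_key_twice_in_one_group_rejected(self):
        data = pd.DataFrame(np.ones((2, 4)), index=["a", "b"], columns=list("wxyz"))
        groups = pd.Series(["tumor", "tumor", "normal", "normal"], index=data.columns)
        pairs = pd.Series(["p1", "p1", "p1", "p2"], index=data.columns)
        with pytest.raises(DataValidationError, match="appears twice"):
            ExpressionMatrix(data=data, feature_kind="mRNA", group_labels=groups, pair_ids=pairs)

    def test_infinite_values_rejected(self):
        data = pd.DataFrame([[np.inf, 1.0]], index=["a"], columns=["x", "y"])
        with pytest.raises(DataValidationError, match="finite"):
            ExpressionMatrix(data=data, feature_kind="mRNA")


class TestLog2Transform:
    def test_element_wise_values(self):
        """log2(0+1)=0, log2(7+1)=3, and a grid matches element-wise recomputation."""
        grid = pd.DataFrame([[0.0, 7.0], [3.0, 15.0], [1.0, 63.0]],
                            index=list("abc"), columns=["s1", "s2"])
        m = ExpressionMatrix(data=grid, feature_kind="mRNA")
        out = log2_transform(m, offset=1.0)
        assert out.data.loc["a", "s1"] == 0.0
        assert out.data.loc["a", "s2"] == 3.0
        expected = np.log2(grid.values + 1.0)
        assert np.array_equal(out.data.values, expected)

    def test_already_log_is_bit_identical_noop(self, small_matrix):
        out = log2_transform(small_matrix, already_log=True)
        assert np.array_equal(out.data.values, small_matrix.data.values)

    def test_negative_input_rejected(self):
        m = ExpressionMatrix(
            data=pd.DataFrame([[-1.0]], index=["a"], columns=["s"]), feature_kind="mRNA"
        )
        with pytest.raises(DataValidationError, match="negative"):
            log2_transform(m, offset=1.0)


class TestMapFeatureIds:
    def test_unmapped_probes_dropped(self, rng):
        data = pd.DataFrame(rng.normal(size=(5, 3)), index=[f"p{i}" for i in range(5)],
                            columns=list("abc"))
        m = ExpressionMatrix(data=data, feature_kind="mRNA")
        mapped = map_feature_ids(m, {"p0": "G1", "p1": "G2", "p2": "G3"})
        assert mapped.n_features == 3
        assert set(mapped.data.index) == {"G1", "G2", "G3"}

    def test_identity_mapping_is_noop(self, small_matrix):
        mapping = {f: f for f in small_matrix.feature_ids}
        out = map_feature_ids(small_matrix, mapping)
        assert (out.data.values == small_matrix.data.values).all()

    def test_mean_collapse_after_mapping_is_columnwise_mean(self):
        """Two probes -> one symbol: hand-checked per-column mean of a 2x3 table."""
        data = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 6.0, 7.0]], index=["p1", "p2"],
                            columns=list("abc"))
        m = ExpressionMatrix(data=data, feature_kind="mRNA")
        out = map_feature_ids(m, {"p1": "G", "p2": "G"}, collapse="mean")
        assert list(out.data.loc["G"]) == [3.0, 4.0, 5.0]

    def test_never_increases_feature_count(self, bundle):
        m = bundle.matrices["circ_a"]
        mapping = {f: f.upper() for f in m.feature_ids[:100]}
        assert map_feature_ids(m, mapping).n_features <= m.n_features

    def test_empty_mapping_rejected(self, small_matrix):
        with pytest.raises(DataValidationError, match="empty"):
            map_feature_ids(small_matrix, {})


class TestOtherReaders:
    def test_gmt_line_parses_members(self, tmp_path):
        path = _write_tsv(tmp_path / "s.gmt", "JAK_STAT\tdesc\tIL7R\tCCND2\n")
        gs = data_io.read_gene_sets_gmt(path)
        assert gs.sets["JAK_STAT"] == frozenset({"IL7R", "CCND2"})

    def test_gmt_short_line_reports_line_number(self, tmp_path):
        path = _write_tsv(tmp_path / "s.gmt", "OK\td\tG1\nBAD\tonly-two\n")
        with pytest.raises(DataValidationError, match="line 2"):
            data_io.read_gene_sets_gmt(path)

    def test_interaction_duplicates_removed(self, tmp_path):
        path = _write_tsv(
            tmp_path / "p.tsv", "mirna_id\tpartner_id\nm1\tc1\nm1\tc1\nm2\tc2\n"
        )
        table = data_io.read_interaction_table(path, "miRNA_circRNA")
        assert len(table) == 2

    def test_negative_survival_time_rejected(self, tmp_path):
        path = _write_tsv(
            tmp_path / "c.tsv", "sample_id\tos_time_days\tos_event\ns1\t-3\t1\n"
        )
        with pytest.raises(DataValidationError, match="invalid os_time"):
            data_io.read_clinical_table(path)

    def test_duplicate_clinical_sample_rejected(self, tmp_path):
        path = _write_tsv(
            tmp_path / "c.tsv",
            "sample_id\tos_time_days\tos_event\ns1\t3\t1\ns1\t5\t0\n",
        )
        with pytest.raises(DataValidationError, match="duplicate"):
            data_io.read_clinical_table(path)

    def test_drug_matrix_requires_scale_metadata(self, tmp_path):
        path = _write_tsv(tmp_path / "d.tsv", "cell_line_id\tD1\nCL1\t0.5\n")
        with pytest.raises(DataValidationError, match="#scale="):
            data_io.read_drug_matrix(path)
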
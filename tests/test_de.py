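import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cernet.data_io import DataValidationError, ExpressionMatrix
from cernet.de import (
    ThresholdConfig,
    bh_adjust,
    classify_direction,
    differential_expression,
    overlap_significance,
    significant_features,
)

from _oracles import bh_step_up, enum_hypergeom_upper


def _matrix(tumor: dict, normal: dict, pair=False) -> ExpressionMatrix:
    data = pd.DataFrame(tumor).T
    data.columns = [f"T{i}" for i in range(data.shape[1])]
    norm = pd.DataFrame(normal).T
    norm.columns = [f"N{i}" for i in range(norm.shape[1])]
    full = pd.concat([data, norm], axis=1)
    groups = pd.Series(
        ["tumor"] * data.shape[1] + ["normal"] * norm.shape[1], index=full.columns
    )
    pairs = None
    if pair:
        keys = [f"p{i}" for i in range(data.shape[1])]
        pairs = pd.Series(keys + keys, index=full.columns)
    return ExpressionMatrix(data=full, feature_kind="mRNA", group_labels=groups, pair_ids=pairs)


class TestDifferentialExpression:
    def test_identical_groups_give_zero_fc_and_none(self):
        m = _matrix({"f": [1.0, 2.0, 3.0]}, {"f": [1.0, 2.0, 3.0]})
        res = differential_expression(m, ThresholdConfig(de_method="student_t"))
        assert res.loc[0, "log2fc"] == 0.0
        assert res.loc[0, "direction"] == "none"

    def test_student_t_matches_closed_form(self):
        """Tumor {5,6,7} vs normal {1,2,3}: log2FC = 4 and the p-value equals
        the pooled-variance two-sample t formula with 4 df, recomputed here
        from first principles."""
        m = _matrix({"f": [5.0, 6.0, 7.0]}, {"f": [1.0, 2.0, 3.0]})
        res = differential_expression(m, ThresholdConfig(de_method="student_t"))
        assert res.loc[0, "log2fc"] == pytest.approx(4.0)
        # closed form: s_p^2 = (2 + 2) / 4 = 1; t = 4 / sqrt(1 * (1/3 + 1/3))
        t_stat = 4.0 / math.sqrt(2.0 / 3.0)
        p_expected = 2.0 * stats.t.sf(t_stat, df=4)
        assert res.loc[0, "p_value"] == pytest.approx(p_expected, rel=1e-12)

    def test_zero_variance_both_groups(self):
        m = _matrix({"f": [2.0, 2.0, 2.0], "g": [2.0, 2.0, 2.0]},
                    {"f": [1.0, 1.0, 1.0], "g": [2.0, 2.0, 2.0]})
        res = differential_expression(m).set_index("feature_id")
        assert res.loc["f", "p_value"] == 0.0
        assert res.loc["g", "p_value"] == 1.0

    def test_group_smaller_than_two_rejected(self):
        data = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=["a", "b", "c"])
        groups = pd.Series(["tumor", "normal", "normal"], index=data.columns)
        m = ExpressionMatrix(data=data, feature_kind="mRNA", group_labels=groups)
        with pytest.raises(DataValidationError, match="at least 2"):
            differential_expression(m)

    def test_up_down_partition_sums_to_significant(self, bundle):
        res = differential_expression(bundle.matrices["mrna_seq"], dataset_id="x")
        sig = significant_features(res)
        assert len(sig) == (res["direction"] == "up").sum() + (res["direction"] == "down").sum()

    def test_paired_t_uses_pairing(self):
        # strong patient effect: unpaired test is diluted, paired is not
        rng = np.random.default_rng(0)
        offsets = rng.normal(0, 5, size=6)
        tumor = offsets + 1.0
        normal = offsets
        m = _matrix({"f": list(tumor)}, {"f": list(normal)}, pair=True)
        paired = differential_expression(m, ThresholdConfig(de_method="paired_t"))
        welch = differential_expression(m, ThresholdConfig(de_method="welch_t"))
        assert paired.loc[0, "p_value"] < welch.loc[0, "p_value"]
        assert paired.loc[0, "p_value"] < 1e-6

    def test_label_swap_negates_fc_and_preserves_p(self, rng):
        data = pd.DataFrame(rng.normal(size=(30, 10)), index=[f"f{i}" for i in range(30)],
                            columns=[f"s{i}" for i in range(10)])
        labels = ["tumor"] * 5 + ["normal"] * 5
        m1 = ExpressionMatrix(data=data, feature_kind="mRNA",
                              group_labels=pd.Series(labels, index=data.columns))
        m2 = ExpressionMatrix(data=data, feature_kind="mRNA",
                              group_labels=pd.Series(labels[::-1], index=data.columns))
        r1 = differential_expression(m1)
        r2 = differential_expression(m2)
        assert np.allclose(r1["log2fc"], -r2["log2fc"], atol=1e-12)
        assert np.allclose(r1["p_value"], r2["p_value"], rtol=1e-10)


class TestClassifyDirection:
    config = ThresholdConfig()

    @pytest.mark.parametrize(
        ("p", "fc", "expected"),
        [
            (0.01, 1.5, "up"),
            (0.01, -1.5, "down"),
            (0.01, 1.0, "none"),   # |log2FC| exactly at threshold: strict
            (0.05, -2.0, "none"),  # p exactly at threshold: strict
            (0.049, -1.001, "down"),
            (0.2, 3.0, "none"),
        ],
    )
    def test_strict_thresholds(self, p, fc, expected):
        assert classify_direction(fc, p, self.config) == expected


class TestBHAdjust:
    def test_toy_vector_collapses_to_max(self):
        assert list(bh_adjust([0.01, 0.02, 0.03])) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert list(bh_adjust([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_hand_step_up_and_dominates_raw(self, ps):
        adj = bh_adjust(ps)
        assert np.allclose(adj, bh_step_up(ps), atol=1e-12)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestOverlapSignificance:
    def test_zero_overlap_is_certain_event(self):
        res = overlap_significance(["a"], ["b"], [f"u{i}" for i in range(98)] + ["a", "b"])
        assert res.n_overlap == 0
        assert res.p_value == pytest.approx(1.0)

    def test_full_overlap_degenerate_margins(self):
        universe = [f"u{i}" for i in range(10)]
        res = overlap_significance(universe, universe, universe)
        assert res.n_overlap == 10
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_for_5_5_5_85(self):
        """overlap=5, a_only=5, b_only=5, neither=85: p must equal the exact
        sum of hypergeometric masses for k=5..10 (N=100, K=10, n=10)."""
        a = [f"ab{i}" for i in range(5)] + [f"a{i}" for i in range(5)]
        b = [f"ab{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        universe = set(a) | set(b) | {f"n{i}" for i in range(85)}
        res = overlap_significance(a, b, universe)
        assert res.p_value == pytest.approx(enum_hypergeom_upper(5, 10, 10, 100), rel=1e-12)
        assert res.n_neither == 85

    def test_odds_ratio_uses_haldane_when_cell_zero(self):
        a = ["x1", "x2"]
        b = ["x1", "x2"]
        universe = ["x1", "x2", "y1", "y2"]
        res = overlap_significance(a, b, universe)  # n12 = n21 = 0
        assert res.odds_ratio == pytest.approx((2.5 * 2.5) / (0.5 * 0.5))

    def test_empty_universe_rejected(self):
        with pytest.raises(DataValidationError, match="universe"):
            overlap_significance([], [], [])

    def test_non_subset_rejected(self):
        with pytest.raises(DataValidationError, match="subset"):
            overlap_significance(["z"], [], ["a"])
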
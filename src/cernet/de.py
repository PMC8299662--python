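"""Tumor-vs-normal differential expression and DE-list overlap significance.

Per feature: log2 fold change = mean(log2 tumor) - mean(log2 normal), a
two-sample t test (Welch, pooled-variance Student, or paired), and a
Benjamini-Hochberg adjusted p.  A feature is called differentially
expressed when p < 0.05 and |log2FC| > 1 (strict inequalities, raw p by
default).  Overlap between two DE lists is scored with the one-sided
Fisher exact (hypergeometric upper-tail) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import NORMAL, TUMOR, DataValidationError, ExpressionMatrix, drop_sparse_features

logger = logging.getLogger(__name__)

DE_METHODS = ("welch_t", "student_t", "paired_t")

#: columns of the differential-expression result table
DE_COLUMNS = ["feature_id", "log2fc", "p_value", "adj_p", "direction", "dataset_id"]


@dataclass(frozen=True)
class ThresholdConfig:
    """Significance thresholds for calling differential expression."""

    p_threshold: float = 0.05
    fc_threshold: float = 1.0  # on the log2 scale: >1 means >2-fold
    use_adjusted_p: bool = False
    de_method: str = "welch_t"
    max_missing_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.p_threshold > 1:
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if self.de_method not in DE_METHODS:
            raise ValueError(f"de_method must be one of {DE_METHODS}")


@dataclass(frozen=True)
class OverlapResult:
    """2x2 overlap of two DE lists within a shared universe."""

    n_overlap: int
    n_a_only: int
    n_b_only: int
    n_universe: int
    odds_ratio: float
    p_value: float

    @property
    def n_neither(self) -> int:
        return self.n_universe - self.n_overlap - self.n_a_only - self.n_b_only


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_direction(log2fc: float, p: float, config: ThresholdConfig) -> str:
    """up/down/none under strict thresholds (boundary values are not DE)."""
    if p < config.p_threshold and log2fc > config.fc_threshold:
        return "up"
    if p < config.p_threshold and log2fc < -config.fc_threshold:
        return "down"
    return "none"


def _paired_arrays(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Align tumor and normal columns by pair id."""
    if matrix.pair_ids is None or matrix.pair_ids.isna().any():
        raise DataValidationError("paired_t requires complete pair_ids")
    tumor = {matrix.pair_ids[s]: s for s in matrix.samples_in_group(TUMOR)}
    normal = {matrix.pair_ids[s]: s for s in matrix.samples_in_group(NORMAL)}
    keys = sorted(set(tumor) & set(normal))
    if len(keys) < 2:
        raise DataValidationError("paired_t requires at least 2 complete pairs")
    t = matrix.data[[tumor[k] for k in keys]].to_numpy()
    n = matrix.data[[normal[k] for k in keys]].to_numpy()
    return t, n


def differential_expression(
    matrix: ExpressionMatrix,
    config: ThresholdConfig = ThresholdConfig(),
    dataset_id: str = "",
) -> pd.DataFrame:
    """Per-feature log2FC, t-test p, BH adjusted p and direction call.

    Features with zero variance in both groups get p = 0 when the group
    means differ and p = 1 when they are equal (logged as a warning);
    missingness is handled pairwise-complete per feature after dropping
    features exceeding ``max_missing_fraction``.
    """
    if matrix.group_labels is None:
        raise DataValidationError("differential expression requires group labels")
    matrix = drop_sparse_features(matrix, config.max_missing_fraction)
    tumor_ids = matrix.samples_in_group(TUMOR)
    normal_ids = matrix.samples_in_group(NORMAL)
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise DataValidationError("each group needs at least 2 samples")

    if config.de_method == "paired_t":
        t_arr, n_arr = _paired_arrays(matrix)
    else:
        t_arr = matrix.data[tumor_ids].to_numpy()
        n_arr = matrix.data[normal_ids].to_numpy()

    log2fc = np.nanmean(t_arr, axis=1) - np.nanmean(n_arr, axis=1)
    pvals = np.empty(matrix.n_features)
    n_degenerate = 0
    for i in range(matrix.n_features):
        x = t_arr[i][~np.isnan(t_arr[i])]
        y = n_arr[i][~np.isnan(n_arr[i])]
        if config.de_method == "paired_t":
            diffs = t_arr[i] - n_arr[i]
            diffs = diffs[~np.isnan(diffs)]
            if len(diffs) < 2:
                pvals[i] = np.nan
                continue
            if np.ptp(diffs) == 0:
                pvals[i] = 0.0 if diffs[0] != 0 else 1.0
                n_degenerate += 1
                continue
            pvals[i] = stats.ttest_1samp(diffs, 0.0).pvalue
            continue
        if len(x) < 2 or len(y) < 2:
            pvals[i] = np.nan
            continue
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            pvals[i] = 0.0 if x[0] != y[0] else 1.0
            n_degenerate += 1
            continue
        equal_var = config.de_method == "student_t"
        pvals[i] = stats.ttest_ind(x, y, equal_var=equal_var).pvalue
    if n_degenerate:
        logger.warning("%d features had zero within-group variance in both groups", n_degenerate)

    computable = ~np.isnan(pvals)
    adj = np.full_like(pvals, np.nan)
    adj[computable] = bh_adjust(pvals[computable])
    p_for_calls = adj if config.use_adjusted_p else pvals
    directions = [
        classify_direction(fc, p, config) if np.isfinite(p) else "none"
        for fc, p in zip(log2fc, p_for_calls)
    ]
    result = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2fc": log2fc,
            "p_value": pvals,
            "adj_p": adj,
            "direction": directions,
            "dataset_id": dataset_id,
        }
    )
    n_up = (result["direction"] == "up").sum()
    n_down = (result["direction"] == "down").sum()
    logger.info(
        "%s: %d features, %d DE (%d up / %d down)",
        dataset_id or "DE", len(result), n_up + n_down, n_up, n_down,
    )
    return result


def significant_features(de: pd.DataFrame) -> pd.DataFrame:
    """Rows called up or down."""
    return de[de["direction"] != "none"]


def hypergeom_upper_tail(k: int, n_marked: int, n_drawn: int, n_total: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(n_total, n_marked, n_drawn)."""
    return float(stats.hypergeom.sf(k - 1, n_total, n_marked, n_drawn))


def overlap_significance(list_a, list_b, universe) -> OverlapResult:
    """One-sided Fisher exact enrichment of the overlap of two feature lists.

    The p-value is the hypergeometric upper tail including the observed
    overlap; the odds ratio uses a 0.5 Haldane substitute in every cell
    when any cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise DataValidationError("empty universe")
    a, b = set(list_a), set(list_b)
    if not a <= universe or not b <= universe:
        raise DataValidationError("DE lists must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    p = hypergeom_upper_tail(n11, len(a), len(b), len(universe))
    cells = [n11, n12, n21, n22]
    if 0 in cells:
        n11c, n12c, n21c, n22c = (c + 0.5 for c in cells)
    else:
        n11c, n12c, n21c, n22c = cells
    odds = (n11c * n22c) / (n12c * n21c)
    return OverlapResult(
        n_overlap=n11, n_a_only=n12, n_b_only=n21, n_universe=len(universe),
        odds_ratio=odds, p_value=p,
    )


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_table(path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "dataset_id": str})
    missing = set(DE_COLUMNS) - set(de.columns)
    if missing:
        raise DataValidationError(f"{path}: DE table lacks columns {sorted(missing)}")
    return de
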
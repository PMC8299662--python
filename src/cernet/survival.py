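"""Median-split Kaplan-Meier estimation and log-rank prognostic screening.

Each candidate gene dichotomizes the cohort at its median expression
(ties go to the low group, so "high" means strictly above the median);
the two overall-survival curves are then compared with the two-group
log-rank test, and genes with log-rank p < 0.05 are flagged prognostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .data_io import DataValidationError, ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

SCREEN_COLUMNS = [
    "gene_id", "n_high", "n_low", "chi_square", "p_value", "significant", "skip_reason",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate stepping only at event times."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray     # number at risk just before each event time

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise DataValidationError("KM survival must be non-increasing")


def median_split(expression: pd.Series) -> pd.Series:
    """Label samples high (strictly above the median) or low (at or below)."""
    values = expression.astype(float)
    if len(values) < 4:
        raise DataValidationError("median split needs >=4 samples")
    if values.nunique() == 1:
        raise DataValidationError("degenerate split: constant expression")
    median = values.median()
    labels = pd.Series(np.where(values > median, "high", "low"), index=values.index)
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise DataValidationError("degenerate split: one group empty")
    return labels


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod(1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise DataValidationError("empty survival input")
    if (times < 0).any() or not np.isin(events, (0, 1)).all():
        raise DataValidationError("times must be >=0, events binary")
    fitter = KaplanMeierFitter().fit(times, events)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return KMCurve(times=event_times, survival=np.array([]), at_risk=np.array([]))
    survival = fitter.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return KMCurve(times=event_times, survival=survival, at_risk=at_risk)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square with 1 df, p-value).

    Symmetric in group order; with no events in either group the curves
    are trivially equal and (0, 1) is returned with a warning.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if times_a.size == 0 or times_b.size == 0:
        raise DataValidationError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        logger.warning("no events in either group; log-rank p set to 1")
        return 0.0, 1.0
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def prognostic_screen(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    gene_ids,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Median-split log-rank screen over candidate genes.

    Samples are matched by id between the expression matrix and the
    clinical table; genes that cannot be tested (absent from the matrix,
    degenerate split) get a row with an explicit skip reason instead of
    being silently dropped.  Results are invariant to sample ordering.
    """
    shared = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if not shared:
        raise DataValidationError("no samples shared between expression and clinical data")
    if len(shared) < 10:
        raise DataValidationError("prognostic screen needs >=10 matched samples")
    shared = sorted(shared)
    os_time = clinical.table.loc[shared, "os_time_days"].to_numpy()
    os_event = clinical.table.loc[shared, "os_event"].to_numpy()

    rows = []
    for gene in gene_ids:
        if gene not in expr.data.index:
            rows.append(_skip_row(gene, "not in expression matrix"))
            continue
        values = expr.data.loc[gene, shared]
        if values.isna().any():
            rows.append(_skip_row(gene, "missing expression values"))
            continue
        try:
            groups = median_split(values)
        except DataValidationError as err:
            rows.append(_skip_row(gene, str(err)))
            continue
        high = groups == "high"
        chi2, p = logrank_test(
            os_time[high.to_numpy()], os_event[high.to_numpy()],
            os_time[~high.to_numpy()], os_event[~high.to_numpy()],
        )
        rows.append(
            {
                "gene_id": gene,
                "n_high": int(high.sum()),
                "n_low": int((~high).sum()),
                "chi_square": chi2,
                "p_value": p,
                "significant": bool(p < p_threshold),
                "skip_reason": "",
            }
        )
    result = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    n_sig = result["significant"].fillna(False).sum()
    logger.info("prognostic screen: %d/%d genes significant at p<%g", n_sig, len(result), p_threshold)
    return result


def _skip_row(gene: str, reason: str) -> dict:
    return {
        "gene_id": gene, "n_high": 0, "n_low": 0,
        "chi_square": np.nan, "p_value": np.nan,
        "significant": False, "skip_reason": reason,
    }


def write_screen_tsv(screen: pd.DataFrame, path) -> None:
    screen.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_km_curve_tsv(curve: KMCurve, path) -> None:
    pd.DataFrame(
        {"time": curve.times, "survival": curve.survival, "at_risk": curve.at_risk}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
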
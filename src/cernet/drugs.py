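"""Spearman drug-sensitivity association screen across cell lines.

Each gene's expression is correlated with each drug's IC50 across the
shared cell lines (pairwise-complete).  A negative rho means higher
expression goes with a lower IC50, i.e. the gene sensitizes to the
drug; BH FDR < 0.05 across the whole screen flags significant pairs.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DataValidationError, DrugResponseMatrix, ExpressionMatrix
from .de import bh_adjust

logger = logging.getLogger(__name__)

#: sample sizes up to which the exact permutation p-value is computed
EXACT_PERMUTATION_MAX_N = 10

ASSOC_COLUMNS = [
    "gene_id", "drug_id", "n", "rho", "p_value", "fdr", "direction", "flagged", "note",
]


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided exact p for Spearman rho by full permutation enumeration.

    For fixed rank vectors, rho (Pearson correlation of ranks, so valid
    under average-rank ties) is an increasing function of sum(rx * ry_perm);
    the tail is therefore counted on that cross-sum.  Enumerates all n!
    permutations in chunks.
    """
    n = len(rx)
    mean = (n + 1) / 2.0
    cx = rx - mean
    cy = ry - mean
    observed = float(cx @ cy)
    denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
    count = 0
    total = 0
    chunk_size = 40320  # 8!
    perm_iter = itertools.permutations(cy)
    while True:
        chunk = np.array(list(itertools.islice(perm_iter, chunk_size)))
        if chunk.size == 0:
            break
        sums = chunk @ cx
        count += int((np.abs(sums) >= abs(observed) - 1e-12 * denom).sum())
        total += len(chunk)
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    Returns (rho, p).  p is the exact permutation p-value for n <= 10
    and the t-approximation otherwise.  A constant input vector makes
    rho undefined: (nan, nan) is returned as the degenerate marker.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError("x and y must be equal-length vectors")
    complete = ~(np.isnan(x) | np.isnan(y))
    x, y = x[complete], y[complete]
    n = len(x)
    if n < 3:
        raise DataValidationError("spearman needs >=3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry)
    else:
        # t approximation: t = rho * sqrt((n-2) / (1-rho^2)), df = n-2
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, p


def drug_gene_screen(
    expr_cell_lines: ExpressionMatrix,
    drugs: DrugResponseMatrix,
    gene_ids=None,
    fdr_threshold: float = 0.05,
    fdr_scope: str = "global",
) -> pd.DataFrame:
    """Correlate every gene with every drug IC50 across shared cell lines.

    Pairwise-complete over missing IC50s; pairs with fewer than 3 complete
    observations or a degenerate (constant) vector are excluded from BH
    and carry an explanatory note.  ``fdr_scope`` is ``global`` (one BH
    family over the whole screen, the default) or ``per_gene``.
    """
    if fdr_scope not in ("global", "per_gene"):
        raise DataValidationError("fdr_scope must be 'global' or 'per_gene'")
    shared = [s for s in expr_cell_lines.sample_ids if s in set(drugs.cell_line_ids)]
    if not shared:
        raise DataValidationError("no cell lines shared between expression and IC50 data")
    if gene_ids is None:
        gene_ids = expr_cell_lines.feature_ids
    rows = []
    for gene in gene_ids:
        if gene not in expr_cell_lines.data.index:
            continue
        gx = expr_cell_lines.data.loc[gene, shared].to_numpy(dtype=float)
        for drug in drugs.drug_ids:
            dy = drugs.ic50.loc[shared, drug].to_numpy(dtype=float)
            complete = ~(np.isnan(gx) | np.isnan(dy))
            n = int(complete.sum())
            if n < 3:
                rows.append(_assoc_row(gene, drug, n, note="fewer than 3 complete pairs"))
                continue
            rho, p = spearman(gx[complete], dy[complete])
            if math.isnan(rho):
                rows.append(_assoc_row(gene, drug, n, note="degenerate: constant values"))
                continue
            rows.append(_assoc_row(gene, drug, n, rho=rho, p=p))
    result = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    testable = result["p_value"].notna()
    result["fdr"] = np.nan
    if testable.any():
        if fdr_scope == "global":
            result.loc[testable, "fdr"] = bh_adjust(result.loc[testable, "p_value"])
        else:
            for _, sub in result[testable].groupby("gene_id"):
                result.loc[sub.index, "fdr"] = bh_adjust(sub["p_value"])
    result["flagged"] = result["fdr"] < fdr_threshold
    n_flagged = int(result["flagged"].sum())
    logger.info(
        "drug screen: %d pairs tested, %d flagged at FDR<%g",
        int(testable.sum()), n_flagged, fdr_threshold,
    )
    return result


def _assoc_row(gene, drug, n, rho=math.nan, p=math.nan, note="") -> dict:
    if math.isnan(rho):
        direction = ""
    else:
        direction = "sensitizing" if rho < 0 else "resistant"
    return {
        "gene_id": gene, "drug_id": drug, "n": n,
        "rho": rho, "p_value": p, "fdr": math.nan,
        "direction": direction, "flagged": False, "note": note,
    }


def associations_per_gene(screen: pd.DataFrame) -> pd.Series:
    """Number of BH-flagged drug associations per gene."""
    flagged = screen[screen["flagged"]]
    counts = flagged.groupby("gene_id").size()
    return counts.reindex(sorted(screen["gene_id"].unique()), fill_value=0)


def write_assoc_tsv(screen: pd.DataFrame, path) -> None:
    screen.to_csv(path, sep="\t", index=False, float_format="%.6g")
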
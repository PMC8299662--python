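"""Over-representation analysis of gene lists against GO/KEGG-style sets.

For a query of q genes drawn from a universe of N genes, a set with K
members in the universe and k genes shared with the query is scored with
the hypergeometric upper tail P(X >= k); BH adjustment is applied across
all sets tested within one collection.
"""

from __future__ import annotations

import logging

import pandas as pd

from .data_io import DataValidationError, GeneSetCollection
from .de import bh_adjust, hypergeom_upper_tail

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "set_name", "n_query", "n_set", "n_overlap", "n_universe",
    "p_value", "adj_p", "overlap_genes",
]


def hypergeometric_enrichment(
    query_genes, gene_sets: GeneSetCollection, universe_genes
) -> pd.DataFrame:
    """Score every gene set; results sorted by p then set name.

    Query genes outside the universe are dropped with a warning; each set
    is intersected with the universe first, and sets with no universe
    members are skipped.
    """
    universe = {g.upper() for g in universe_genes}
    if not universe:
        raise DataValidationError("empty universe")
    query = {g.upper() for g in query_genes}
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
        query &= universe
    if not query:
        raise DataValidationError("empty query after universe filtering")

    rows = []
    for name, members in gene_sets.sets.items():
        in_universe = members & universe
        if not in_universe:
            continue
        overlap = sorted(query & in_universe)
        p = hypergeom_upper_tail(len(overlap), len(in_universe), len(query), len(universe))
        rows.append(
            {
                "set_name": name,
                "n_query": len(query),
                "n_set": len(in_universe),
                "n_overlap": len(overlap),
                "n_universe": len(universe),
                "p_value": p,
                "overlap_genes": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    result = pd.DataFrame(rows)
    result["adj_p"] = bh_adjust(result["p_value"])
    result = result.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    return result[ENRICHMENT_COLUMNS]


def top_terms(results: pd.DataFrame, k: int, p_threshold: float = 0.05) -> pd.DataFrame:
    """First k results with p strictly below the threshold (input kept sorted)."""
    significant = results[results["p_value"] < p_threshold]
    return significant.head(k).reset_index(drop=True)


def write_enrichment_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
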
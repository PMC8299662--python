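"""ceRNA (circRNA-miRNA-mRNA) network assembly under direction constraints.

A circRNA acting as a miRNA sponge de-represses the miRNA's mRNA
targets, so in a credible ceRNA triplet the circRNA and mRNA move in the
same direction between tumor and normal while the miRNA moves in the
opposite direction.  The default ``sign_rule`` mode enforces exactly
that on differential-expression calls; ``correlation`` mode instead
thresholds Spearman correlations when both partners are measured on the
same samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DataValidationError, ExpressionMatrix, InteractionTable

logger = logging.getLogger(__name__)


class CeRNATriplet(NamedTuple):
    circ_id: str
    mirna_id: str
    gene_id: str
    circ_direction: str
    mirna_direction: str
    gene_direction: str


def satisfies_sign_rule(circ_dir: str, mirna_dir: str, gene_dir: str) -> bool:
    """circRNA and mRNA concordant, miRNA opposite, all differentially expressed."""
    if "none" in (circ_dir, mirna_dir, gene_dir):
        return False
    return gene_dir == circ_dir and gene_dir != mirna_dir


@dataclass(frozen=True)
class CeRNANetwork:
    """Canonically ordered set of ceRNA triplets with derived summaries."""

    triplets: tuple[CeRNATriplet, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "triplets", tuple(sorted(set(self.triplets))))
        for t in self.triplets:
            if not satisfies_sign_rule(t.circ_direction, t.mirna_direction, t.gene_direction):
                raise DataValidationError(f"triplet {t} violates the sign rule")

    @property
    def circ_ids(self) -> set[str]:
        return {t.circ_id for t in self.triplets}

    @property
    def mirna_ids(self) -> set[str]:
        return {t.mirna_id for t in self.triplets}

    @property
    def gene_ids(self) -> set[str]:
        return {t.gene_id for t in self.triplets}

    def genes_per_circ(self) -> dict[str, int]:
        counts: dict[str, set[str]] = {}
        for t in self.triplets:
            counts.setdefault(t.circ_id, set()).add(t.gene_id)
        return {c: len(g) for c, g in sorted(counts.items())}

    def __len__(self) -> int:
        return len(self.triplets)


def _direction_map(de: pd.DataFrame) -> dict[str, str]:
    sig = de[de["direction"] != "none"]
    return dict(zip(sig["feature_id"], sig["direction"]))


def build_cerna_network(
    de_circ: pd.DataFrame,
    de_mirna: pd.DataFrame,
    de_gene: pd.DataFrame,
    mc_pairs: InteractionTable,
    mg_pairs: InteractionTable,
    mode: str = "sign_rule",
    correlation_inputs: dict | None = None,
) -> CeRNANetwork:
    """Join DE calls with interaction tables into sign-consistent triplets.

    Returns exactly the triplets (c, m, g) such that all three members are
    significant DE features of the right kind, (m, c) and (m, g) are known
    interactions, and the direction sign rule holds.  ``mode='correlation'``
    additionally requires ``correlation_inputs`` (see
    :func:`correlation_filter`) with same-cohort expression for both pair
    kinds and replaces the interaction tables by their correlation-filtered
    versions before the join.
    """
    if mc_pairs.kind != "miRNA_circRNA" or mg_pairs.kind != "miRNA_mRNA":
        raise DataValidationError("interaction tables of mismatched kinds")
    if mode not in ("sign_rule", "correlation"):
        raise DataValidationError(f"unknown network mode {mode!r}")
    if mode == "correlation":
        if not correlation_inputs:
            raise DataValidationError(
                "mode='correlation' needs same-cohort expression matrices "
                "(keys: circ_expr, mirna_expr, gene_expr, rho_threshold)"
            )
        rho = correlation_inputs.get("rho_threshold", 0.3)
        mc_pairs = correlation_filter(
            correlation_inputs["mirna_expr"], correlation_inputs["circ_expr"],
            mc_pairs, rho_threshold=rho, sign="negative",
        )
        mg_pairs = correlation_filter(
            correlation_inputs["mirna_expr"], correlation_inputs["gene_expr"],
            mg_pairs, rho_threshold=rho, sign="negative",
        )

    circ_dir = _direction_map(de_circ)
    mirna_dir = _direction_map(de_mirna)
    gene_dir = _direction_map(de_gene)

    circ_by_mirna: dict[str, list[str]] = {}
    for m, c in mc_pairs.pairs:
        if m in mirna_dir and c in circ_dir:
            circ_by_mirna.setdefault(m, []).append(c)
    gene_by_mirna: dict[str, list[str]] = {}
    for m, g in mg_pairs.pairs:
        if m in mirna_dir and g in gene_dir:
            gene_by_mirna.setdefault(m, []).append(g)

    triplets = []
    for m in set(circ_by_mirna) & set(gene_by_mirna):
        for c in circ_by_mirna[m]:
            for g in gene_by_mirna[m]:
                if satisfies_sign_rule(circ_dir[c], mirna_dir[m], gene_dir[g]):
                    triplets.append(
                        CeRNATriplet(c, m, g, circ_dir[c], mirna_dir[m], gene_dir[g])
                    )
    net = CeRNANetwork(triplets=tuple(triplets))
    logger.info(
        "ceRNA network: %d triplets, %d circRNAs, %d miRNAs, %d genes",
        len(net), len(net.circ_ids), len(net.mirna_ids), len(net.gene_ids),
    )
    return net


def correlation_filter(
    expr_x: ExpressionMatrix,
    expr_y: ExpressionMatrix,
    pairs: InteractionTable,
    rho_threshold: float,
    sign: str,
) -> InteractionTable:
    """Retain pairs whose Spearman rho has the required sign and magnitude.

    ``expr_x`` holds the miRNAs (first pair member), ``expr_y`` the
    partners; both must share at least 5 sample ids.  Pairs with an
    undefined rho (constant expression) are dropped with a warning.
    """
    if sign not in ("negative", "positive"):
        raise DataValidationError("sign must be 'negative' or 'positive'")
    shared = [s for s in expr_x.sample_ids if s in set(expr_y.sample_ids)]
    if len(shared) < 5:
        raise DataValidationError("correlation filter needs >=5 shared samples")
    kept = []
    for m, p in sorted(pairs.pairs):
        if m not in expr_x.data.index or p not in expr_y.data.index:
            continue
        x = expr_x.data.loc[m, shared].to_numpy(dtype=float)
        y = expr_y.data.loc[p, shared].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("pair (%s, %s) dropped: constant expression", m, p)
            continue
        rho = stats.spearmanr(x, y).statistic
        if sign == "negative" and rho <= -rho_threshold:
            kept.append((m, p))
        elif sign == "positive" and rho >= rho_threshold:
            kept.append((m, p))
    return InteractionTable(kind=pairs.kind, pairs=frozenset(kept))


def network_summary(net: CeRNANetwork, de_counts: dict[str, int]) -> pd.DataFrame:
    """Absolute and percentage composition per RNA kind (2-dp percentages)."""
    rows = []
    for kind, members in (
        ("circRNA", net.circ_ids),
        ("miRNA", net.mirna_ids),
        ("mRNA", net.gene_ids),
    ):
        total = de_counts.get(kind, 0)
        if total <= 0:
            raise DataValidationError(f"de_counts for {kind} must be positive")
        rows.append(
            {
                "kind": kind,
                "n_network": len(members),
                "n_de": total,
                "percent": round(100.0 * len(members) / total, 2),
            }
        )
    return pd.DataFrame(rows)


def subnetwork_by_circ(net: CeRNANetwork, circ_id: str) -> CeRNANetwork:
    """Triplets of one circRNA (empty network with a warning if absent)."""
    if circ_id not in net.circ_ids:
        logger.warning("circRNA %s not in network; returning empty subnetwork", circ_id)
    return CeRNANetwork(
        triplets=tuple(t for t in net.triplets if t.circ_id == circ_id)
    )


def host_gene_overlap(host_genes, de_genes: pd.DataFrame) -> tuple[int, float]:
    """How many circRNA host genes are themselves differentially expressed.

    Returns the intersection size and its percentage of the DEG total
    (2-dp).  A small percentage indicates circRNA dysregulation is not
    mediated by host-gene transcription in cis.
    """
    degs = set(de_genes.loc[de_genes["direction"] != "none", "feature_id"])
    n = len(set(host_genes) & degs)
    pct = round(100.0 * n / len(degs), 2) if degs else 0.0
    return n, pct


def write_network_tsv(net: CeRNANetwork, path) -> None:
    pd.DataFrame(net.triplets, columns=CeRNATriplet._fields).to_csv(path, sep="\t", index=False)


def read_network_tsv(path) -> CeRNANetwork:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return CeRNANetwork(
        triplets=tuple(CeRNATriplet(*row) for row in table[list(CeRNATriplet._fields)].itertuples(index=False))
    )


def write_sankey_flows(net: CeRNANetwork, path) -> None:
    """Three-column circ -> miRNA -> gene flow file for alluvial plotting."""
    pd.DataFrame(
        [(t.circ_id, t.mirna_id, t.gene_id) for t in net.triplets],
        columns=["circ_id", "mirna_id", "gene_id"],
    ).to_csv(path, sep="\t", index=False)
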
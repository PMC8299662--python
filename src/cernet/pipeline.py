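"""End-to-end orchestration: DE -> overlap -> network -> enrichment ->
survival -> drug screen, from one validated YAML config.

Stage outputs are plain TSVs under the configured output directory and
a run report (JSON + text) records every decision knob actually used.
Reruns on identical inputs are byte-identical: the analysis stages are
fully deterministic and the report carries no timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, data_io, de, drugs, enrichment, network, survival

logger = logging.getLogger(__name__)


class PipelineValidationError(ValueError):
    """Configuration problem detected before any stage runs."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see docs/methods.md for the schema)."""

    inputs: dict[str, dict[str, str] | str]
    output_dir: str
    thresholds: de.ThresholdConfig = field(default_factory=de.ThresholdConfig)
    network_mode: str = "sign_rule"
    enrichment_p_threshold: float = 0.05
    enrichment_top_k: int = 10
    survival_p_threshold: float = 0.05
    drug_fdr_threshold: float = 0.05
    drug_fdr_scope: str = "global"
    drug_gene_source: str = "prognostic"  # prognostic | network | all
    collapse_policy: str = "max_mean"
    seed: int = 0

    REQUIRED_INPUTS = (
        "circ_a", "circ_b", "mirna", "mrna", "cell_lines",
        "mirna_circ_pairs", "mirna_gene_pairs", "clinical", "drug_ic50", "gene_sets",
    )

    def validate(self) -> None:
        missing = [k for k in self.REQUIRED_INPUTS if k not in self.inputs]
        if missing:
            raise PipelineValidationError(f"missing inputs: {missing}")
        for key, entry in self.inputs.items():
            paths = entry.values() if isinstance(entry, dict) else [entry]
            for p in paths:
                if not Path(p).exists():
                    raise PipelineValidationError(f"input {key}: path {p} does not exist")
        for name, value in (
            ("enrichment_p_threshold", self.enrichment_p_threshold),
            ("survival_p_threshold", self.survival_p_threshold),
            ("drug_fdr_threshold", self.drug_fdr_threshold),
        ):
            if not 0 < value < 1:
                raise PipelineValidationError(f"{name} must lie strictly in (0, 1)")
        if self.network_mode not in ("sign_rule", "correlation"):
            raise PipelineValidationError(f"unknown network mode {self.network_mode!r}")
        if self.drug_gene_source not in ("prognostic", "network", "all"):
            raise PipelineValidationError(f"unknown drug_gene_source {self.drug_gene_source!r}")
        if self.collapse_policy not in data_io.COLLAPSE_POLICIES:
            raise PipelineValidationError(f"unknown collapse policy {self.collapse_policy!r}")


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "inputs" not in raw or "output_dir" not in raw:
        raise PipelineValidationError(f"{path}: config needs 'inputs' and 'output_dir'")
    thresholds = raw.get("thresholds", {})
    try:
        tc = de.ThresholdConfig(**thresholds)
    except (TypeError, ValueError) as err:
        raise PipelineValidationError(f"{path}: bad thresholds: {err}") from err
    known = {
        k: raw[k]
        for k in (
            "network_mode", "enrichment_p_threshold", "enrichment_top_k",
            "survival_p_threshold", "drug_fdr_threshold", "drug_fdr_scope",
            "drug_gene_source", "collapse_policy", "seed",
        )
        if k in raw
    }
    config = PipelineConfig(
        inputs=raw["inputs"], output_dir=raw["output_dir"], thresholds=tc, **known
    )
    config.validate()
    return config


def _read_cohort(entry: dict, kind: str, collapse: str) -> data_io.ExpressionMatrix:
    group_map = pair_map = None
    if "samples" in entry:
        group_map, pair_map = data_io.read_sample_sheet(entry["samples"])
    return data_io.read_expression_table(
        entry["expression"], kind, group_map=group_map, pair_map=pair_map, collapse=collapse
    )


def _resolve_method(matrix: data_io.ExpressionMatrix, config: de.ThresholdConfig) -> de.ThresholdConfig:
    """Paired t when complete pairing is available, otherwise the configured test."""
    if matrix.pair_ids is not None and not matrix.pair_ids.isna().any():
        return de.ThresholdConfig(
            p_threshold=config.p_threshold, fc_threshold=config.fc_threshold,
            use_adjusted_p=config.use_adjusted_p, de_method="paired_t",
            max_missing_fraction=config.max_missing_fraction,
        )
    return config


def consensus_circ_calls(de_a: pd.DataFrame, de_b: pd.DataFrame) -> pd.DataFrame:
    """DE circRNAs called in both cohorts with concordant direction.

    Statistics (log2fc, p) are taken from the first cohort; the
    concordance requirement mirrors screening a circRNA in a discovery
    and a confirmation cohort.
    """
    sig_a = de.significant_features(de_a).set_index("feature_id")
    sig_b = de.significant_features(de_b).set_index("feature_id")
    shared = [
        f for f in sig_a.index
        if f in sig_b.index and sig_a.loc[f, "direction"] == sig_b.loc[f, "direction"]
    ]
    out = sig_a.loc[shared].reset_index()
    return out[de.DE_COLUMNS]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written to disk)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "thresholds": {
            "p_threshold": config.thresholds.p_threshold,
            "fc_threshold": config.thresholds.fc_threshold,
            "use_adjusted_p": config.thresholds.use_adjusted_p,
            "de_method": config.thresholds.de_method,
            "collapse_policy": config.collapse_policy,
            "network_mode": config.network_mode,
            "survival_p_threshold": config.survival_p_threshold,
            "drug_fdr_threshold": config.drug_fdr_threshold,
            "drug_fdr_scope": config.drug_fdr_scope,
            "median_split_ties": "low",
        },
        "stages": {},
    }

    def _stage(name):
        logger.info("stage: %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    try:
        # ---- differential expression ---------------------------------
        info = _stage("differential_expression")
        cohorts = {
            "circ_a": ("circRNA", config.inputs["circ_a"]),
            "circ_b": ("circRNA", config.inputs["circ_b"]),
            "mirna": ("miRNA", config.inputs["mirna"]),
            "mrna": ("mRNA", config.inputs["mrna"]),
        }
        de_tables: dict[str, pd.DataFrame] = {}
        matrices: dict[str, data_io.ExpressionMatrix] = {}
        for name, (kind, entry) in cohorts.items():
            matrix = _read_cohort(entry, kind, config.collapse_policy)
            matrices[name] = matrix
            result = de.differential_expression(
                matrix, _resolve_method(matrix, config.thresholds), dataset_id=name
            )
            de.write_de_table(result, outdir / f"de_{name}.tsv")
            de_tables[name] = result
            sig = de.significant_features(result)
            info[name] = {
                "n_features": len(result),
                "n_de": len(sig),
                "n_up": int((sig["direction"] == "up").sum()),
                "n_down": int((sig["direction"] == "down").sum()),
            }

        # ---- circRNA overlap across the two cohorts ------------------
        info = _stage("overlap")
        universe = sorted(
            set(de_tables["circ_a"]["feature_id"]) & set(de_tables["circ_b"]["feature_id"])
        )
        list_a = [f for f in de.significant_features(de_tables["circ_a"])["feature_id"] if f in set(universe)]
        list_b = [f for f in de.significant_features(de_tables["circ_b"])["feature_id"] if f in set(universe)]
        overlap = de.overlap_significance(list_a, list_b, universe)
        consensus = consensus_circ_calls(de_tables["circ_a"], de_tables["circ_b"])
        de.write_de_table(consensus, outdir / "de_circ_consensus.tsv")
        info.update(
            n_universe=overlap.n_universe, n_overlap=overlap.n_overlap,
            odds_ratio=overlap.odds_ratio, p_value=overlap.p_value,
            n_consensus_circ=len(consensus),
        )

        # ---- ceRNA network -------------------------------------------
        info = _stage("network")
        mc = data_io.read_interaction_table(config.inputs["mirna_circ_pairs"], "miRNA_circRNA")
        mg = data_io.read_interaction_table(config.inputs["mirna_gene_pairs"], "miRNA_mRNA")
        net = network.build_cerna_network(
            consensus, de_tables["mirna"], de_tables["mrna"], mc, mg, mode=config.network_mode
        )
        network.write_network_tsv(net, outdir / "cerna_network.tsv")
        network.write_sankey_flows(net, outdir / "cerna_sankey.tsv")
        de_counts = {
            "circRNA": max(len(consensus), 1),
            "miRNA": max(info_de_count(de_tables["mirna"]), 1),
            "mRNA": max(info_de_count(de_tables["mrna"]), 1),
        }
        summary = network.network_summary(net, de_counts) if len(net) else None
        if summary is not None:
            summary.to_csv(outdir / "network_summary.tsv", sep="\t", index=False)
        genes_per_circ = net.genes_per_circ()
        info.update(
            n_triplets=len(net), n_circ=len(net.circ_ids), n_mirna=len(net.mirna_ids),
            n_genes=len(net.gene_ids), genes_per_circ=genes_per_circ,
            triplets=[list(t) for t in net.triplets],
        )
        top_circ = max(genes_per_circ, key=lambda c: (genes_per_circ[c], c)) if genes_per_circ else None
        info["top_circ"] = top_circ

        # ---- enrichment ----------------------------------------------
        info = _stage("enrichment")
        if top_circ is not None:
            sub = network.subnetwork_by_circ(net, top_circ)
            gene_sets = data_io.read_gene_sets_gmt(config.inputs["gene_sets"])
            universe_genes = matrices["mrna"].feature_ids
            enrich = enrichment.hypergeometric_enrichment(sub.gene_ids, gene_sets, universe_genes)
            enrichment.write_enrichment_tsv(enrich, outdir / "enrichment.tsv")
            top = enrichment.top_terms(enrich, config.enrichment_top_k, config.enrichment_p_threshold)
            info.update(
                query_circ=top_circ, n_query=len(sub.gene_ids), n_sets=len(enrich),
                n_significant=int((enrich["p_value"] < config.enrichment_p_threshold).sum()),
                top_terms=list(top["set_name"]),
            )
        else:
            info["skipped"] = "empty network"

        # ---- survival screen -----------------------------------------
        info = _stage("survival")
        clinical = data_io.read_clinical_table(config.inputs["clinical"])
        screen_genes = sorted(net.gene_ids)
        if screen_genes:
            screen = survival.prognostic_screen(
                matrices["mrna"], clinical, screen_genes, p_threshold=config.survival_p_threshold
            )
            survival.write_screen_tsv(screen, outdir / "survival_screen.tsv")
            prognostic = sorted(screen.loc[screen["significant"], "gene_id"])
            info.update(
                n_screened=len(screen), n_significant=len(prognostic),
                significant_genes=prognostic,
            )
        else:
            prognostic = []
            info["skipped"] = "empty network"

        # ---- drug association screen ---------------------------------
        info = _stage("drug_screen")
        cell_expr = _read_cohort(config.inputs["cell_lines"], "mRNA", config.collapse_policy)
        ic50 = data_io.read_drug_matrix(config.inputs["drug_ic50"])
        if config.drug_gene_source == "prognostic":
            drug_genes = prognostic
        elif config.drug_gene_source == "network":
            drug_genes = sorted(net.gene_ids)
        else:
            drug_genes = cell_expr.feature_ids
        if drug_genes:
            screen = drugs.drug_gene_screen(
                cell_expr, ic50, drug_genes,
                fdr_threshold=config.drug_fdr_threshold, fdr_scope=config.drug_fdr_scope,
            )
            drugs.write_assoc_tsv(screen, outdir / "drug_associations.tsv")
            per_gene = drugs.associations_per_gene(screen)
            info.update(
                n_pairs_tested=int(screen["p_value"].notna().sum()),
                n_flagged=int(screen["flagged"].sum()),
                associations_per_gene={g: int(c) for g, c in per_gene.items() if c > 0},
            )
        else:
            info["skipped"] = "no genes to screen"
    except (data_io.DataValidationError, de.DataValidationError) as err:
        failed = list(report["stages"])[-1] if report["stages"] else "setup"
        report["failed_stage"] = failed
        report["error"] = str(err)
        _write_report(report, outdir)
        raise

    _write_report(report, outdir)
    return report


def info_de_count(de_table: pd.DataFrame) -> int:
    return len(de.significant_features(de_table))


def _write_report(report: dict, outdir: Path) -> None:
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    lines = [f"cernet pipeline report (version {report['version']})", ""]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}]")
        for key, value in info.items():
            lines.append(f"  {key}: {value}")
        lines.append("")
    if "error" in report:
        lines.append(f"FAILED at stage {report['failed_stage']}: {report['error']}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
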
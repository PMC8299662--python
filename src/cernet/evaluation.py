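"""Operating-characteristic studies of the pipeline on synthetic data.

Each study regenerates synthetic inputs with planted truth across a set
of seeds, runs the corresponding pipeline stage, and scores the result
against the generator's manifest: DE sensitivity and false-positive
rate, exact ceRNA-network recovery, prognostic-screen hit rate and null
type-I error, and the drug screen's null flag fraction and planted-sign
recovery.  The study conditions (effect sizes, cohort shapes, hazard
ratios) are the generator defaults unless a study states otherwise.
"""

from __future__ import annotations

import numpy as np

from . import de, drugs, network, simulate, survival


def de_operating_characteristics(
    seeds, cohort: str = "circ_b", kind: str = "circRNA"
) -> tuple[float, float]:
    """Mean DE sensitivity and false-positive rate over seeds.

    Runs the paired t-test path on the 5-pair circRNA cohort (planted
    |log2 shift| and noise sd are the generator defaults: 2.0 and 0.5)
    and scores calls against the planted truth.
    """
    sens, fpr = [], []
    config_t = de.ThresholdConfig(de_method="paired_t")
    for seed in seeds:
        cfg = simulate.SyntheticConfig(seed=int(seed))
        matrices, manifest = simulate.generate_expression(cfg)
        result = de.differential_expression(matrices[cohort], config_t).set_index("feature_id")
        truth = manifest.de_features[kind]
        called = set(result.index[result["direction"] != "none"])
        planted = set(truth)
        correct = {f for f in called & planted if result.loc[f, "direction"] == truth[f]}
        sens.append(len(correct) / len(planted))
        nulls = set(result.index) - planted
        fpr.append(len(called & nulls) / len(nulls))
    return float(np.mean(sens)), float(np.mean(fpr))


def network_recovery(seeds) -> tuple[float, int]:
    """(mean planted-triplet recovery fraction, total decoys admitted).

    DE calls are injected directly from the manifest (perfect calls), so
    any miss or decoy admission is a defect of the join itself.
    """
    import pandas as pd

    def _as_de(truth: dict[str, str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": list(truth),
                "log2fc": [2.0 if d == "up" else -2.0 for d in truth.values()],
                "p_value": 1e-6, "adj_p": 1e-5,
                "direction": list(truth.values()), "dataset_id": "injected",
            }
        )

    recovery, decoys_admitted = [], 0
    for seed in seeds:
        cfg = simulate.SyntheticConfig(seed=int(seed))
        _, manifest = simulate.generate_expression(cfg)
        mc, mg = simulate.generate_interactions(cfg, manifest)
        truth = manifest.de_features
        net = network.build_cerna_network(
            _as_de(truth["circRNA"]), _as_de(truth["miRNA"]), _as_de(truth["mRNA"]), mc, mg
        )
        got = set(net.triplets)
        planted = set(manifest.planted_triplets)
        recovery.append(len(got & planted) / len(planted))
        admitted = {(t.circ_id, t.mirna_id, t.gene_id) for t in net.triplets}
        decoys_admitted += sum(
            (d["circ"], d["mirna"], d["gene"]) in admitted
            for d in manifest.decoy_candidates
        )
        # nothing beyond the planted triplets should appear at all
        decoys_admitted += len(got - planted)
    return float(np.mean(recovery)), int(decoys_admitted)


def prognostic_screen_study(seeds, n_tumor: int = 400) -> tuple[int, float]:
    """(seeds where the planted HR=3 gene is flagged, mean null flag rate).

    One planted prognostic gene among 20 designated nulls, n_tumor
    clinical samples with ~40% observed events (generator defaults).
    """
    hits, null_rates = 0, []
    for seed in seeds:
        cfg = simulate.SyntheticConfig(seed=int(seed), n_tumor_seq=n_tumor)
        matrices, manifest = simulate.generate_expression(cfg)
        simulate.generate_interactions(cfg, manifest)
        clinical = simulate.generate_clinical(cfg, manifest, matrices["mrna_seq"])
        planted = list(manifest.prognostic_genes)
        nulls = manifest.null_prognostic_genes
        screen = survival.prognostic_screen(
            matrices["mrna_seq"], clinical, planted + nulls
        ).set_index("gene_id")
        hits += bool(screen.loc[planted[0], "significant"])
        null_rates.append(float(screen.loc[nulls, "significant"].mean()))
    return int(hits), float(np.mean(null_rates))


def logrank_null_type1(n_sims: int, seed: int, n_per_group: int = 50, alpha: float = 0.05) -> float:
    """Empirical type-I error of the log-rank test under one exponential null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        ta = rng.exponential(10.0, size=n_per_group)
        tb = rng.exponential(10.0, size=n_per_group)
        ones = np.ones(n_per_group, dtype=int)
        _, p = survival.logrank_test(ta, ones, tb, ones)
        rejections += p < alpha
    return rejections / n_sims


def _drug_config(seed: int, planted: int) -> simulate.SyntheticConfig:
    # 50 genes x 20 drugs over 30 cell lines; small cohorts elsewhere since
    # only the cell-line panel feeds this study
    return simulate.SyntheticConfig(
        seed=seed, n_mrna=50, n_mirna=20, n_circ=20, n_tumor_seq=20, n_normal_seq=10,
        n_cell_lines=30, n_drugs=20, n_planted_drug_pairs=planted,
        drug_missing_rate=0.0,
    )


def drug_null_flag_fraction(seeds, fdr_threshold: float = 0.05) -> float:
    """Mean fraction of gene-drug pairs BH-flagged under the global null."""
    fractions = []
    for seed in seeds:
        cfg = _drug_config(int(seed), planted=0)
        matrices, manifest = simulate.generate_expression(cfg)
        ic50 = simulate.generate_drug_response(cfg, manifest, matrices["cell_lines"])
        screen = drugs.drug_gene_screen(
            matrices["cell_lines"], ic50, fdr_threshold=fdr_threshold
        )
        tested = screen["p_value"].notna()
        fractions.append(float(screen.loc[tested, "flagged"].mean()))
    return float(np.mean(fractions))


def drug_sign_recovery(seeds) -> float:
    """Fraction of planted gene-drug pairs recovered with the planted rho sign."""
    correct = total = 0
    for seed in seeds:
        cfg = _drug_config(int(seed), planted=2)
        matrices, manifest = simulate.generate_expression(cfg)
        ic50 = simulate.generate_drug_response(cfg, manifest, matrices["cell_lines"])
        expr = matrices["cell_lines"]
        for pair in manifest.drug_pairs:
            rho, _ = drugs.spearman(
                expr.data.loc[pair["gene"]].to_numpy(),
                ic50.ic50.loc[expr.sample_ids, pair["drug"]].to_numpy(),
            )
            correct += np.sign(rho) == pair["slope_sign"]
            total += 1
    return correct / total
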
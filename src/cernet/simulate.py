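"""Synthetic pipeline inputs with known planted structure.

Emulates the full study design: two small paired circRNA microarray
cohorts plus a paired mRNA array cohort, large unpaired miRNA/mRNA
sequencing cohorts (45 normal / 450 tumor), ENCORI-style interaction
pair tables, GMT gene sets, an overall-survival clinical table and a
GDSC-style cell-line IC50 matrix.  Every planted effect (DE features
and directions, sign-rule-consistent ceRNA triplets, per-condition
decoy pairs, prognostic genes with their hazard ratios, drug-gene
correlations) is recorded in a :class:`GroundTruthManifest`, which is
the oracle the tests and acceptance checks compare against.

All randomness flows through named substreams of one seed, so adding a
generator does not perturb the output of the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .data_io import (
    ClinicalTable,
    DataValidationError,
    DrugResponseMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionTable,
)
from .network import CeRNATriplet, satisfies_sign_rule

logger = logging.getLogger(__name__)

#: fixed substream codes — append-only so streams stay stable
_STREAMS = {
    "plant_circ": 1, "plant_mirna": 2, "plant_mrna": 3,
    "circ_a": 11, "circ_b": 12, "mrna_array": 13, "mirna_seq": 14, "mrna_seq": 15,
    "cell_lines": 16, "interactions": 22, "clinical": 31,
    "drugs": 41, "gene_sets": 51,
}

DECOY_VIOLATIONS = ("mirna_not_de", "sign_rule_breach", "gene_not_de", "circ_not_de")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs; defaults mirror the emulated cohort shapes."""

    seed: int
    # cohort shapes (pairs for the array cohorts, normal/tumor for sequencing)
    n_pairs_circ_a: int = 4
    n_pairs_circ_b: int = 5
    n_pairs_mrna_array: int = 6
    n_normal_seq: int = 45
    n_tumor_seq: int = 450
    # feature space
    n_circ: int = 300
    n_mirna: int = 200
    n_mrna: int = 1000
    # planted differential expression
    de_fraction: float = 0.1
    effect_size: float = 2.0      # |log2 shift| planted in tumor
    within_sd: float = 0.5        # Gaussian noise sd on the log2 scale
    baseline_low: float = 4.0
    baseline_high: float = 12.0
    # ceRNA structure
    n_triplet_circs: int = 3
    n_planted_triplets: int = 6
    n_decoys_per_condition: int = 2
    n_background_pairs: int = 40
    # survival
    n_prognostic: int = 1
    hazard_ratio: float = 3.0
    n_null_prognostic: int = 20
    baseline_hazard: float = float(np.log(2)) / 730.0  # median OS ~ 2 years (days)
    censoring_rate: float = 0.6                 # ~40% observed events
    # drug response
    n_cell_lines: int = 30
    n_drugs: int = 20
    n_planted_drug_pairs: int = 2
    drug_effect_ratio: float = 1.0  # |slope| / noise sd
    drug_missing_rate: float = 0.05
    # gene sets
    n_gene_sets: int = 20
    gene_set_size: int = 25

    def __post_init__(self) -> None:
        counts = (
            self.n_pairs_circ_a, self.n_pairs_circ_b, self.n_pairs_mrna_array,
            self.n_normal_seq, self.n_tumor_seq, self.n_circ, self.n_mirna, self.n_mrna,
            self.n_cell_lines, self.n_drugs, self.n_gene_sets, self.gene_set_size,
        )
        if any(c <= 0 for c in counts):
            raise DataValidationError("all cohort and feature counts must be positive")
        if not np.isfinite(self.effect_size):
            raise DataValidationError("effect size must be finite")
        if self.de_fraction > 0 and self.effect_size <= 0:
            raise DataValidationError("effect size must be positive when DE is planted")
        if self.hazard_ratio <= 0:
            raise DataValidationError("hazard ratio must be positive")
        if not 0 <= self.censoring_rate <= 1:
            raise DataValidationError("censoring rate must lie in [0, 1]")


@dataclass
class GroundTruthManifest:
    """Planted effects; the acceptance oracle for every pipeline stage."""

    seed: int
    de_features: dict[str, dict[str, str]] = field(default_factory=dict)  # kind -> id -> up/down
    planted_triplets: list[CeRNATriplet] = field(default_factory=list)
    decoy_pairs: list[dict] = field(default_factory=list)
    decoy_candidates: list[dict] = field(default_factory=list)  # would-be triplets, each broken
    prognostic_genes: dict[str, float] = field(default_factory=dict)
    null_prognostic_genes: list[str] = field(default_factory=list)
    drug_pairs: list[dict] = field(default_factory=list)  # gene, drug, slope_sign
    planted_gene_set: str = ""
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["planted_triplets"] = [list(t) for t in self.planted_triplets]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text())
        payload["planted_triplets"] = [CeRNATriplet(*t) for t in payload["planted_triplets"]]
        return cls(**payload)


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces."""

    matrices: dict[str, ExpressionMatrix]
    mc_pairs: InteractionTable
    mg_pairs: InteractionTable
    clinical: ClinicalTable
    drugs: DrugResponseMatrix
    gene_sets: GeneSetCollection
    manifest: GroundTruthManifest


# ---------------------------------------------------------------------------
# feature naming
# ---------------------------------------------------------------------------


def _circ_ids(n: int) -> list[str]:
    return [f"hsa_circ_{i:07d}" for i in range(1, n + 1)]


def _mirna_ids(n: int) -> list[str]:
    return [f"hsa-miR-{i:04d}-5p" for i in range(1, n + 1)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _plant_directions(rng: np.random.Generator, ids: list[str], fraction: float) -> dict[str, str]:
    n_de = int(round(fraction * len(ids)))
    chosen = rng.choice(len(ids), size=n_de, replace=False)
    directions = {}
    for j, idx in enumerate(sorted(chosen)):
        directions[ids[idx]] = "up" if j % 2 == 0 else "down"
    return directions


def _simulate_matrix(
    rng: np.random.Generator,
    feature_ids: list[str],
    kind: str,
    dataset: str,
    directions: dict[str, str],
    config: SyntheticConfig,
    n_tumor: int,
    n_normal: int,
    paired: bool,
) -> ExpressionMatrix:
    n_feat = len(feature_ids)
    baseline = rng.uniform(config.baseline_low, config.baseline_high, size=n_feat)
    tumor = baseline[:, None] + rng.normal(0, config.within_sd, size=(n_feat, n_tumor))
    normal = baseline[:, None] + rng.normal(0, config.within_sd, size=(n_feat, n_normal))
    for i, fid in enumerate(feature_ids):
        d = directions.get(fid)
        if d == "up":
            tumor[i] += config.effect_size
        elif d == "down":
            tumor[i] -= config.effect_size
    t_ids = [f"{dataset}_T{i:03d}" for i in range(1, n_tumor + 1)]
    n_ids = [f"{dataset}_N{i:03d}" for i in range(1, n_normal + 1)]
    data = pd.DataFrame(np.hstack([tumor, normal]), index=feature_ids, columns=t_ids + n_ids)
    groups = pd.Series(
        [data_io.TUMOR] * n_tumor + [data_io.NORMAL] * n_normal, index=data.columns
    )
    pairs = None
    if paired:
        if n_tumor != n_normal:
            raise DataValidationError("paired design needs equal group sizes")
        keys = [f"{dataset}_P{i}" for i in range(1, n_tumor + 1)]
        pairs = pd.Series(keys + keys, index=data.columns)
    return ExpressionMatrix(data=data, feature_kind=kind, group_labels=groups, pair_ids=pairs)


def generate_expression(config: SyntheticConfig) -> tuple[dict[str, ExpressionMatrix], GroundTruthManifest]:
    """Simulate every expression cohort and start the manifest.

    Baselines are uniform on [baseline_low, baseline_high] log2 units with
    Gaussian within-group noise; planted DE features are shifted by
    +-effect_size in tumor.  The two circRNA cohorts share one true DE set
    (so their DE lists overlap far beyond chance), as do the mRNA array
    and sequencing cohorts.
    """
    circ_ids = _circ_ids(config.n_circ)
    mirna_ids = _mirna_ids(config.n_mirna)
    gene_ids = _gene_ids(config.n_mrna)
    truth = {
        "circRNA": _plant_directions(_rng(config.seed, "plant_circ"), circ_ids, config.de_fraction),
        "miRNA": _plant_directions(_rng(config.seed, "plant_mirna"), mirna_ids, config.de_fraction),
        "mRNA": _plant_directions(_rng(config.seed, "plant_mrna"), gene_ids, config.de_fraction),
    }
    matrices = {
        "circ_a": _simulate_matrix(
            _rng(config.seed, "circ_a"), circ_ids, "circRNA", "circA",
            truth["circRNA"], config, config.n_pairs_circ_a, config.n_pairs_circ_a, paired=True,
        ),
        "circ_b": _simulate_matrix(
            _rng(config.seed, "circ_b"), circ_ids, "circRNA", "circB",
            truth["circRNA"], config, config.n_pairs_circ_b, config.n_pairs_circ_b, paired=True,
        ),
        "mrna_array": _simulate_matrix(
            _rng(config.seed, "mrna_array"), gene_ids, "mRNA", "mrnaArr",
            truth["mRNA"], config, config.n_pairs_mrna_array, config.n_pairs_mrna_array, paired=True,
        ),
        "mirna_seq": _simulate_matrix(
            _rng(config.seed, "mirna_seq"), mirna_ids, "miRNA", "mirSeq",
            truth["miRNA"], config, config.n_tumor_seq, config.n_normal_seq, paired=False,
        ),
        "mrna_seq": _simulate_matrix(
            _rng(config.seed, "mrna_seq"), gene_ids, "mRNA", "mrnaSeq",
            truth["mRNA"], config, config.n_tumor_seq, config.n_normal_seq, paired=False,
        ),
    }
    # cell-line panel: no tumor/normal contrast, just inter-line variation
    rng_cl = _rng(config.seed, "cell_lines")
    cl_ids = [f"CL{i:03d}" for i in range(1, config.n_cell_lines + 1)]
    cl_data = pd.DataFrame(
        rng_cl.uniform(config.baseline_low, config.baseline_high, size=(config.n_mrna, 1))
        + rng_cl.normal(0, 1.0, size=(config.n_mrna, config.n_cell_lines)),
        index=gene_ids, columns=cl_ids,
    )
    matrices["cell_lines"] = ExpressionMatrix(data=cl_data, feature_kind="mRNA")

    manifest = GroundTruthManifest(
        seed=config.seed, de_features=truth, config=dataclasses.asdict(config)
    )
    return matrices, manifest


# ---------------------------------------------------------------------------
# interactions (planted triplets + per-condition decoys)
# ---------------------------------------------------------------------------


def _split_pool(items: list[str], *sizes: int) -> list[list[str]]:
    out, start = [], 0
    for s in sizes:
        out.append(items[start:start + s])
        start += s
    return out


def generate_interactions(
    config: SyntheticConfig, manifest: GroundTruthManifest
) -> tuple[InteractionTable, InteractionTable]:
    """Emit interaction pairs realizing the planted triplets plus decoys.

    Each decoy is a candidate triplet whose pairs are both present but
    which violates exactly one admission condition (non-DE miRNA, non-DE
    gene, non-DE circRNA, or a sign-rule breach); members are drawn from
    pools disjoint from the planted triplets so decoys cannot combine
    into valid triplets.  Background pairs among further unused features
    add realistic bulk without creating triplets.
    """
    truth = manifest.de_features
    rng = _rng(config.seed, "interactions")
    de_circ_up = sorted(c for c, d in truth["circRNA"].items() if d == "up")
    de_circ_dn = sorted(c for c, d in truth["circRNA"].items() if d == "down")
    de_mir_up = sorted(m for m, d in truth["miRNA"].items() if d == "up")
    de_mir_dn = sorted(m for m, d in truth["miRNA"].items() if d == "down")
    de_gene_up = sorted(g for g, d in truth["mRNA"].items() if d == "up")
    de_gene_dn = sorted(g for g, d in truth["mRNA"].items() if d == "down")
    non_de = {
        kind: sorted(set(ids) - set(truth[kind]))
        for kind, ids in (
            ("circRNA", _circ_ids(config.n_circ)),
            ("miRNA", _mirna_ids(config.n_mirna)),
            ("mRNA", _gene_ids(config.n_mrna)),
        )
    }

    n_need = config.n_triplet_circs + config.n_decoys_per_condition
    if (
        min(len(de_circ_up), len(de_circ_dn)) < n_need
        or min(len(de_mir_up), len(de_mir_dn)) < n_need
        or min(len(de_gene_up), len(de_gene_dn)) < config.n_planted_triplets + 2 * config.n_decoys_per_condition
    ):
        raise DataValidationError("more planted triplets/decoys than available DE features")

    # reserve disjoint pools: triplet members first, then decoy members
    circ_pool_up, circ_decoy_up = _split_pool(de_circ_up, config.n_triplet_circs, config.n_decoys_per_condition)
    circ_pool_dn, circ_decoy_dn = _split_pool(de_circ_dn, config.n_triplet_circs, config.n_decoys_per_condition)
    mir_pool_up, mir_decoy_up = _split_pool(de_mir_up, config.n_triplet_circs, config.n_decoys_per_condition)
    mir_pool_dn, mir_decoy_dn = _split_pool(de_mir_dn, config.n_triplet_circs, config.n_decoys_per_condition)
    gene_pool_up, gene_decoy_up = _split_pool(
        de_gene_up, config.n_planted_triplets, config.n_decoys_per_condition
    )
    gene_pool_dn, gene_decoy_dn = _split_pool(
        de_gene_dn, config.n_planted_triplets, config.n_decoys_per_condition
    )

    # planted triplets: circs alternate direction; one miRNA per circ with
    # the opposite direction; genes concordant with their circ
    circs = [
        (circ_pool_up[i // 2], "up") if i % 2 == 0 else (circ_pool_dn[i // 2], "down")
        for i in range(config.n_triplet_circs)
    ]
    triplets: list[CeRNATriplet] = []
    gene_cursor = {"up": 0, "down": 0}
    for k in range(config.n_planted_triplets):
        circ_id, circ_dir = circs[k % len(circs)]
        i = [c for c, _ in circs].index(circ_id)
        if circ_dir == "up":
            mirna_id, mirna_dir = mir_pool_dn[i], "down"
            gene_id = gene_pool_up[gene_cursor["up"]]
            gene_cursor["up"] += 1
            gene_dir = "up"
        else:
            mirna_id, mirna_dir = mir_pool_up[i], "up"
            gene_id = gene_pool_dn[gene_cursor["down"]]
            gene_cursor["down"] += 1
            gene_dir = "down"
        t = CeRNATriplet(circ_id, mirna_id, gene_id, circ_dir, mirna_dir, gene_dir)
        assert satisfies_sign_rule(t.circ_direction, t.mirna_direction, t.gene_direction)
        triplets.append(t)

    mc: set[tuple[str, str]] = set()
    mg: set[tuple[str, str]] = set()
    for t in triplets:
        mc.add((t.mirna_id, t.circ_id))
        mg.add((t.mirna_id, t.gene_id))

    # decoys: complete pair structure, exactly one broken condition each
    decoy_candidates = []
    nd_mir = non_de["miRNA"]
    nd_circ = non_de["circRNA"]
    nd_gene = non_de["mRNA"]
    for j in range(config.n_decoys_per_condition):
        # 1) miRNA not DE (circ up, gene up would be valid with a down miRNA)
        cand = (circ_decoy_up[j], nd_mir[j], gene_decoy_up[j], "mirna_not_de")
        decoy_candidates.append(cand)
        # 2) sign-rule breach: miRNA direction equals the gene/circ direction
        cand = (circ_decoy_dn[j], mir_decoy_dn[j], gene_decoy_dn[j], "sign_rule_breach")
        decoy_candidates.append(cand)
        # 3) gene not DE
        cand = (circ_decoy_up[j], mir_decoy_dn[j], nd_gene[j], "gene_not_de")
        decoy_candidates.append(cand)
        # 4) circRNA not DE (miRNA down, gene up: sign rule would hold)
        cand = (nd_circ[j], mir_decoy_up[j], gene_decoy_dn[j], "circ_not_de")
        decoy_candidates.append(cand)
    for circ_id, mirna_id, gene_id, violation in decoy_candidates:
        mc.add((mirna_id, circ_id))
        mg.add((mirna_id, gene_id))
        manifest.decoy_pairs.append({"kind": "miRNA_circRNA", "mirna": mirna_id, "partner": circ_id, "violation": violation})
        manifest.decoy_pairs.append({"kind": "miRNA_mRNA", "mirna": mirna_id, "partner": gene_id, "violation": violation})
        manifest.decoy_candidates.append(
            {"circ": circ_id, "mirna": mirna_id, "gene": gene_id, "violation": violation}
        )

    # background bulk: miRNA-circ pairs only (no gene partner -> no triplet)
    offset = config.n_decoys_per_condition
    bg_mirnas = nd_mir[offset:]
    bg_circs = nd_circ[offset:]
    for j in range(config.n_background_pairs):
        m = bg_mirnas[int(rng.integers(len(bg_mirnas)))]
        c = bg_circs[int(rng.integers(len(bg_circs)))]
        mc.add((m, c))

    manifest.planted_triplets = sorted(triplets)
    mc_table = InteractionTable(kind="miRNA_circRNA", pairs=frozenset(mc))
    mg_table = InteractionTable(kind="miRNA_mRNA", pairs=frozenset(mg))
    logger.info(
        "interactions: %d miRNA-circ pairs, %d miRNA-mRNA pairs, %d planted triplets, %d decoy candidates",
        len(mc_table), len(mg_table), len(triplets), len(decoy_candidates),
    )
    return mc_table, mg_table


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------


def _censoring_rate_for(lam_c: float, hazards: np.ndarray) -> float:
    # independent exponential censoring: P(C < T_i) = lam_c / (lam_c + h_i)
    return float(np.mean(lam_c / (lam_c + hazards)))


def _solve_censoring_rate(target: float, hazards: np.ndarray) -> float:
    lo, hi = 1e-12, 1e6 * hazards.max()
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if _censoring_rate_for(mid, hazards) < target:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def generate_clinical(
    config: SyntheticConfig, manifest: GroundTruthManifest, expr: ExpressionMatrix
) -> ClinicalTable:
    """Simulate overall survival for the tumor samples of ``expr``.

    Event times are exponential with hazard h0 * HR^z_g per planted
    prognostic gene g, where z_g indicates expression above the tumor
    median.  Censoring is independent exponential with its rate solved so
    the expected censored fraction matches ``censoring_rate``.  Prognostic
    genes default to planted network-triplet genes; a set of designated
    null genes (HR = 1) is recorded for type-I-error checks.
    """
    rng = _rng(config.seed, "clinical")
    tumor_ids = expr.samples_in_group(data_io.TUMOR)
    n = len(tumor_ids)

    triplet_genes = [t.gene_id for t in manifest.planted_triplets]
    prognostic = list(dict.fromkeys(triplet_genes))[: config.n_prognostic]
    if len(prognostic) < config.n_prognostic:
        raise DataValidationError("not enough planted genes for the requested prognostic count")
    used = set(prognostic) | set(triplet_genes)
    nulls = [g for g in expr.feature_ids if g not in used][: config.n_null_prognostic]
    manifest.prognostic_genes = {g: config.hazard_ratio for g in prognostic}
    manifest.null_prognostic_genes = nulls

    log_hr = np.zeros(n)
    for g in prognostic:
        values = expr.data.loc[g, tumor_ids].to_numpy(dtype=float)
        z = (values > np.median(values)).astype(float)
        log_hr += np.log(config.hazard_ratio) * z
    hazards = config.baseline_hazard * np.exp(log_hr)
    event_times = rng.exponential(1.0 / hazards)

    if config.censoring_rate >= 1.0:
        times, events = event_times * rng.uniform(0, 1, size=n), np.zeros(n, dtype=int)
    elif config.censoring_rate <= 0.0:
        times, events = event_times, np.ones(n, dtype=int)
    else:
        # exponential censoring clock at rate lam_c: the observed time
        # min(T, C) ~ Exp(h_i + lam_c) is independent of which clock fired,
        # so the censored subset can be drawn with a fixed count (weighted by
        # each sample's censoring probability) while keeping the observed
        # times exactly distributed — this pins the realized censored
        # fraction to the configured rate instead of leaving it binomial
        lam_c = _solve_censoring_rate(config.censoring_rate, hazards)
        times = rng.exponential(1.0 / (hazards + lam_c))
        p_censor = lam_c / (lam_c + hazards)
        m = int(round(config.censoring_rate * n))
        censored = rng.choice(n, size=m, replace=False, p=p_censor / p_censor.sum())
        events = np.ones(n, dtype=int)
        events[censored] = 0
    table = pd.DataFrame(
        {"os_time_days": times, "os_event": events}, index=pd.Index(tumor_ids, name="sample_id")
    )
    logger.info("clinical: %d samples, %.0f%% events", n, 100 * events.mean())
    return ClinicalTable(table=table)


# ---------------------------------------------------------------------------
# drug response
# ---------------------------------------------------------------------------


def generate_drug_response(
    config: SyntheticConfig, manifest: GroundTruthManifest, cell_expr: ExpressionMatrix
) -> DrugResponseMatrix:
    """Simulate a cell-line x drug IC50 grid with planted monotone pairs.

    For each planted (gene, drug) pair, ln IC50 = a + b * standardized
    expression + noise with |b| / sd(noise) = ``drug_effect_ratio`` and
    alternating slope sign (negative slope = sensitizing).  All other
    entries are independent noise; a missingness mask is applied at
    ``drug_missing_rate``.
    """
    rng = _rng(config.seed, "drugs")
    drug_ids = [f"DRUG{i:03d}" for i in range(1, config.n_drugs + 1)]
    cl_ids = cell_expr.sample_ids
    n_cl = len(cl_ids)
    base = rng.normal(0, 1.0, size=(n_cl, config.n_drugs)) + rng.uniform(-2, 2, size=config.n_drugs)
    ic50 = pd.DataFrame(base, index=cl_ids, columns=drug_ids)

    # planted pairs use genes outside the ceRNA/prognostic truth for isolation
    reserved = (
        {t.gene_id for t in manifest.planted_triplets}
        | set(manifest.prognostic_genes)
        | set(manifest.null_prognostic_genes)
    )
    candidates = [g for g in cell_expr.feature_ids if g not in reserved]
    if len(candidates) < config.n_planted_drug_pairs:
        raise DataValidationError("not enough genes for planted drug pairs")
    for k in range(config.n_planted_drug_pairs):
        gene = candidates[k]
        drug = drug_ids[k % config.n_drugs]
        sign = -1 if k % 2 == 0 else 1
        x = cell_expr.data.loc[gene].to_numpy(dtype=float)
        x_std = (x - x.mean()) / x.std()
        ic50[drug] = sign * config.drug_effect_ratio * x_std + rng.normal(0, 1.0, size=n_cl)
        manifest.drug_pairs.append({"gene": gene, "drug": drug, "slope_sign": sign})
    if config.drug_missing_rate > 0:
        mask = rng.uniform(size=ic50.shape) < config.drug_missing_rate
        ic50 = ic50.mask(mask)
    return DrugResponseMatrix(ic50=ic50, scale="ln_ic50")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def generate_gene_sets(
    config: SyntheticConfig, manifest: GroundTruthManifest
) -> GeneSetCollection:
    """Random GMT-style sets plus one set enriched for planted triplet genes."""
    rng = _rng(config.seed, "gene_sets")
    universe = _gene_ids(config.n_mrna)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    triplet_genes = sorted({t.gene_id for t in manifest.planted_triplets})
    filler_pool = [g for g in universe if g not in triplet_genes]
    n_fill = max(0, config.gene_set_size - len(triplet_genes))
    planted_name = "PLANTED_CERNA_TARGETS"
    fill = [filler_pool[i] for i in rng.choice(len(filler_pool), size=n_fill, replace=False)]
    sets[planted_name] = frozenset(triplet_genes + fill)
    descriptions[planted_name] = "set seeded with the planted ceRNA target genes"
    for i in range(1, config.n_gene_sets):
        name = f"RANDOM_SET_{i:02d}"
        members = rng.choice(len(universe), size=config.gene_set_size, replace=False)
        sets[name] = frozenset(universe[j] for j in members)
        descriptions[name] = "random background set"
    manifest.planted_gene_set = planted_name
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def generate_all(config: SyntheticConfig) -> SyntheticBundle:
    """Run every generator in a fixed order and return the full bundle."""
    matrices, manifest = generate_expression(config)
    mc_pairs, mg_pairs = generate_interactions(config, manifest)
    clinical = generate_clinical(config, manifest, matrices["mrna_seq"])
    drugs = generate_drug_response(config, manifest, matrices["cell_lines"])
    gene_sets = generate_gene_sets(config, manifest)
    return SyntheticBundle(
        matrices=matrices, mc_pairs=mc_pairs, mg_pairs=mg_pairs,
        clinical=clinical, drugs=drugs, gene_sets=gene_sets, manifest=manifest,
    )


def write_all(bundle: SyntheticBundle, outdir) -> None:
    """Write every file the pipeline reads, plus the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, matrix in bundle.matrices.items():
        data_io.write_expression_table(matrix, outdir / f"expr_{name}.tsv")
        if matrix.group_labels is not None:
            data_io.write_sample_sheet(matrix, outdir / f"samples_{name}.tsv")
    data_io.write_interaction_table(bundle.mc_pairs, outdir / "pairs_mirna_circ.tsv")
    data_io.write_interaction_table(bundle.mg_pairs, outdir / "pairs_mirna_gene.tsv")
    data_io.write_clinical_table(bundle.clinical, outdir / "clinical.tsv")
    data_io.write_drug_matrix(bundle.drugs, outdir / "drug_ic50.tsv")
    data_io.write_gene_sets_gmt(bundle.gene_sets, outdir / "gene_sets.gmt")
    bundle.manifest.to_json(outdir / "manifest.json")


def load_bundle(indir) -> SyntheticBundle:
    """Re-read a written bundle (round-trip of :func:`write_all`)."""
    indir = Path(indir)
    manifest = GroundTruthManifest.from_json(indir / "manifest.json")
    matrices = {}
    kinds = {
        "circ_a": "circRNA", "circ_b": "circRNA", "mrna_array": "mRNA",
        "mirna_seq": "miRNA", "mrna_seq": "mRNA", "cell_lines": "mRNA",
    }
    for name, kind in kinds.items():
        sheet = indir / f"samples_{name}.tsv"
        group_map = pair_map = None
        if sheet.exists():
            group_map, pair_map = data_io.read_sample_sheet(sheet)
        matrices[name] = data_io.read_expression_table(
            indir / f"expr_{name}.tsv", kind, group_map=group_map, pair_map=pair_map
        )
    return SyntheticBundle(
        matrices=matrices,
        mc_pairs=data_io.read_interaction_table(indir / "pairs_mirna_circ.tsv", "miRNA_circRNA"),
        mg_pairs=data_io.read_interaction_table(indir / "pairs_mirna_gene.tsv", "miRNA_mRNA"),
        clinical=data_io.read_clinical_table(indir / "clinical.tsv"),
        drugs=data_io.read_drug_matrix(indir / "drug_ic50.tsv"),
        gene_sets=data_io.read_gene_sets_gmt(indir / "gene_sets.gmt"),
        manifest=manifest,
    )
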
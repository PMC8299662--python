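"""Tabular readers/writers and the validated in-memory model.

Every downstream stage consumes the containers defined here:
log2-scale expression matrices with tumor/normal labels (and optional
patient pairing), miRNA interaction pair tables, GMT gene-set
collections, overall-survival clinical tables and cell-line IC50
matrices.  All files are plain TSV so fixtures stay text-only and
diffable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"
FEATURE_KINDS = ("circRNA", "miRNA", "mRNA")
COLLAPSE_POLICIES = ("max_mean", "mean")

#: float format that round-trips IEEE doubles through text
_FLOAT_FMT = "%.17g"


class DataValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Feature-by-sample abundance on the log2 scale.

    ``data`` holds features on the rows and samples on the columns; missing
    values are NaN, never silent zeros.  ``group_labels`` maps each sample to
    ``tumor``/``normal`` (may be None for unlabelled cohorts such as cell-line
    panels).  ``pair_ids`` optionally keys tumor/normal samples from the same
    patient; each key must occur exactly once per group.
    """

    data: pd.DataFrame
    feature_kind: str
    group_labels: pd.Series | None = None
    pair_ids: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise DataValidationError(
                f"feature_kind must be one of {FEATURE_KINDS}, got {self.feature_kind!r}"
            )
        if self.data.shape[0] == 0:
            raise DataValidationError("no features")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataValidationError(f"duplicate feature id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DataValidationError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataValidationError("expression values must be numeric")
        if np.isinf(values).any():
            raise DataValidationError("expression values must be finite (NaN marks missing)")
        if self.group_labels is not None:
            self.group_labels = self.group_labels.reindex(self.data.columns)
            if self.group_labels.isna().any():
                missing = self.group_labels.index[self.group_labels.isna()][0]
                raise DataValidationError(f"sample {missing!r} has no group label")
            bad = set(self.group_labels.unique()) - {TUMOR, NORMAL}
            if bad:
                raise DataValidationError(f"unknown group labels {sorted(bad)}")
        if self.pair_ids is not None:
            if self.group_labels is None:
                raise DataValidationError("pair_ids require group_labels")
            self.pair_ids = self.pair_ids.reindex(self.data.columns)
            paired = self.pair_ids.dropna()
            for grp in (TUMOR, NORMAL):
                keys = paired[self.group_labels.loc[paired.index] == grp]
                if keys.duplicated().any():
                    k = keys[keys.duplicated()].iloc[0]
                    raise DataValidationError(f"pair id {k!r} appears twice in group {grp!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        if self.group_labels is None:
            raise DataValidationError("matrix has no group labels")
        return list(self.group_labels.index[self.group_labels == group])


@dataclass(frozen=True)
class InteractionTable:
    """Set of (miRNA id, partner id) interaction pairs of one kind."""

    kind: str  # miRNA_circRNA | miRNA_mRNA
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.kind not in ("miRNA_circRNA", "miRNA_mRNA"):
            raise DataValidationError(f"unknown interaction kind {self.kind!r}")
        for m, p in self.pairs:
            if not m or not p:
                raise DataValidationError("interaction ids must be non-empty strings")

    def partners_of(self, mirna_id: str) -> set[str]:
        return {p for m, p in self.pairs if m == mirna_id}

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT content) with uppercase-normalized symbols."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample overall survival: time in days and event indicator."""

    table: pd.DataFrame  # index sample_id; columns os_time_days, os_event

    def __post_init__(self) -> None:
        required = {"os_time_days", "os_event"}
        if not required.issubset(self.table.columns):
            raise DataValidationError(f"clinical table needs columns {sorted(required)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise DataValidationError(f"duplicate clinical sample {dup!r}")
        if (self.table["os_time_days"] < 0).any():
            bad = self.table.index[self.table["os_time_days"] < 0][0]
            raise DataValidationError(f"negative survival time for sample {bad!r}")
        if not self.table["os_event"].isin((0, 1)).all():
            raise DataValidationError("os_event must be 0 (censored) or 1 (death)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class DrugResponseMatrix:
    """Cell-line by drug IC50 grid; scale metadata is mandatory."""

    ic50: pd.DataFrame  # rows cell lines, columns drugs, NaN allowed
    scale: str  # ln_ic50 | log10_ic50

    def __post_init__(self) -> None:
        if self.scale not in ("ln_ic50", "log10_ic50"):
            raise DataValidationError(f"unknown IC50 scale {self.scale!r}")
        if self.ic50.index.has_duplicates or self.ic50.columns.has_duplicates:
            raise DataValidationError("duplicate cell line or drug id")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.ic50.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.ic50.columns)


# ---------------------------------------------------------------------------
# duplicate-feature collapsing
# ---------------------------------------------------------------------------


def _collapse_duplicates(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    """Collapse rows sharing an id: keep the max-mean row, or average them."""
    if policy not in COLLAPSE_POLICIES:
        raise DataValidationError(f"unknown collapse policy {policy!r}")
    if not df.index.has_duplicates:
        return df
    n_before = len(df)
    if policy == "mean":
        out = df.groupby(level=0, sort=False).mean()
    else:  # max_mean: keep the single probe with the highest mean expression
        means = df.mean(axis=1, skipna=True).to_numpy()
        by_mean = df.iloc[np.argsort(-means, kind="stable")]
        best = by_mean.loc[~by_mean.index.duplicated(keep="first")]
        out = best.loc[df.index.drop_duplicates()]  # original id order
    logger.info("collapsed %d duplicate rows to %d (%s)", n_before, len(out), policy)
    return out


# ---------------------------------------------------------------------------
# expression I/O and transforms
# ---------------------------------------------------------------------------


def read_expression_table(
    path,
    feature_kind: str,
    group_map: dict[str, str] | None = None,
    pair_map: dict[str, str] | None = None,
    collapse: str = "max_mean",
) -> ExpressionMatrix:
    """Read a feature-by-sample TSV (first column ``feature_id``).

    ``group_map`` assigns tumor/normal per sample and must not mention
    samples absent from the table; non-numeric cells are hard errors
    naming the offending row and column.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if raw.shape[0] == 0:
        raise DataValidationError(f"{path}: no features")
    if raw.shape[1] == 0:
        raise DataValidationError(f"{path}: no sample columns")
    data = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str), dtype=float)
    def _cell(value: str | float) -> float:
        if value is None or (isinstance(value, float) and np.isnan(value)) or value in ("", "NA"):
            return np.nan
        return float(value)  # exact (correctly rounded) round-trip conversion

    for col in raw.columns:
        try:
            data[col] = np.array([_cell(v) for v in raw[col]], dtype=float)
        except (TypeError, ValueError):
            for row, v in zip(raw.index, raw[col]):
                try:
                    _cell(v)
                except (TypeError, ValueError):
                    raise DataValidationError(
                        f"{path}: non-numeric value in row {row!r}, column {col!r}"
                    ) from None
    data = _collapse_duplicates(data, collapse)

    groups = pairs = None
    if group_map is not None:
        unknown = set(group_map) - set(data.columns)
        if unknown:
            raise DataValidationError(f"group_map mentions unknown sample {sorted(unknown)[0]!r}")
        groups = pd.Series({s: group_map[s] for s in data.columns if s in group_map})
        groups = groups.reindex(data.columns)
    if pair_map is not None:
        unknown = set(pair_map) - set(data.columns)
        if unknown:
            raise DataValidationError(f"pair_map mentions unknown sample {sorted(unknown)[0]!r}")
        pairs = pd.Series(pair_map).reindex(data.columns)
    matrix = ExpressionMatrix(data=data, feature_kind=feature_kind, group_labels=groups, pair_ids=pairs)
    logger.info("read %s: %d features x %d samples", path, matrix.n_features, matrix.n_samples)
    return matrix


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id", float_format=_FLOAT_FMT)


def read_sample_sheet(path) -> tuple[dict[str, str], dict[str, str] | None]:
    """Read the two/three-column sample sheet (sample_id, group[, pair_id])."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in sheet.columns or "group" not in sheet.columns:
        raise DataValidationError(f"{path}: sample sheet needs sample_id and group columns")
    if sheet["sample_id"].duplicated().any():
        raise DataValidationError(f"{path}: duplicate sample id in sample sheet")
    group_map = dict(zip(sheet["sample_id"], sheet["group"]))
    pair_map = None
    if "pair_id" in sheet.columns:
        pair_map = {
            s: p for s, p in zip(sheet["sample_id"], sheet["pair_id"]) if isinstance(p, str) and p
        }
    return group_map, pair_map


def write_sample_sheet(matrix: ExpressionMatrix, path) -> None:
    if matrix.group_labels is None:
        raise DataValidationError("matrix has no group labels to write")
    out = pd.DataFrame({"sample_id": matrix.sample_ids, "group": matrix.group_labels.to_numpy()})
    if matrix.pair_ids is not None:
        out["pair_id"] = matrix.pair_ids.to_numpy()
    out.to_csv(path, sep="\t", index=False)


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0, already_log: bool = False) -> ExpressionMatrix:
    """Return log2(value + offset); a bit-identical no-op when ``already_log``."""
    if already_log:
        return replace(matrix, data=matrix.data.copy())
    if offset < 0:
        raise DataValidationError("offset must be non-negative")
    if (matrix.data < 0).any().any():
        raise DataValidationError("negative value encountered with already_log=False")
    return replace(matrix, data=np.log2(matrix.data + offset))


def map_feature_ids(
    matrix: ExpressionMatrix, mapping: dict[str, str], collapse: str = "max_mean"
) -> ExpressionMatrix:
    """Map probe ids to canonical ids, dropping unmapped probes.

    Probes mapping to the same canonical id are collapsed under ``collapse``;
    the number of dropped probes is logged.  Never increases the feature count.
    """
    if not mapping:
        raise DataValidationError("empty id mapping")
    mapped_mask = matrix.data.index.isin(mapping)
    n_dropped = int((~mapped_mask).sum())
    kept = matrix.data.loc[mapped_mask]
    if kept.shape[0] == 0:
        raise DataValidationError("no features left after id mapping")
    kept = kept.rename(index=mapping)
    kept = _collapse_duplicates(kept, collapse)
    logger.info("id mapping: %d probes dropped, %d features kept", n_dropped, len(kept))
    return replace(matrix, data=kept)


def drop_sparse_features(matrix: ExpressionMatrix, max_missing_fraction: float = 0.2) -> ExpressionMatrix:
    """Drop features missing in more than the given fraction of samples."""
    frac = matrix.data.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d features with >%.0f%% missing values", n_dropped, 100 * max_missing_fraction)
    if keep.sum() == 0:
        raise DataValidationError("all features dropped by missingness filter")
    return replace(matrix, data=matrix.data.loc[keep])


# ---------------------------------------------------------------------------
# interaction tables, GMT, clinical, drug response
# ---------------------------------------------------------------------------


def read_interaction_table(path, kind: str) -> InteractionTable:
    """Read a two-column TSV with header ``mirna_id<TAB>partner_id``."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:2]) != ["mirna_id", "partner_id"]:
        raise DataValidationError(f"{path}: expected header 'mirna_id\\tpartner_id'")
    if table.isna().any().any():
        line = int(np.where(table.isna().any(axis=1))[0][0]) + 2
        raise DataValidationError(f"{path}: malformed line {line}")
    pairs = list(zip(table["mirna_id"], table["partner_id"]))
    unique = frozenset(pairs)
    if len(unique) < len(pairs):
        logger.info("%s: %d duplicate pairs removed", path, len(pairs) - len(unique))
    return InteractionTable(kind=kind, pairs=unique)


def write_interaction_table(table: InteractionTable, path) -> None:
    pd.DataFrame(sorted(table.pairs), columns=["mirna_id", "partner_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated members)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g.strip().upper() for g in genes if g.strip()]
            if not genes:
                raise DataValidationError(f"{path}: line {lineno} defines an empty set")
            if name in sets:
                raise DataValidationError(f"{path}: line {lineno} redefines set {name!r}")
            sets[name] = frozenset(genes)
            descriptions[name] = desc
    if not sets:
        raise DataValidationError(f"{path}: no gene sets")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(collection.sets[name])]) + "\n")


def read_clinical_table(path) -> ClinicalTable:
    """Read the clinical TSV (sample_id, os_time_days, os_event)."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    required = {"sample_id", "os_time_days", "os_event"}
    if not required.issubset(table.columns):
        raise DataValidationError(f"{path}: clinical table needs columns {sorted(required)}")
    for lineno, value in enumerate(table["os_time_days"], start=2):
        if not math.isfinite(value) or value < 0:
            raise DataValidationError(f"{path}: invalid os_time on line {lineno}")
    return ClinicalTable(table=table.set_index("sample_id")[["os_time_days", "os_event"]])


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)


def read_drug_matrix(path) -> DrugResponseMatrix:
    """Read the IC50 TSV; first line declares ``#scale=ln_ic50|log10_ic50``."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#scale="):
            raise DataValidationError(f"{path}: missing '#scale=' metadata line")
        scale = header.split("=", 1)[1]
        table = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    return DrugResponseMatrix(ic50=table, scale=scale)


def write_drug_matrix(drugs: DrugResponseMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#scale={drugs.scale}\n")
        drugs.ic50.to_csv(fh, sep="\t", index_label="cell_line_id", float_format=_FLOAT_FMT)
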
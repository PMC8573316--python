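"""Tabular containers and TSV I/O for abundance data, weight matrices and feature maps.

All on-disk formats are UTF-8, tab-separated, with a mandatory header row and
the identifier in the first column.  Missing values are written as ``NA`` and
accepted as ``NA`` or an empty cell on read.  Numbers are serialised with the
shortest decimal representation that parses back to the identical float, so
write/read round-trips are bit-exact for finite values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

_MISSING_TOKENS = ["NA", ""]
_REL_SUM_TOL = 1e-6  # tolerance for inferring RELATIVE unit on read
_REL_SUM_STRICT = 1e-8  # invariant tolerance for validated tables


class Unit(str, enum.Enum):
    RAW = "RAW"
    RELATIVE = "RELATIVE"


class Modality(str, enum.Enum):
    DNA = "DNA"
    RNA = "RNA"
    BOTH = "BOTH"
    METABOLITE = "METABOLITE"


class MapKind(str, enum.Enum):
    GENE_TO_SPECIES = "GENE_TO_SPECIES"
    METABOLITE_TO_PATHWAY = "METABOLITE_TO_PATHWAY"


class Orientation(str, enum.Enum):
    SAMPLES_IN_ROWS = "samples_in_rows"
    FEATURES_IN_ROWS = "features_in_rows"


@dataclass
class AbundanceTable:
    """Samples x features abundance matrix with unit and modality metadata.

    ``data`` always stores samples in rows.  Missing entries (NaN) are only
    allowed for metabolite tables; gene-family tables must be fully observed.
    """

    data: pd.DataFrame
    unit: Unit
    modality: Modality

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        self.modality = Modality(self.modality)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, unit: Unit | None = None) -> "AbundanceTable":
        return AbundanceTable(data=data, unit=unit or self.unit, modality=self.modality)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any() and self.modality is not Modality.METABOLITE:
            raise ValidationError(
                f"missing values are not allowed in a {self.modality.value} table"
            )
        with np.errstate(invalid="ignore"):
            if (vals < 0).any():
                raise ValidationError("abundance values must be non-negative")
        if self.unit is Unit.RELATIVE:
            complete = ~np.isnan(vals).any(axis=1)
            if complete.any():
                # feature filters produce subcompositions, so rows may sum to
                # less than 1, but never more
                sums = vals[complete].sum(axis=1)
                if (sums > 1.0 + _REL_SUM_STRICT).any():
                    bad = np.asarray(self.data.index)[complete][sums > 1.0 + _REL_SUM_STRICT]
                    raise ValidationError(
                        f"RELATIVE table has rows summing to more than 1: {list(bad[:5])}"
                    )
        if self.modality is Modality.BOTH:
            tagged = [f for f in self.data.columns if str(f).endswith(("|DNA", "|RNA"))]
            if len(tagged) != self.data.shape[1]:
                raise ValidationError(
                    "modality=BOTH requires every feature id to carry a |DNA or |RNA suffix"
                )


@dataclass
class FeatureMap:
    """Feature-to-group mapping (gene->species or metabolite->pathway)."""

    entries: list[tuple[str, str]]
    kind: MapKind

    def __post_init__(self) -> None:
        self.kind = MapKind(self.kind)
        for feat, group in self.entries:
            if not feat or not group:
                raise ValidationError("feature map entries must have non-empty ids")
        # drop exact duplicate pairs, preserving first-seen order
        self.entries = list(dict.fromkeys(self.entries))

    def groups_of(self, feature_id: str) -> set[str]:
        return {g for f, g in self.entries if f == feature_id}

    def by_group(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for feat, group in self.entries:
            out.setdefault(group, []).append(feat)
        return out


@dataclass
class WeightMatrix:
    """Per-metabolite elastic-net coefficients over gene families plus intercepts.

    This is the method's primary artefact: column j holds the regression
    weights mapping (transformed) gene-family abundances to the (transformed)
    abundance of metabolite j.
    """

    gene_ids: list[str]
    metabolite_ids: list[str]
    intercepts: np.ndarray  # (n_metabolites,)
    coefficients: np.ndarray  # (n_genes, n_metabolites)
    transform_params_ref: str = ""

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.intercepts.shape != (len(self.metabolite_ids),):
            raise ValidationError("one intercept per metabolite is required")
        if self.coefficients.shape != (len(self.gene_ids), len(self.metabolite_ids)):
            raise ValidationError(
                f"coefficient matrix shape {self.coefficients.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.metabolite_ids)} metabolites"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids in weight matrix")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise FormatError("duplicate metabolite ids in weight matrix")


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(
    path,
    modality: Modality | str,
    orientation: Orientation | str = Orientation.SAMPLES_IN_ROWS,
) -> AbundanceTable:
    """Read a samples x features abundance TSV.

    The unit is inferred: RELATIVE if every complete row sums to 1 within
    1e-6, RAW otherwise.  ``orientation`` says how the file is laid out; the
    returned table always has samples in rows.
    """
    modality = Modality(modality)
    orientation = Orientation(orientation)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=_MISSING_TOKENS,
            keep_default_na=False, float_precision="round_trip"
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if not all(pd.api.types.is_numeric_dtype(df[c]) for c in df.columns):
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        raise FormatError(f"non-numeric column(s) in {path}: {bad[:5]}")
    if orientation is Orientation.FEATURES_IN_ROWS:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    vals = df.to_numpy(dtype=float)
    complete = ~np.isnan(vals).any(axis=1)
    unit = Unit.RAW
    if complete.any():
        sums = vals[complete].sum(axis=1)
        if np.allclose(sums, 1.0, atol=_REL_SUM_TOL, rtol=0):
            unit = Unit.RELATIVE
            # rows within the loose read tolerance but outside the strict
            # invariant are renormalised; exact tables are left untouched
            off = ~np.isclose(sums, 1.0, atol=_REL_SUM_STRICT, rtol=0)
            if off.any():
                rows = np.flatnonzero(complete)[off]
                vals[rows] = vals[rows] / vals[rows].sum(axis=1, keepdims=True)
                df = pd.DataFrame(vals, index=df.index, columns=df.columns)
    return AbundanceTable(data=df, unit=unit, modality=modality)


def write_abundance_table(table: AbundanceTable, path) -> None:
    try:
        table.data.to_csv(path, sep="\t", na_rep="NA")
    except OSError as exc:
        raise OSError(f"failed writing abundance table to {path}: {exc}") from exc


_INTERCEPT_ROW = "#intercept"


def write_weight_matrix(w: WeightMatrix, path) -> None:
    """Write genes-as-rows weight TSV; first data row is ``#intercept``."""
    body = pd.DataFrame(w.coefficients, index=w.gene_ids, columns=w.metabolite_ids)
    head = pd.DataFrame([w.intercepts], index=[_INTERCEPT_ROW], columns=w.metabolite_ids)
    out = pd.concat([head, body])
    out.index.name = f"gene_id;transform={w.transform_params_ref}"
    try:
        out.to_csv(path, sep="\t")
    except OSError as exc:
        raise OSError(f"failed writing weight matrix to {path}: {exc}") from exc


def read_weight_matrix(path) -> WeightMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise FormatError(f"cannot parse weight matrix {path}: {exc}") from exc
    if df.index[0] != _INTERCEPT_ROW:
        raise FormatError(f"weight matrix {path} lacks the leading '{_INTERCEPT_ROW}' row")
    ref = ""
    if df.index.name and ";transform=" in str(df.index.name):
        ref = str(df.index.name).split(";transform=", 1)[1]
    intercepts = df.iloc[0].to_numpy(dtype=float)
    body = df.iloc[1:]
    return WeightMatrix(
        gene_ids=[str(g) for g in body.index],
        metabolite_ids=[str(m) for m in df.columns],
        intercepts=intercepts,
        coefficients=body.to_numpy(dtype=float),
        transform_params_ref=ref,
    )


def read_feature_map(path, kind: MapKind | str) -> FeatureMap:
    """Read a two-column (feature_id, group_id) TSV with a header row."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse feature map {path}: {exc}") from exc
    if df.shape[1] != 2:
        raise FormatError(
            f"feature map {path} must have exactly 2 columns, found {df.shape[1]}"
        )
    entries = [(str(a), str(b)) for a, b in df.itertuples(index=False)]
    return FeatureMap(entries=entries, kind=MapKind(kind))


def write_feature_map(fmap: FeatureMap, path) -> None:
    cols = ("gene_id", "species_id") if fmap.kind is MapKind.GENE_TO_SPECIES else (
        "metabolite_id", "pathway_id")
    pd.DataFrame(fmap.entries, columns=cols).to_csv(path, sep="\t", index=False)
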
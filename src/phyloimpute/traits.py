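"""Mixed-type species-trait tables: schema, validation, I/O and screening.

A :class:`TraitTable` is the currency of the whole pipeline: a species x trait
matrix where every trait is declared as continuous, count, binary or
multicategorical, and missingness is explicit.  Numeric traits are stored as
floats (NaN = missing); categorical traits as strings (None = missing).

The screening operations implement the dataset-construction rules used to
carve a near-complete-case table out of a large, gappy trait compilation:
a severe-outlier screen (Q3 + 3*IQR), a class-imbalance screen for
categorical traits, and the near-complete-case row filter (per-trait
missingness cap plus a minimum number of observed companion traits for any
row that has gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "TraitTable",
    "TraitTableError",
    "load_trait_table",
    "write_trait_table",
    "detect_severe_outliers",
    "screen_class_imbalance",
    "build_near_complete_case",
    "apply_transforms",
    "invert_transforms",
]

NUMERIC_DTYPES = ("continuous", "count")
CATEGORICAL_DTYPES = ("binary", "multicategorical")
VALID_DTYPES = NUMERIC_DTYPES + CATEGORICAL_DTYPES
VALID_TRANSFORMS = ("none", "natural_log")


class TraitTableError(ValueError):
    """Raised for schema violations, bad cells, or infeasible screens."""


@dataclass(frozen=True)
class TraitSpec:
    """Declaration of one trait column.

    Parameters
    ----------
    name : str
        Column label in the table.
    dtype : {"continuous", "count", "binary", "multicategorical"}
        Statistical type; decides the imputation model family and the
        error metric (MSE for numeric, PFC for categorical).
    categories : tuple of str
        Ordered category labels; required (non-empty) exactly for the
        categorical dtypes, and a binary trait has exactly two.
    transform : {"none", "natural_log"}
        Model-scale transform applied before imputation.  Natural log is
        only valid for strictly positive numeric traits (a signed trait
        such as a latitude centroid must keep ``"none"``).
    mnar_tail : mapping, optional
        Declarative description of the realistic worst-case missingness for
        this trait: for numeric traits ``{"side": "lower"|"upper"|
        "center-on-zero", "fraction": 0.10}``; for categorical traits
        ``{"category": label, "fraction": 1.0}``.
    """

    name: str
    dtype: str
    categories: tuple[str, ...] = ()
    transform: str = "none"
    mnar_tail: Mapping | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise TraitTableError("trait name must be non-empty")
        if self.dtype not in VALID_DTYPES:
            raise TraitTableError(f"unknown dtype {self.dtype!r} for trait {self.name!r}")
        if self.transform not in VALID_TRANSFORMS:
            raise TraitTableError(f"unknown transform {self.transform!r} for trait {self.name!r}")
        if self.dtype in CATEGORICAL_DTYPES:
            if not self.categories:
                raise TraitTableError(f"categorical trait {self.name!r} needs categories")
            if self.dtype == "binary" and len(self.categories) != 2:
                raise TraitTableError(f"binary trait {self.name!r} must have exactly 2 categories")
            if len(set(self.categories)) != len(self.categories):
                raise TraitTableError(f"duplicate categories for trait {self.name!r}")
            if self.transform != "none":
                raise TraitTableError(f"transform not allowed for categorical trait {self.name!r}")
        else:
            if self.categories:
                raise TraitTableError(f"numeric trait {self.name!r} must not declare categories")
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def is_numeric(self) -> bool:
        return self.dtype in NUMERIC_DTYPES

    @property
    def is_categorical(self) -> bool:
        return self.dtype in CATEGORICAL_DTYPES


@dataclass
class TraitTable:
    """A validated species x trait matrix with explicit missingness.

    ``data`` is a DataFrame indexed by species identifier with one column
    per spec (numeric columns float64, categorical columns object).
    ``aux_columns`` names fully-observed helper predictors (for example
    phylogenetic eigenvectors) that are appended to ``data`` but are never
    imputed or scored.
    """

    data: pd.DataFrame
    specs: tuple[TraitSpec, ...]
    aux_columns: tuple[str, ...] = ()
    transformed: bool = False
    # derived tables (back-transformed or pooled) may carry non-integer counts
    strict_counts: bool = True

    def __post_init__(self) -> None:
        self.specs = tuple(self.specs)
        self.aux_columns = tuple(self.aux_columns)
        self.validate()

    # -- structure -----------------------------------------------------

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> TraitSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def n_species(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise TraitTableError(f"duplicate species identifiers: {dups}")
        if any(not str(s) for s in idx):
            raise TraitTableError("empty species identifier")
        expected = [s.name for s in self.specs] + list(self.aux_columns)
        missing_cols = [c for c in expected if c not in self.data.columns]
        if missing_cols:
            raise TraitTableError(f"table lacks declared columns: {missing_cols}")
        for spec in self.specs:
            col = self.data[spec.name]
            if spec.is_numeric:
                if not pd.api.types.is_float_dtype(col):
                    self.data[spec.name] = col.astype(float)
                    col = self.data[spec.name]
                vals = col.dropna()
                if spec.dtype == "count" and not self.transformed and self.strict_counts:
                    bad = vals[(vals < 0) | (vals != np.floor(vals))]
                    if len(bad):
                        raise TraitTableError(
                            f"count trait {spec.name!r} has non-count value "
                            f"{bad.iloc[0]!r} for species {bad.index[0]!r}"
                        )
            else:
                vals = col[col.notna()]
                bad = vals[~vals.isin(spec.categories)]
                if len(bad):
                    raise TraitTableError(
                        f"trait {spec.name!r}: unknown category {bad.iloc[0]!r} "
                        f"for species {bad.index[0]!r} (categories: {list(spec.categories)})"
                    )

    # -- missingness ---------------------------------------------------

    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame over trait columns only (aux columns excluded)."""
        return self.data[self.trait_names].isna()

    def missing_fraction(self, trait: str) -> float:
        return float(self.data[trait].isna().mean())

    def observed_cells(self, trait: str) -> list[str]:
        """Species with an observed value for ``trait``."""
        col = self.data[trait]
        return list(col.index[col.notna()])

    # -- convenience ---------------------------------------------------

    def copy(self) -> "TraitTable":
        return TraitTable(
            data=self.data.copy(),
            specs=self.specs,
            aux_columns=self.aux_columns,
            transformed=self.transformed,
            strict_counts=self.strict_counts,
        )

    def subset(self, species: Sequence[str]) -> "TraitTable":
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise TraitTableError(f"unknown species: {missing}")
        return TraitTable(
            data=self.data.loc[list(species)].copy(),
            specs=self.specs,
            aux_columns=self.aux_columns,
            transformed=self.transformed,
            strict_counts=self.strict_counts,
        )


# ---------------------------------------------------------------------------
# I/O


def load_trait_table(
    csv_path,
    schema: Sequence[TraitSpec],
    missing_token: str = "NA",
    species_column: str = "species",
) -> TraitTable:
    """Read a trait CSV against a declared schema.

    Every coercion failure is reported with its (species, trait) coordinate
    so a malformed compilation can be repaired cell by cell.
    """
    raw = pd.read_csv(
        csv_path, dtype=str, keep_default_na=False, na_values=[missing_token]
    )
    if species_column not in raw.columns:
        raise TraitTableError(f"CSV lacks species column {species_column!r}")
    raw = raw.set_index(species_column)
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique())
        raise TraitTableError(f"duplicate species IDs in CSV: {dups}")

    cols: dict[str, pd.Series] = {}
    errors: list[str] = []
    for spec in schema:
        if spec.name not in raw.columns:
            raise TraitTableError(f"CSV lacks column {spec.name!r}")
        col = raw[spec.name]
        if spec.is_numeric:
            parsed = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & parsed.isna()
            for sp in col.index[bad]:
                errors.append(
                    f"cell ({sp!r}, {spec.name!r}): cannot parse {col[sp]!r} as {spec.dtype}"
                )
            if spec.dtype == "count":
                vals = parsed.dropna()
                badc = vals[(vals < 0) | (vals != np.floor(vals))]
                for sp, v in badc.items():
                    errors.append(
                        f"cell ({sp!r}, {spec.name!r}): {v!r} is not a non-negative integer"
                    )
                    parsed[sp] = np.nan
            cols[spec.name] = parsed.astype(float)
        else:
            vals = col[col.notna()]
            bad = vals[~vals.isin(spec.categories)]
            for sp, v in bad.items():
                errors.append(
                    f"cell ({sp!r}, {spec.name!r}): unknown category {v!r} "
                    f"(expected one of {list(spec.categories)})"
                )
            cols[spec.name] = col.where(col.notna(), None)
    if errors:
        raise TraitTableError("invalid cells:\n  " + "\n  ".join(errors))
    data = pd.DataFrame(cols, index=raw.index)
    data.index.name = species_column
    return TraitTable(data=data, specs=tuple(schema))


def write_trait_table(table: TraitTable, csv_path, missing_token: str = "NA") -> None:
    out = table.data.copy()
    out.index.name = out.index.name or "species"
    out.to_csv(csv_path, na_rep=missing_token)


# ---------------------------------------------------------------------------
# Screening rules


def detect_severe_outliers(values: Sequence[float]) -> set[int]:
    """Indices of values strictly above Q3 + 3*IQR (type-7 quantiles).

    Missing (NaN) entries are ignored and never flagged.  At least four
    observed values are required for the quartiles to be meaningful.
    """
    arr = np.asarray(values, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size < 4:
        raise TraitTableError("need at least 4 observed values for the outlier screen")
    q1, q3 = np.quantile(obs, [0.25, 0.75])  # linear interpolation = type 7
    threshold = q3 + 3.0 * (q3 - q1)
    return {i for i, v in enumerate(arr) if not np.isnan(v) and v > threshold}


def screen_class_imbalance(
    values: Sequence, dominance_threshold: float = 0.90
) -> bool:
    """True = keep, False = exclude (modal share strictly above threshold).

    A categorical trait in which one category holds more than 90% of the
    observed values carries too little signal to impute or score usefully.
    """
    ser = pd.Series(list(values))
    obs = ser[ser.notna()]
    if obs.empty:
        raise TraitTableError("class-imbalance screen on an all-missing trait")
    share = obs.value_counts(normalize=True).iloc[0]
    return not (share > dominance_threshold)


def build_near_complete_case(
    table: TraitTable,
    max_missing_per_trait: float = 0.10,
    min_observed_other: int = 3,
) -> TraitTable:
    """Row-filter a table down to a near-complete-case subset.

    Rules: (a) every trait ends with missingness <= ``max_missing_per_trait``;
    (b) any retained row with a missing cell has at least
    ``min_observed_other`` observed values among the other traits.  Rows
    violating (b) are dropped first; then rows with the most missing cells
    are dropped greedily (ties by species ID) until (a) holds.
    """
    traits = table.trait_names
    df = table.data[traits]
    mask = df.isna()

    observed_per_row = (~mask).sum(axis=1)
    has_missing = mask.any(axis=1)
    # rule (b): for a row with a missing target cell, the observed values all
    # sit in *other* traits, so its other-trait count equals observed_per_row
    keep = list(df.index[~has_missing | (observed_per_row >= min_observed_other)])
    if not keep:
        raise TraitTableError("near-complete-case subset is empty")

    def worst_trait_excess(rows: list[str]) -> float:
        sub = mask.loc[rows]
        return float((sub.mean(axis=0) - max_missing_per_trait).max())

    rows = keep
    while worst_trait_excess(rows) > 1e-12:
        sub = mask.loc[rows]
        n_missing = sub.sum(axis=1)
        gappy = n_missing[n_missing > 0]
        if gappy.empty:
            raise TraitTableError(
                "cannot satisfy per-trait missingness cap: no gappy rows left"
            )
        worst = gappy.max()
        candidates = sorted(gappy.index[gappy == worst])
        rows = [r for r in rows if r != candidates[0]]
        if not rows:
            raise TraitTableError("near-complete-case subset is empty")
    return table.subset(rows)


# ---------------------------------------------------------------------------
# Transforms


def apply_transforms(table: TraitTable) -> TraitTable:
    """Move numeric traits to the model scale (natural log where declared).

    Imputation operates on this scale; :func:`invert_transforms` maps a
    completed table back for reporting.
    """
    if table.transformed:
        return table.copy()
    out = table.data.copy()
    for spec in table.specs:
        if spec.transform == "natural_log":
            col = out[spec.name]
            bad = col[col.notna() & (col <= 0)]
            if len(bad):
                raise TraitTableError(
                    f"natural_log trait {spec.name!r}: non-positive value "
                    f"{bad.iloc[0]!r} for species {bad.index[0]!r}"
                )
            out[spec.name] = np.log(col)
    return TraitTable(
        data=out, specs=table.specs, aux_columns=table.aux_columns, transformed=True
    )


def invert_transforms(table: TraitTable, round_counts: bool = False) -> TraitTable:
    """Undo :func:`apply_transforms`.

    Count traits are left non-integer after exponentiation unless
    ``round_counts`` is set (evaluation happens on the model scale, so the
    raw back-transform is usually what a report wants).
    """
    if not table.transformed:
        return table.copy()
    out = table.data.copy()
    for spec in table.specs:
        if spec.transform == "natural_log":
            out[spec.name] = np.exp(out[spec.name])
            if spec.dtype == "count" and round_counts:
                out[spec.name] = np.round(out[spec.name])
    return TraitTable(
        data=out,
        specs=table.specs,
        aux_columns=table.aux_columns,
        transformed=False,
        strict_counts=round_counts,
    )
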
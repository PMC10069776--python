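"""Simulated missingness: MCAR, MAR and MNAR mask plans over a trait table.

Masks are expressed as :class:`MaskPlan` objects — explicit sets of
(species, trait) cells that were observed in the source table and are to be
blanked for one replicate.  Keeping the plan separate from the table makes
every replicate replayable and lets the same masks be applied across all
candidate imputation methods, which is what makes the method comparison fair.

Mechanisms
----------
MCAR
    Per trait, exactly round(p * n) observed cells are drawn uniformly, and
    the plans for increasing proportions are *nested*: each step adds cells
    on top of the previous plan, so differences between proportions reflect
    the amount of missingness rather than which species went missing.
MAR
    A logistic regression of the missingness indicator on auxiliary traits
    is fitted to a large gappy reference table; significant predictors are
    kept and the refitted model drives Bernoulli deletions in the target
    table, with the intercept shifted so the expected number of masked
    cells matches a configured proportion.
MNAR
    Deterministic worst-case deletion: the configured tail of a numeric
    trait's distribution (lower, upper, or centred on zero via absolute
    value), or a configured fraction of one category of a categorical trait.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq

from .traits import TraitTable, TraitTableError

__all__ = [
    "MaskPlan",
    "MissingnessModel",
    "NoSignificantPredictor",
    "mask_mcar",
    "fit_mar_model",
    "mask_mar",
    "mask_mnar",
    "apply_mask",
]


def _round_half_away(x: float) -> int:
    """Deterministic rounding, half away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class MaskPlan:
    """Cells deliberately masked in one simulated-missingness replicate."""

    mechanism: str  # MCAR | MAR | MNAR
    proportion_label: str  # e.g. "0.10", or "n/a" for MNAR
    cells: frozenset  # of (species, trait)
    replicate_id: int
    seed: int

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise TraitTableError(f"unknown mechanism {self.mechanism!r}")

    def cells_for(self, trait: str) -> list[str]:
        return sorted(sp for sp, tr in self.cells if tr == trait)

    def traits(self) -> list[str]:
        return sorted({tr for _, tr in self.cells})

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.cells)
        return pd.DataFrame(
            {
                "mechanism": self.mechanism,
                "proportion": self.proportion_label,
                "replicate": self.replicate_id,
                "species": [r[0] for r in rows],
                "trait": [r[1] for r in rows],
                "seed": self.seed,
            }
        )


def _check_plan_cells(table: TraitTable, cells) -> None:
    for sp, tr in cells:
        if pd.isna(table.data.at[sp, tr]):
            raise TraitTableError(f"mask targets an already-missing cell ({sp!r}, {tr!r})")


def apply_mask(table: TraitTable, plan: MaskPlan) -> TraitTable:
    """Blank the plan's cells; every targeted cell must be observed."""
    _check_plan_cells(table, plan.cells)
    out = table.copy()
    for sp, tr in plan.cells:
        out.data.at[sp, tr] = np.nan if table.spec(tr).is_numeric else None
    return out


# ---------------------------------------------------------------------------
# MCAR


def mask_mcar(
    table: TraitTable,
    proportions: Sequence[float],
    traits: Sequence[str] | None = None,
    replicate_seed: int = 0,
    replicate_id: int = 0,
) -> list[MaskPlan]:
    """Nested MCAR plans, one per proportion (round(p * n) cells per trait).

    Pre-existing missing cells count toward neither the proportion nor the
    maskable pool: p is *additional* missingness on top of what is already
    absent.
    """
    props = list(proportions)
    if any(not (0 < p <= 1) for p in props):
        raise TraitTableError("MCAR proportions must lie in (0, 1]")
    if any(b <= a for a, b in zip(props, props[1:])):
        raise TraitTableError("MCAR proportions must be strictly increasing")
    traits = list(traits) if traits is not None else table.trait_names
    n = table.n_species
    rng = np.random.default_rng(replicate_seed)

    per_trait_orders: dict[str, list[str]] = {}
    for tr in traits:
        observed = table.observed_cells(tr)
        need = _round_half_away(props[-1] * n)
        if len(observed) < need:
            raise TraitTableError(
                f"trait {tr!r}: only {len(observed)} observed cells but "
                f"{need} needed at proportion {props[-1]}"
            )
        order = list(rng.permutation(observed))
        per_trait_orders[tr] = order

    plans = []
    for p in props:
        cells = set()
        for tr in traits:
            take = _round_half_away(p * n)
            cells.update((sp, tr) for sp in per_trait_orders[tr][:take])
        plans.append(
            MaskPlan(
                mechanism="MCAR",
                proportion_label=f"{p:.2f}",
                cells=frozenset(cells),
                replicate_id=replicate_id,
                seed=replicate_seed,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# MAR


class NoSignificantPredictor(Exception):
    """No auxiliary trait predicts this trait's missingness: MAR-ineligible."""


@dataclass
class MissingnessModel:
    """Fitted logistic model for one trait's missingness indicator."""

    target_trait: str
    predictors: list[str]
    coefficients: Mapping[str, float]  # includes "intercept"
    alpha: float
    design_columns: list[str] = field(default_factory=list)

    def linear_predictor(self, table: TraitTable) -> pd.Series:
        X, idx = _design_matrix(table, self.predictors)
        lp = pd.Series(self.coefficients["intercept"], index=idx)
        for col in self.design_columns:
            lp += self.coefficients[col] * X[col]
        return lp


def _design_matrix(table: TraitTable, predictors: Sequence[str]):
    """Numeric design frame over rows where all predictors are observed.

    Categorical predictors are dummy-coded against their first declared
    category.
    """
    sub = table.data[list(predictors)].dropna()
    cols = {}
    for name in predictors:
        spec = table.spec(name)
        if spec.is_numeric:
            cols[name] = sub[name].astype(float)
        else:
            for cat in spec.categories[1:]:
                cols[f"{name}[{cat}]"] = (sub[name] == cat).astype(float)
    X = pd.DataFrame(cols, index=sub.index)
    return X, sub.index


def _coef_names(table: TraitTable, aux: str) -> list[str]:
    spec = table.spec(aux)
    if spec.is_numeric:
        return [aux]
    return [f"{aux}[{c}]" for c in spec.categories[1:]]


def fit_mar_model(
    reference: TraitTable,
    target_trait: str,
    alpha: float = 0.05,
) -> MissingnessModel:
    """Fit missing(target) ~ auxiliaries by logistic regression on a reference.

    Predictors whose every coefficient has p >= alpha are dropped and the
    model refitted on the survivors.  Raises
    :class:`NoSignificantPredictor` when nothing survives — the trait is
    then ineligible for MAR simulation.
    """
    if target_trait not in reference.trait_names:
        raise TraitTableError(f"unknown trait {target_trait!r}")
    indicator = reference.data[target_trait].isna().astype(float)
    if indicator.sum() == 0:
        raise TraitTableError(f"trait {target_trait!r} has no missing cells in reference")
    auxiliaries = [t for t in reference.trait_names if t != target_trait]

    def _fit(predictors):
        X, idx = _design_matrix(reference, predictors)
        y = indicator.loc[idx]
        if y.nunique() < 2:
            raise TraitTableError(
                f"missingness of {target_trait!r} constant on complete-predictor rows"
            )
        Xc = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
        # perfect separation inflates coefficients without bound; report and
        # drop the offending predictor rather than trusting its p-value
        separated = [
            aux
            for aux in predictors
            if any(
                abs(res.params.get(nm, 0.0)) > 15.0
                for nm in _coef_names(reference, aux)
            )
        ]
        if separated:
            warnings.warn(
                f"MAR fit for {target_trait!r}: perfect separation in "
                f"{separated}; predictor(s) dropped"
            )
            remaining = [p for p in predictors if p not in separated]
            if not remaining:
                raise NoSignificantPredictor(target_trait)
            return _fit(remaining)
        return res, X

    dropped = []
    usable = []
    for aux in auxiliaries:
        col = reference.data[aux]
        if col.dropna().nunique() <= 1:
            dropped.append((aux, "constant"))
            continue
        usable.append(aux)
    res, X = _fit(usable)
    keep = []
    for aux in usable:
        spec = reference.spec(aux)
        names = (
            [aux] if spec.is_numeric else [f"{aux}[{c}]" for c in spec.categories[1:]]
        )
        pvals = [res.pvalues.get(nm, 1.0) for nm in names]
        if any(p < alpha for p in pvals):
            keep.append(aux)
    if not keep:
        raise NoSignificantPredictor(target_trait)
    res, X = _fit(keep)
    coefs = {"intercept": float(res.params["const"])}
    for col in X.columns:
        coefs[col] = float(res.params[col])
    return MissingnessModel(
        target_trait=target_trait,
        predictors=keep,
        coefficients=coefs,
        alpha=alpha,
        design_columns=list(X.columns),
    )


def mask_mar(
    table: TraitTable,
    model: MissingnessModel,
    target_proportion: float = 0.20,
    replicate_seed: int = 0,
    replicate_id: int = 0,
) -> MaskPlan:
    """Bernoulli deletions driven by the fitted model's probabilities.

    The intercept is shifted (root-finding on the expected count) so that
    the expected number of masked cells equals round(p * n); the covariate
    dependence of the fitted model is preserved.
    """
    if not (0 < target_proportion < 1):
        raise TraitTableError("target_proportion must be in (0, 1)")
    tr = model.target_trait
    lp = model.linear_predictor(table)
    observed = set(table.observed_cells(tr))
    eligible = lp.index[lp.index.isin(observed)]
    lp = lp.loc[eligible]
    n = table.n_species
    target = _round_half_away(target_proportion * n)
    if target > len(lp):
        raise TraitTableError(
            f"target count {target} exceeds {len(lp)} eligible cells for {tr!r}"
        )

    def expected(shift: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(lp.values + shift)))).sum())

    shift = brentq(lambda s: expected(s) - target, -40.0, 40.0, xtol=1e-10)
    probs = 1.0 / (1.0 + np.exp(-(lp.values + shift)))
    rng = np.random.default_rng(replicate_seed)
    draws = rng.random(len(probs)) < probs
    cells = frozenset((sp, tr) for sp, hit in zip(lp.index, draws) if hit)
    return MaskPlan(
        mechanism="MAR",
        proportion_label=f"{target_proportion:.2f}",
        cells=cells,
        replicate_id=replicate_id,
        seed=replicate_seed,
    )


# ---------------------------------------------------------------------------
# MNAR


def mask_mnar(
    table: TraitTable,
    trait: str,
    tail_spec: Mapping | None = None,
    replicate_seed: int = 0,
    replicate_id: int = 0,
) -> MaskPlan:
    """Worst-case biased deletion in one trait.

    Numeric: cells whose (optionally |.|-transformed) values fall at or
    below the tail quantile (``side``: lower / upper / center-on-zero,
    ``fraction`` default 0.10).  Categorical: a ``fraction`` (default 1.0)
    of the observed cells of the named ``category``, sampled uniformly when
    below 1.
    """
    spec = table.spec(trait)
    tail = dict(tail_spec) if tail_spec is not None else dict(spec.mnar_tail or {})
    col = table.data[trait]
    obs = col[col.notna()]
    if obs.empty:
        raise TraitTableError(f"trait {trait!r} fully missing")

    if spec.is_numeric:
        side = tail.get("side", "lower")
        fraction = float(tail.get("fraction", 0.10))
        vals = obs.astype(float)
        if side == "upper":
            scores = -vals
        elif side == "lower":
            scores = vals
        elif side == "center-on-zero":
            scores = vals.abs()
        else:
            raise TraitTableError(f"unknown tail side {side!r}")
        cutoff = np.quantile(scores.values, fraction)  # type-7 quantile
        chosen = scores.index[scores.values <= cutoff]
        if len(chosen) == 0:
            raise TraitTableError(f"empty tail for trait {trait!r}")
        cells = frozenset((sp, trait) for sp in chosen)
    else:
        category = tail.get("category")
        if category not in spec.categories:
            raise TraitTableError(
                f"unknown category {category!r} for trait {trait!r}"
            )
        fraction = float(tail.get("fraction", 1.0))
        pool = sorted(obs.index[obs == category])
        if not pool:
            raise TraitTableError(f"no observed {category!r} cells in trait {trait!r}")
        if fraction >= 1.0:
            chosen = pool
        else:
            k = max(1, _round_half_away(fraction * len(pool)))
            rng = np.random.default_rng(replicate_seed)
            chosen = sorted(rng.choice(pool, size=k, replace=False))
        cap = tail.get("cap")
        if cap is not None and len(chosen) > int(cap):
            chosen = chosen[: int(cap)]
        cells = frozenset((sp, trait) for sp in chosen)
    return MaskPlan(
        mechanism="MNAR",
        proportion_label="n/a",
        cells=cells,
        replicate_id=replicate_id,
        seed=replicate_seed,
    )
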
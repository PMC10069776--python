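"""The four candidate imputation methods for mixed-type trait tables.

* mean/mode — the baseline: column mean for numeric traits, modal category
  for categorical ones.
* KNN — Gower-distance k-nearest-neighbour with median/mode aggregation
  over the donors.
* RF — iterative random-forest imputation (missForest-style): initialise by
  mean/mode, then repeatedly re-fit a forest per trait on the currently
  completed predictors until the imputed values stop improving.
* MICE — chained equations with predictive mean matching for numeric
  traits, logistic draws for binary and multinomial-logit draws for
  multicategorical traits, repeated m times and pooled (mean / mode).

All methods accept a per-target predictor map produced by
:func:`select_auxiliary_traits` (single-covariate association screening with
the regression family matched to the target's type) and treat appended
phylogenetic eigenvector columns as always-included extra predictors.
Observed cells are never altered; every imputer is deterministic given
(table, config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression

from .phylo import EigenvectorSet
from .traits import TraitTable, TraitTableError

__all__ = [
    "ImputationConfig",
    "ImputedTable",
    "select_auxiliary_traits",
    "impute_mean_mode",
    "impute_knn",
    "impute_missforest",
    "impute_mice",
    "impute",
    "augment_with_eigenvectors",
    "tune_parameters",
]

METHODS = ("mean_mode", "knn", "rf", "mice")


@dataclass(frozen=True)
class ImputationConfig:
    """A candidate method plus its parameters and phylogeny source."""

    method: str
    k_neighbors: int = 5
    n_trees: int = 100
    max_iterations: int = 10
    m_imputations: int = 5
    donor_pool_k: int = 5
    chain_iterations: int = 5
    phylogeny_source: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise TraitTableError(f"unknown method {self.method!r}")
        if self.method == "mean_mode" and self.phylogeny_source != "none":
            raise TraitTableError("mean_mode has no phylogenetic variant")
        for name in (
            "k_neighbors",
            "n_trees",
            "max_iterations",
            "m_imputations",
            "donor_pool_k",
            "chain_iterations",
        ):
            if getattr(self, name) < 1:
                raise TraitTableError(f"{name} must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.method}+{self.phylogeny_source}"


@dataclass
class ImputedTable:
    """A completed table plus provenance of every filled cell."""

    table: TraitTable
    imputed_cells: frozenset  # of (species, trait)
    config: ImputationConfig
    per_imputation_values: dict = field(default_factory=dict)  # cell -> list

    def value(self, species: str, trait: str):
        return self.table.data.at[species, trait]


# ---------------------------------------------------------------------------
# Predictor screening


def _mode(series: pd.Series) -> str:
    """Modal category; ties broken by lexicographically smallest label."""
    counts = series.value_counts()
    top = counts[counts == counts.iloc[0]]
    return sorted(top.index)[0]


def select_auxiliary_traits(
    table: TraitTable, target: str, alpha: float = 0.05, min_overlap: int = 20
) -> list[str]:
    """Screen auxiliary traits for association with the target.

    One single-covariate regression per auxiliary, the family chosen by the
    target's type: linear (continuous), Poisson (count), logistic (binary)
    or multinomial logit (multicategorical).  An auxiliary is retained iff
    any of its coefficients has p < alpha.  Constant and non-convergent
    auxiliaries are skipped with a warning.
    """
    spec = table.spec(target)
    y_raw = table.data[target].dropna()
    kept: list[str] = []
    for aux in table.trait_names:
        if aux == target:
            continue
        aux_spec = table.spec(aux)
        sub = table.data[[target, aux]].dropna()
        if len(sub) < min_overlap:
            raise TraitTableError(
                f"targets {target!r}/{aux!r}: only {len(sub)} overlapping rows "
                f"(need >= {min_overlap})"
            )
        x = sub[aux]
        if x.nunique() <= 1:
            warnings.warn(f"auxiliary {aux!r} constant on overlap; skipped")
            continue
        if aux_spec.is_numeric:
            X = pd.DataFrame({aux: x.astype(float)})
        else:
            X = pd.DataFrame(
                {
                    f"{aux}[{c}]": (x == c).astype(float)
                    for c in aux_spec.categories[1:]
                    if (x == c).any()
                }
            )
            if X.empty:
                warnings.warn(f"auxiliary {aux!r} single-level on overlap; skipped")
                continue
        Xc = sm.add_constant(X, has_constant="add")
        y = sub[target]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if spec.dtype == "continuous":
                    res = sm.OLS(y.astype(float), Xc).fit()
                    pvals = res.pvalues.drop("const")
                elif spec.dtype == "count":
                    counts = y.astype(float)
                    if table.transformed and spec.transform == "natural_log":
                        counts = np.round(np.exp(counts))
                    res = sm.GLM(counts, Xc, family=sm.families.Poisson()).fit()
                    pvals = res.pvalues.drop("const")
                elif spec.dtype == "binary":
                    yb = (y == spec.categories[1]).astype(float)
                    res = sm.GLM(yb, Xc, family=sm.families.Binomial()).fit()
                    pvals = res.pvalues.drop("const")
                else:  # multicategorical
                    codes = pd.Categorical(y, categories=spec.categories).codes
                    res = sm.MNLogit(np.asarray(codes), Xc.values).fit(disp=0)
                    frame = pd.DataFrame(res.pvalues)
                    frame.index = Xc.columns
                    pvals = frame.drop("const").values.ravel()
                    pvals = pd.Series(pvals).dropna()
        except Exception as exc:
            warnings.warn(f"association fit failed for {target!r} ~ {aux!r}: {exc}")
            continue
        if (np.asarray(pvals) < alpha).any():
            kept.append(aux)
    return kept


# ---------------------------------------------------------------------------
# Shared helpers


def _imputable_traits(table: TraitTable) -> list[str]:
    """Trait columns with missing cells, ordered by increasing missingness."""
    fracs = [(table.missing_fraction(t), t) for t in table.trait_names]
    return [t for f, t in sorted(fracs) if f > 0]


def _predictor_columns(
    table: TraitTable, target: str, predictors: Mapping[str, Sequence[str]] | None
) -> list[str]:
    """Predictor traits for ``target`` plus every eigenvector aux column.

    When screening retained nothing (and no eigenvectors are appended),
    fall back to all other traits: an unscreened model beats leaving the
    trait at its random/mean initialisation.
    """
    if predictors is None:
        cols = [t for t in table.trait_names if t != target]
    else:
        cols = [t for t in predictors.get(target, []) if t != target]
    out = cols + list(table.aux_columns)
    if not out:
        out = [t for t in table.trait_names if t != target]
    return out


def _encode(table: TraitTable, rows: pd.Index, cols: Sequence[str]) -> pd.DataFrame:
    """Numeric design frame (dummy-coded categoricals, first level dropped)."""
    out = {}
    for name in cols:
        if name in table.aux_columns:
            out[name] = table.data.loc[rows, name].astype(float)
            continue
        spec = table.spec(name)
        if spec.is_numeric:
            out[name] = table.data.loc[rows, name].astype(float)
        else:
            col = table.data.loc[rows, name]
            for cat in spec.categories[1:]:
                out[f"{name}[{cat}]"] = (col == cat).astype(float)
    return pd.DataFrame(out, index=rows)


def _finalize(
    source: TraitTable, completed: pd.DataFrame, config: ImputationConfig, per_imp=None
) -> ImputedTable:
    cells = set()
    mask = source.missing_mask()
    for tr in source.trait_names:
        for sp in mask.index[mask[tr]]:
            cells.add((sp, tr))
    out = TraitTable(
        data=completed,
        specs=source.specs,
        aux_columns=source.aux_columns,
        transformed=source.transformed,
    )
    return ImputedTable(
        table=out,
        imputed_cells=frozenset(cells),
        config=config,
        per_imputation_values=per_imp or {},
    )


# ---------------------------------------------------------------------------
# mean / mode


def impute_mean_mode(
    table: TraitTable, config: ImputationConfig | None = None
) -> ImputedTable:
    config = config or ImputationConfig(method="mean_mode")
    data = table.data.copy()
    for spec in table.specs:
        col = data[spec.name]
        if not col.isna().any():
            continue
        obs = col.dropna()
        if obs.empty:
            raise TraitTableError(f"trait {spec.name!r} fully missing")
        fill = float(obs.mean()) if spec.is_numeric else _mode(obs)
        data[spec.name] = col.fillna(fill)
    return _finalize(table, data, config)


# ---------------------------------------------------------------------------
# KNN (Gower)


def gower_distances(
    table: TraitTable, cols: Sequence[str], query: pd.Index, donors: pd.Index
) -> pd.DataFrame:
    """Gower dissimilarity between query rows and donor rows over ``cols``.

    Numeric columns contribute |xi - xj| / range (range over the observed
    column); categorical columns contribute a 0/1 mismatch.  Pairs missing
    either value are excluded and the remaining contributions averaged.
    """
    contribs = []
    avail = []
    for name in cols:
        is_num = name in table.aux_columns or table.spec(name).is_numeric
        qv = table.data.loc[query, name]
        dv = table.data.loc[donors, name]
        if is_num:
            allv = table.data[name].dropna().astype(float)
            rng = float(allv.max() - allv.min()) if len(allv) else 0.0
            q = qv.astype(float).values[:, None]
            d = dv.astype(float).values[None, :]
            diff = np.abs(q - d)
            c = diff / rng if rng > 0 else np.zeros_like(diff)
        else:
            q = qv.values[:, None]
            d = dv.values[None, :]
            c = (q != d).astype(float)
        ok = (~pd.isna(qv).values[:, None]) & (~pd.isna(dv).values[None, :])
        c = np.where(ok, c, 0.0)
        contribs.append(c)
        avail.append(ok.astype(float))
    num = np.sum(contribs, axis=0)
    den = np.sum(avail, axis=0)
    with np.errstate(invalid="ignore"):
        dist = np.where(den > 0, num / den, np.nan)
    return pd.DataFrame(dist, index=query, columns=donors)


def impute_knn(
    table: TraitTable,
    predictors: Mapping[str, Sequence[str]] | None = None,
    k_neighbors: int = 5,
    config: ImputationConfig | None = None,
) -> ImputedTable:
    """Gower k-nearest-neighbour imputation (median / mode over donors)."""
    config = config or ImputationConfig(method="knn", k_neighbors=k_neighbors)
    k = config.k_neighbors
    data = table.data.copy()
    for tr in _imputable_traits(table):
        spec = table.spec(tr)
        col = table.data[tr]
        donors = col.index[col.notna()]
        targets = col.index[col.isna()]
        if donors.empty:
            raise TraitTableError(f"trait {tr!r}: no donor rows")
        if k > len(donors):
            raise TraitTableError(f"trait {tr!r}: k={k} exceeds {len(donors)} donors")
        cols = _predictor_columns(table, tr, predictors)
        if not cols:
            raise TraitTableError(f"trait {tr!r}: no predictors for KNN")
        dist = gower_distances(table, cols, targets, donors)
        all_cols = [t for t in table.trait_names if t != tr] + list(table.aux_columns)
        for sp in targets:
            row = dist.loc[sp]
            if row.isna().all() and cols != all_cols:
                # no overlap on the screened predictors: widen to all columns
                row = gower_distances(table, all_cols, pd.Index([sp]), donors).iloc[0]
            if row.isna().all():
                # row observed for nothing at all: degenerate to median/mode
                vals = col.loc[donors]
                data.at[sp, tr] = (
                    float(vals.astype(float).median())
                    if spec.is_numeric
                    else _mode(vals)
                )
                continue
            row = row.dropna()
            # stable order: by distance, then donor ID, for determinism
            order = sorted(row.index, key=lambda d: (row[d], str(d)))
            chosen = order[:k]
            vals = col.loc[chosen]
            if spec.is_numeric:
                data.at[sp, tr] = float(vals.astype(float).median())
            else:
                data.at[sp, tr] = _mode(vals)
    return _finalize(table, data, config)


# ---------------------------------------------------------------------------
# missForest-style iterative random forest


def impute_missforest(
    table: TraitTable,
    predictors: Mapping[str, Sequence[str]] | None = None,
    n_trees: int = 100,
    max_iterations: int = 10,
    seed: int = 0,
    config: ImputationConfig | None = None,
) -> ImputedTable:
    """Iterative random-forest imputation with the missForest stopping rule.

    Stops when the difference criterion (normalised squared change over
    numeric imputed cells; proportion of changed categorical cells)
    increases for both families, returning the previous iterate.
    """
    config = config or ImputationConfig(
        method="rf", n_trees=n_trees, max_iterations=max_iterations, seed=seed
    )
    rng = np.random.default_rng(config.seed)
    mask = table.missing_mask()
    traits = _imputable_traits(table)
    if not traits:
        return _finalize(table, table.data.copy(), config)
    if len(table.trait_names) < 2 and not table.aux_columns:
        raise TraitTableError("random-forest imputation needs >= 2 columns")

    current = impute_mean_mode(table).table  # warm start
    num_traits = [t for t in traits if table.spec(t).is_numeric]
    cat_traits = [t for t in traits if table.spec(t).is_categorical]
    prev_crit = (np.inf, np.inf)
    for _ in range(config.max_iterations):
        new = current.copy()
        for tr in traits:
            spec = table.spec(tr)
            cols = _predictor_columns(table, tr, predictors)
            if not cols:
                continue
            obs_rows = mask.index[~mask[tr]]
            mis_rows = mask.index[mask[tr]]
            X_obs = _encode(new, obs_rows, cols)
            X_mis = _encode(new, mis_rows, cols)
            y_obs = table.data.loc[obs_rows, tr]
            rs = int(rng.integers(0, 2**31 - 1))
            try:
                if spec.is_numeric:
                    model = RandomForestRegressor(
                        n_estimators=config.n_trees,
                        max_features=1.0 / 3.0,
                        random_state=rs,
                        n_jobs=1,
                    )
                    model.fit(X_obs.values, y_obs.astype(float).values)
                    pred = model.predict(X_mis.values)
                else:
                    model = RandomForestClassifier(
                        n_estimators=config.n_trees,
                        max_features="sqrt",
                        random_state=rs,
                        n_jobs=1,
                    )
                    model.fit(X_obs.values, y_obs.values)
                    pred = model.predict(X_mis.values)
            except Exception as exc:
                raise TraitTableError(f"forest fit failed for trait {tr!r}: {exc}")
            for sp, v in zip(mis_rows, pred):
                new.data.at[sp, tr] = float(v) if spec.is_numeric else v

        # missForest difference criterion over imputed cells only
        num_crit = 0.0
        if num_traits:
            delta = sq = 0.0
            for tr in num_traits:
                mis_rows = mask.index[mask[tr]]
                a = new.data.loc[mis_rows, tr].astype(float).values
                b = current.data.loc[mis_rows, tr].astype(float).values
                delta += float(((a - b) ** 2).sum())
                sq += float((a**2).sum())
            num_crit = delta / sq if sq > 0 else 0.0
        cat_crit = 0.0
        if cat_traits:
            changed = total = 0
            for tr in cat_traits:
                mis_rows = mask.index[mask[tr]]
                a = new.data.loc[mis_rows, tr].values
                b = current.data.loc[mis_rows, tr].values
                changed += int((a != b).sum())
                total += len(mis_rows)
            cat_crit = changed / total if total else 0.0
        crit = (num_crit, cat_crit)
        worse_num = (not num_traits) or crit[0] > prev_crit[0]
        worse_cat = (not cat_traits) or crit[1] > prev_crit[1]
        if worse_num and worse_cat:
            # criterion rose for both families: keep the previous iterate
            return _finalize(table, current.data.copy(), config)
        prev_crit = crit
        current = new
    return _finalize(table, current.data.copy(), config)


# ---------------------------------------------------------------------------
# MICE with predictive mean matching


def _pmm_fill(
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    X_mis: np.ndarray,
    donor_k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Predictive mean matching: linear fit, nearest-fitted-mean donors."""
    A = np.column_stack([np.ones(len(X_obs)), X_obs])
    coef, *_ = np.linalg.lstsq(A, y_obs, rcond=None)
    fitted = A @ coef
    pred = np.column_stack([np.ones(len(X_mis)), X_mis]) @ coef
    out = np.empty(len(X_mis))
    k = min(donor_k, len(y_obs))
    for i, p in enumerate(pred):
        gaps = np.abs(fitted - p)
        pool = np.argsort(gaps, kind="stable")[:k]
        out[i] = y_obs[pool[rng.integers(0, k)]]
    return out


def _logit_draw(
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    X_mis: np.ndarray,
    categories: Sequence[str],
    rng: np.random.Generator,
) -> list[str]:
    """Multinomial/logistic draws from fitted category probabilities."""
    present = [c for c in categories if (y_obs == c).any()]
    if len(present) == 1:
        return [present[0]] * len(X_mis)
    model = LogisticRegression(max_iter=1000)
    model.fit(X_obs, y_obs)
    probs = model.predict_proba(X_mis)
    classes = list(model.classes_)
    out = []
    for p in probs:
        out.append(classes[rng.choice(len(classes), p=p / p.sum())])
    return out


def impute_mice(
    table: TraitTable,
    predictors: Mapping[str, Sequence[str]] | None = None,
    m_imputations: int = 5,
    donor_pool_k: int = 5,
    chain_iterations: int = 5,
    seed: int = 0,
    config: ImputationConfig | None = None,
) -> ImputedTable:
    """Chained-equations multiple imputation, pooled to a single table.

    Numeric traits use predictive mean matching (imputed values are always
    members of the trait's observed-value set); binary traits use logistic
    draws; multicategorical traits use multinomial-logit draws.  The m
    completed datasets are pooled by mean (numeric) / mode (categorical).
    """
    config = config or ImputationConfig(
        method="mice",
        m_imputations=m_imputations,
        donor_pool_k=donor_pool_k,
        chain_iterations=chain_iterations,
        seed=seed,
    )
    mask = table.missing_mask()
    traits = _imputable_traits(table)
    if not traits:
        return _finalize(table, table.data.copy(), config)

    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(config.m_imputations)]
    completions: list[pd.DataFrame] = []
    for m in range(config.m_imputations):
        rng = streams[m]
        work = table.copy()
        # initial fill: random draws from each trait's observed values
        for tr in traits:
            col = work.data[tr]
            obs = col.dropna()
            mis_rows = col.index[col.isna()]
            draws = obs.values[rng.integers(0, len(obs), size=len(mis_rows))]
            for sp, v in zip(mis_rows, draws):
                work.data.at[sp, tr] = v
        for _ in range(config.chain_iterations):
            for tr in traits:
                spec = table.spec(tr)
                cols = _predictor_columns(table, tr, predictors)
                if not cols:
                    continue
                obs_rows = mask.index[~mask[tr]]
                mis_rows = mask.index[mask[tr]]
                X_obs = _encode(work, obs_rows, cols).values
                X_mis = _encode(work, mis_rows, cols).values
                if spec.is_numeric:
                    y_obs = table.data.loc[obs_rows, tr].astype(float).values
                    vals = _pmm_fill(X_obs, y_obs, X_mis, config.donor_pool_k, rng)
                    for sp, v in zip(mis_rows, vals):
                        work.data.at[sp, tr] = float(v)
                else:
                    y_obs = table.data.loc[obs_rows, tr].values
                    vals = _logit_draw(X_obs, y_obs, X_mis, spec.categories, rng)
                    for sp, v in zip(mis_rows, vals):
                        work.data.at[sp, tr] = v
        completions.append(work.data.copy())

    pooled = table.data.copy()
    per_imp: dict = {}
    for tr in traits:
        spec = table.spec(tr)
        for sp in mask.index[mask[tr]]:
            vals = [c.at[sp, tr] for c in completions]
            per_imp[(sp, tr)] = vals
            if spec.is_numeric:
                pooled.at[sp, tr] = float(np.mean([float(v) for v in vals]))
            else:
                pooled.at[sp, tr] = _mode(pd.Series(vals))
    return _finalize(table, pooled, config, per_imp)


# ---------------------------------------------------------------------------
# Dispatch, augmentation, tuning


def impute(
    table: TraitTable,
    config: ImputationConfig,
    predictors: Mapping[str, Sequence[str]] | None = None,
) -> ImputedTable:
    """Run the configured method on the table."""
    if config.method == "mean_mode":
        return impute_mean_mode(table, config)
    if config.method == "knn":
        return impute_knn(table, predictors, config=config)
    if config.method == "rf":
        return impute_missforest(table, predictors, config=config)
    return impute_mice(table, predictors, config=config)


def augment_with_eigenvectors(table: TraitTable, evs: EigenvectorSet) -> TraitTable:
    """Append eigenvector columns as fully observed, non-imputable predictors.

    Species lacking eigenvector coordinates are excluded from the returned
    table (phylogenetic runs can only use species present in the tree).
    """
    clash = set(evs.coordinates.columns) & set(table.data.columns)
    if clash:
        raise TraitTableError(f"duplicate column names: {sorted(clash)}")
    common = [s for s in table.species if s in evs.coordinates.index]
    dropped = [s for s in table.species if s not in evs.coordinates.index]
    if dropped:
        warnings.warn(
            f"{len(dropped)} species lack eigenvector coordinates and are "
            f"excluded: {dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    if not common:
        raise TraitTableError("no species overlap with the eigenvector set")
    data = table.data.loc[common].join(evs.coordinates.loc[common])
    return TraitTable(
        data=data,
        specs=table.specs,
        aux_columns=tuple(table.aux_columns) + tuple(evs.coordinates.columns),
        transformed=table.transformed,
    )


def tune_parameters(
    grid: Sequence[ImputationConfig],
    evaluate: Callable[[ImputationConfig], float],
) -> ImputationConfig:
    """Pick the grid point with the lowest mean error.

    Ties are broken by smallest parameter values, then declaration order,
    so the winner is deterministic.
    """
    grid = list(grid)
    if not grid:
        raise TraitTableError("empty parameter grid")
    scored = []
    for order, cfg in enumerate(grid):
        err = float(evaluate(cfg))
        key = (
            err,
            cfg.k_neighbors,
            cfg.n_trees,
            cfg.m_imputations,
            cfg.donor_pool_k,
            cfg.chain_iterations,
            cfg.max_iterations,
            order,
        )
        scored.append((key, cfg))
    return min(scored, key=lambda t: t[0])[1]
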
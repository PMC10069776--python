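"""Synthetic phylogenies and mixed-type trait tables for pipeline testing.

Real squamate-style trait compilations and gene trees cannot be bundled, so
this module generates stand-ins with the same structure: an ultrametric
random tree, latent Brownian-motion trait values with per-trait tunable
phylogenetic signal (Pagel's lambda rescaling) and cross-trait correlation,
and observation links that turn the latent values into continuous, count,
binary or multicategorical traits.  A small fraction of cells can be blanked
completely at random to emulate the pre-existing gaps of a near-complete-case
dataset.

The default specification mirrors a squamate-like table: two log-scale body
size traits, two count (clutch-size-like) traits, one signed latitude-like
trait, a binary insularity trait and a three-level activity-time trait with
realistic class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .phylo import PhyloTree, parse_newick
from .traits import TraitSpec, TraitTable, TraitTableError

__all__ = [
    "SimTrait",
    "SimulationSpec",
    "default_simulation_spec",
    "simulate_tree",
    "simulate_traits",
    "make_worked_example",
]


@dataclass(frozen=True)
class SimTrait:
    """One simulated trait: its declared type plus its generating link.

    ``link`` maps the latent Brownian value to the observed scale:
    ``identity`` (continuous), ``exp_poisson`` (1 + Poisson with a
    log-linear rate, giving right-skewed strictly positive counts) or
    ``threshold`` (cut the latent value at the empirical quantiles in
    ``thresholds`` to produce the declared categories).
    """

    name: str
    dtype: str
    signal_lambda: float = 1.0
    link: str = "identity"
    transform: str = "none"
    categories: tuple[str, ...] = ()
    thresholds: tuple[float, ...] = ()
    loc: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal_lambda <= 1.0):
            raise TraitTableError("signal_lambda must lie in [0, 1]")
        if self.link not in ("identity", "exp_poisson", "threshold"):
            raise TraitTableError(f"unknown link {self.link!r}")
        if self.link == "threshold":
            if len(self.thresholds) != len(self.categories) - 1:
                raise TraitTableError(
                    f"trait {self.name!r}: need one threshold per category boundary"
                )
            if any(not (0 < q < 1) for q in self.thresholds) or list(
                self.thresholds
            ) != sorted(self.thresholds):
                raise TraitTableError("thresholds must be increasing quantiles in (0,1)")

    def trait_spec(self) -> TraitSpec:
        return TraitSpec(
            name=self.name,
            dtype=self.dtype,
            categories=self.categories,
            transform=self.transform,
        )


@dataclass(frozen=True)
class SimulationSpec:
    n_taxa: int = 152
    tree_model: str = "yule"  # yule | birth_death
    birth_rate: float = 1.0
    death_rate: float = 0.0
    traits: tuple[SimTrait, ...] = ()
    correlation: np.ndarray | None = None  # over latent traits, unit diagonal
    pre_missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise TraitTableError("need at least 3 taxa")
        if self.tree_model not in ("yule", "birth_death"):
            raise TraitTableError(f"unknown tree model {self.tree_model!r}")
        if not (0.0 <= self.pre_missing_fraction <= 0.10):
            raise TraitTableError("pre_missing_fraction must lie in [0, 0.10]")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            p = len(self.traits)
            if R.shape != (p, p):
                raise TraitTableError("correlation shape must match trait count")
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise TraitTableError("correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-10:
                raise TraitTableError("correlation matrix must be PSD")


def default_simulation_spec(
    n_taxa: int = 152,
    signal_lambda: float = 0.9,
    pre_missing_fraction: float = 0.05,
    seed: int = 0,
) -> SimulationSpec:
    """Squamate-like default: 5 numeric + 1 binary + 1 three-level trait.

    All traits share the same generating lambda by default so the signal
    regime is a single dial; the correlation matrix links the body-size and
    clutch traits the way real morphometric compilations tend to.
    """
    traits = (
        SimTrait("svl_female", "continuous", signal_lambda, "identity",
                 transform="natural_log", loc=4.2, scale=0.6),
        SimTrait("svl_max", "continuous", signal_lambda, "identity",
                 transform="natural_log", loc=4.5, scale=0.6),
        SimTrait("clutch_largest", "count", signal_lambda, "exp_poisson",
                 transform="natural_log", loc=1.2, scale=0.7),
        SimTrait("clutch_smallest", "count", signal_lambda, "exp_poisson",
                 transform="natural_log", loc=0.3, scale=0.5),
        SimTrait("latitude", "continuous", signal_lambda, "identity",
                 transform="none", loc=5.0, scale=18.0),
        SimTrait("insular", "binary", signal_lambda, "threshold",
                 categories=("no", "yes"), thresholds=(0.7,)),
        SimTrait("activity", "multicategorical", signal_lambda, "threshold",
                 categories=("diurnal", "nocturnal", "cathemeral"),
                 thresholds=(0.55, 0.85)),
    )
    R = np.eye(7)
    pairs = {
        (0, 1): 0.85,  # the two body-size traits
        (0, 2): 0.45, (1, 2): 0.45,  # size vs largest clutch
        (0, 3): 0.30, (1, 3): 0.30,
        (2, 3): 0.60,  # the two clutch traits
        (4, 0): -0.15, (4, 2): -0.10,  # latitude weakly tied to size/clutch
        (5, 0): -0.20,  # insular species skew smaller
        (6, 4): 0.20,
    }
    for (i, j), r in pairs.items():
        R[i, j] = R[j, i] = r
    # nudge to the nearest PSD matrix if the hand-filled entries overshoot
    w, V = np.linalg.eigh(R)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return SimulationSpec(
        n_taxa=n_taxa,
        traits=traits,
        correlation=R,
        pre_missing_fraction=pre_missing_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Tree simulation


def simulate_tree(spec: SimulationSpec, max_retries: int = 100) -> PhyloTree:
    """Random rooted ultrametric tree under a Yule or birth-death process.

    Lineages split at exponential waiting times; under birth-death a
    replicate in which the clade dies before reaching ``n_taxa`` tips is
    resimulated (up to ``max_retries``).  Branch lengths are the waiting
    times, so every root-to-tip path has the same total depth.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_retries):
        tree = _grow_tree(spec, rng)
        if tree is not None:
            return tree
    raise TraitTableError("all lineages went extinct in every retry")


def _grow_tree(spec: SimulationSpec, rng: np.random.Generator) -> PhyloTree | None:
    birth, death = spec.birth_rate, spec.death_rate
    if spec.tree_model == "yule":
        death = 0.0
    next_id = [0]

    def fresh() -> dict:
        next_id[0] += 1
        return {"id": next_id[0], "children": None, "t_birth": 0.0, "t_end": None}

    root_a, root_b = fresh(), fresh()
    active = [root_a, root_b]
    t = 0.0
    while len(active) < spec.n_taxa:
        k = len(active)
        rate = k * (birth + death)
        t += rng.exponential(1.0 / rate)
        node = active[int(rng.integers(0, k))]
        if death > 0 and rng.random() < death / (birth + death):
            node["t_end"] = t
            node["dead"] = True
            active.remove(node)
            if len(active) == 0:
                return None
        else:
            a, b = fresh(), fresh()
            a["t_birth"] = b["t_birth"] = t
            node["children"] = (a, b)
            node["t_end"] = t
            active.remove(node)
            active.extend([a, b])
    # one final waiting time so the last split is not at the present
    t += rng.exponential(1.0 / (len(active) * max(birth + death, birth)))
    for node in active:
        node["t_end"] = t

    counter = [0]

    def newick(node) -> str | None:
        length = node["t_end"] - node["t_birth"]
        if node["children"] is None:
            if node.get("dead"):
                return None
            counter[0] += 1
            return f"t{counter[0]}:{length:.10f}"
        parts = [newick(c) for c in node["children"]]
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        if len(parts) == 1:  # collapse through an extinct sister
            label, colon, ln = parts[0].rpartition(":")
            return f"{label}:{float(ln) + length:.10f}"
        return f"({parts[0]},{parts[1]}):{length:.10f}"

    parts = [p for p in (newick(root_a), newick(root_b)) if p is not None]
    if len(parts) < 2:
        return None
    text = f"({parts[0]},{parts[1]});"
    tree = parse_newick(text, label=f"sim-{spec.tree_model}")
    if tree.n_leaves != spec.n_taxa:
        return None
    return tree


# ---------------------------------------------------------------------------
# Trait simulation


def _latent_traits(
    tree: PhyloTree, spec: SimulationSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent Brownian values, per-trait lambda-rescaled, cross-correlated.

    Separable model: each trait's marginal tip covariance is
    C(lambda) = lambda * C + (1 - lambda) * diag(C), and the cross-trait
    correlation matrix mixes otherwise-independent standard-normal drivers.
    Latent columns are standardised to unit variance before the per-trait
    location/scale is applied downstream.
    """
    species = tree.leaf_labels
    n, p = len(species), len(spec.traits)
    C = tree.vcv(species).values
    depth = np.diag(C).mean()
    Cn = C / depth  # normalise so the latent marginal variance is ~1
    R = spec.correlation if spec.correlation is not None else np.eye(p)
    LR = np.linalg.cholesky(np.asarray(R) + 1e-12 * np.eye(p))
    W = rng.standard_normal((n, p)) @ LR.T  # cross-correlated drivers
    Z = np.empty((n, p))
    for j, trait in enumerate(spec.traits):
        lam = trait.signal_lambda
        Cl = lam * Cn + (1 - lam) * np.diag(np.diag(Cn))
        L = np.linalg.cholesky(Cl + 1e-10 * np.eye(n))
        Z[:, j] = L @ W[:, j]
    return pd.DataFrame(Z, index=species, columns=[t.name for t in spec.traits])


def simulate_traits(tree: PhyloTree, spec: SimulationSpec) -> TraitTable:
    """Observed mixed-type traits from latent Brownian values.

    Links: identity (plus loc/scale), 1 + Poisson(exp(loc + scale * z))
    for counts, and empirical-quantile thresholding for categoricals.
    Afterwards ``pre_missing_fraction`` of cells per trait are blanked
    completely at random, subject to the near-complete-case side condition
    that every gappy row keeps at least three observed companion traits.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    Z = _latent_traits(tree, spec, rng)
    species = list(Z.index)
    cols: dict[str, pd.Series] = {}
    for trait in spec.traits:
        z = Z[trait.name].values
        z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
        if trait.link == "identity":
            vals = trait.loc + trait.scale * z
            if trait.transform == "natural_log":
                # loc/scale parameterise the log scale: log-normal observations
                vals = np.exp(vals)
            cols[trait.name] = pd.Series(vals, index=species)
        elif trait.link == "exp_poisson":
            rate = np.exp(trait.loc + trait.scale * z)
            vals = 1.0 + rng.poisson(rate).astype(float)
            cols[trait.name] = pd.Series(vals, index=species)
        else:  # threshold
            cuts = np.quantile(z, trait.thresholds)
            idx = np.searchsorted(cuts, z, side="right")
            vals = [trait.categories[i] for i in idx]
            cols[trait.name] = pd.Series(vals, index=species, dtype=object)
    data = pd.DataFrame(cols, index=pd.Index(species, name="species"))
    table = TraitTable(data=data, specs=tuple(t.trait_spec() for t in spec.traits))

    if spec.pre_missing_fraction > 0:
        _blank_mcar(table, spec.pre_missing_fraction, rng, min_observed_other=3)
    return table


def _blank_mcar(
    table: TraitTable,
    fraction: float,
    rng: np.random.Generator,
    min_observed_other: int,
) -> None:
    """Blank ~fraction of each trait's cells, keeping rows imputable."""
    n = table.n_species
    per_trait = int(round(fraction * n))
    traits = table.trait_names
    for tr in traits:
        spec = table.spec(tr)
        candidates = list(rng.permutation(table.species))
        taken = 0
        for sp in candidates:
            if taken >= per_trait:
                break
            row = table.data.loc[sp, traits]
            observed_other = int(row.drop(tr).notna().sum())
            if pd.isna(row[tr]) or observed_other < min_observed_other:
                continue
            table.data.at[sp, tr] = np.nan if spec.is_numeric else None
            taken += 1


def inject_mar_missingness(
    table: TraitTable,
    target_trait: str,
    driver_trait: str,
    intercept: float = -1.5,
    slope: float = 1.0,
    seed: int = 0,
) -> TraitTable:
    """Blank cells of one trait with probability logistic(a + b * driver).

    Emulates the missing-at-random structure of real trait compilations
    (e.g. harder-to-measure traits gappier for small-bodied species), which
    is what the MAR model-fitting step is designed to recover.  The driver
    trait must be numeric; it is standardised before applying the slope.
    """
    out = table.copy()
    spec = out.spec(target_trait)
    driver = out.data[driver_trait].astype(float)
    z = (driver - driver.mean()) / (driver.std() if driver.std() > 0 else 1.0)
    probs = 1.0 / (1.0 + np.exp(-(intercept + slope * z)))
    rng = np.random.default_rng(seed)
    for sp in out.species:
        if pd.isna(out.data.at[sp, target_trait]) or pd.isna(probs[sp]):
            continue
        if rng.random() < probs[sp]:
            out.data.at[sp, target_trait] = np.nan if spec.is_numeric else None
    return out


# ---------------------------------------------------------------------------
# Worked example (frozen literals, byte-stable)

_EXAMPLE_NEWICK = (
    "(((s01:0.40,s02:0.40):0.80,((s03:0.55,s04:0.55):0.25,s05:0.80):0.40):0.80,"
    "(((s06:0.30,s07:0.30):0.50,(s08:0.45,s09:0.45):0.35):0.60,"
    "((s10:0.50,s11:0.50):0.40,s12:0.90):0.50):0.60);"
)

_EXAMPLE_ROWS = [
    # species, body_size, clutch, insular, activity
    ("s01", 12.1, 3.0, "no", "diurnal"),
    ("s02", 13.4, 4.0, "no", "diurnal"),
    ("s03", 9.8, 2.0, "no", "diurnal"),
    ("s04", 10.5, None, "no", "cathemeral"),
    ("s05", 11.2, 3.0, "yes", "diurnal"),
    ("s06", 24.0, 6.0, "no", "nocturnal"),
    ("s07", 22.5, 7.0, "no", "nocturnal"),
    ("s08", 19.9, 5.0, "yes", "nocturnal"),
    ("s09", None, 6.0, "yes", "nocturnal"),
    ("s10", 30.2, 8.0, "no", "diurnal"),
    ("s11", 28.7, 9.0, "no", None),
    ("s12", 26.3, 7.0, "yes", "diurnal"),
]


def make_worked_example() -> tuple[TraitTable, PhyloTree]:
    """Fixed 12-species, 4-trait table and matching ultrametric tree.

    Frozen literals (not simulated) so documentation examples and golden
    tests are byte-stable.
    """
    specs = (
        TraitSpec("body_size", "continuous", transform="natural_log"),
        TraitSpec("clutch", "count", transform="natural_log"),
        TraitSpec("insular", "binary", categories=("no", "yes")),
        TraitSpec(
            "activity",
            "multicategorical",
            categories=("diurnal", "nocturnal", "cathemeral"),
        ),
    )
    rows = {
        r[0]: {
            "body_size": np.nan if r[1] is None else float(r[1]),
            "clutch": np.nan if r[2] is None else float(r[2]),
            "insular": r[3],
            "activity": r[4],
        }
        for r in _EXAMPLE_ROWS
    }
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index.name = "species"
    table = TraitTable(data=data, specs=specs)
    tree = parse_newick(_EXAMPLE_NEWICK, label="example")
    return table, tree
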
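"""End-to-end orchestration of the method-selection strategy.

The four steps: (1) simulate missingness in the near-complete-case table
under MCAR (nested proportions), MAR (fitted missingness models) and MNAR
(biased tail/category deletion); (2) impute every replicate with every
candidate (method, phylogeny source) combination; (3) score MSE / PFC per
trait, average over replicates, and pick the best-suited combination by
MAR-first majority vote; (4) apply the winner to the original incomplete
table and compare summaries of complete-case, original and imputed data.

Masks are generated once per (mechanism setting, replicate) and shared by
every combination, so methods are compared on identical missingness — the
fair-comparison requirement of the design.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    EvaluationRecord,
    StrategySummary,
    aggregate_replicates,
    compare_datasets,
    error_ratio_table,
    majority_vote,
    records_frame,
    score_plan,
)
from .imputers import (
    ImputationConfig,
    ImputedTable,
    augment_with_eigenvectors,
    impute,
    select_auxiliary_traits,
)
from .missingness import (
    MaskPlan,
    NoSignificantPredictor,
    apply_mask,
    fit_mar_model,
    mask_mar,
    mask_mcar,
    mask_mnar,
)
from .phylo import EigenvectorSet, PhyloTree, extract_eigenvectors
from .traits import TraitTable, TraitTableError, apply_transforms, build_near_complete_case

__all__ = ["RunConfig", "Setting", "enumerate_settings", "run_strategy", "apply_best_method"]

logger = logging.getLogger("phyloimpute")

_MECHANISM_IDS = {"MCAR": 1, "MAR": 2, "MNAR": 3}


@dataclass(frozen=True)
class Setting:
    """One point of the combination design."""

    method: str
    phylogeny_source: str  # tree label or "none"
    mechanism: str
    proportion: str  # "0.10" ... for MCAR, target for MAR, "n/a" for MNAR

    @property
    def label(self) -> str:
        return f"{self.method}+{self.phylogeny_source}/{self.mechanism}@{self.proportion}"


@dataclass
class RunConfig:
    """Structured configuration of a full strategy run."""

    table: TraitTable
    trees: Mapping[str, PhyloTree] = field(default_factory=dict)
    methods: tuple[str, ...] = ("mean_mode", "knn", "rf", "mice")
    phylogeny_sources: tuple[str, ...] = ("none",)
    mechanisms: tuple[str, ...] = ("MCAR", "MAR", "MNAR")
    mcar_proportions: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40)
    mar_target_proportion: float = 0.20
    n_replicates: int = 100
    alpha: float = 0.05
    ev_threshold: float = 0.65
    master_seed: int = 0
    reference_table: TraitTable | None = None  # for MAR model fitting
    method_params: Mapping[str, Mapping] = field(default_factory=dict)
    max_missing_per_trait: float = 0.10
    min_observed_other: int = 3
    outdir: Path | None = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise TraitTableError("need at least one method")
        if not self.mechanisms:
            raise TraitTableError("need at least one mechanism")
        props = list(self.mcar_proportions)
        if any(b <= a for a, b in zip(props, props[1:])):
            raise TraitTableError("MCAR proportions must be strictly increasing")
        if self.n_replicates < 1:
            raise TraitTableError("n_replicates must be >= 1")
        missing_trees = [
            s for s in self.phylogeny_sources if s != "none" and s not in self.trees
        ]
        if missing_trees:
            raise TraitTableError(f"no tree supplied for sources: {missing_trees}")

    def make_config(self, method: str, source: str, seed: int) -> ImputationConfig:
        params = dict(self.method_params.get(method, {}))
        return ImputationConfig(
            method=method, phylogeny_source=source, seed=seed, **params
        )


def enumerate_settings(config: RunConfig) -> list[Setting]:
    """Cartesian design: method x phylogeny source x mechanism setting.

    mean/mode has no phylogenetic variant, each MCAR proportion is its own
    setting, and MAR / MNAR contribute one setting each.  With four
    methods, four trees and the standard mechanisms this yields 96
    combination settings.
    """
    mech_settings: list[tuple[str, str]] = []
    for mech in config.mechanisms:
        if mech == "MCAR":
            mech_settings.extend(("MCAR", f"{p:.2f}") for p in config.mcar_proportions)
        elif mech == "MAR":
            mech_settings.append(("MAR", f"{config.mar_target_proportion:.2f}"))
        elif mech == "MNAR":
            mech_settings.append(("MNAR", "n/a"))
        else:
            raise TraitTableError(f"unknown mechanism {mech!r}")
    out = []
    for method in config.methods:
        sources = ("none",) if method == "mean_mode" else tuple(config.phylogeny_sources)
        for source in sources:
            for mech, prop in mech_settings:
                out.append(Setting(method, source, mech, prop))
    return out


def _replicate_seed(master_seed: int, mechanism: str, proportion: str, replicate: int) -> int:
    """Stable per-(mechanism, proportion, replicate) seed, < 2**31.

    Methods deliberately do not enter the key: within a replicate every
    method sees the same masks.
    """
    try:
        prop_key = int(round(float(proportion) * 100))
    except ValueError:  # "n/a" (MNAR) or "all" (nested MCAR stream)
        prop_key = 999
    ss = np.random.SeedSequence(
        [int(master_seed), _MECHANISM_IDS[mechanism], prop_key, int(replicate)]
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _method_seed(master_seed: int, setting: Setting, replicate: int) -> int:
    """Stable stochastic-imputer seed (crc32 of labels: process-independent)."""
    key = [
        int(master_seed),
        7,
        zlib.crc32(setting.method.encode()),
        zlib.crc32(setting.phylogeny_source.encode()),
        _MECHANISM_IDS[setting.mechanism],
        int(replicate),
    ]
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class StrategyResult:
    near_complete: TraitTable
    records: list[EvaluationRecord]
    mean_table: pd.DataFrame
    error_ratios: pd.DataFrame
    summary: StrategySummary
    eigenvectors: Mapping[str, EigenvectorSet]
    predictors: Mapping[str, list]
    mar_eligible: list[str]
    settings: list[Setting]


def _build_masks(
    config: RunConfig,
    table: TraitTable,
    mar_models: Mapping[str, object],
) -> dict[tuple[str, str, int], MaskPlan]:
    """One MaskPlan per (mechanism, proportion, replicate), shared by methods."""
    masks: dict[tuple[str, str, int], MaskPlan] = {}
    for rep in range(config.n_replicates):
        if "MCAR" in config.mechanisms:
            seed = _replicate_seed(config.master_seed, "MCAR", "all", rep)
            plans = mask_mcar(
                table,
                config.mcar_proportions,
                replicate_seed=seed,
                replicate_id=rep,
            )
            for p, plan in zip(config.mcar_proportions, plans):
                masks[("MCAR", f"{p:.2f}", rep)] = plan
        if "MAR" in config.mechanisms and mar_models:
            prop = f"{config.mar_target_proportion:.2f}"
            seed = _replicate_seed(config.master_seed, "MAR", prop, rep)
            cells: set = set()
            for i, (trait, model) in enumerate(sorted(mar_models.items())):
                plan = mask_mar(
                    table,
                    model,
                    target_proportion=config.mar_target_proportion,
                    replicate_seed=(seed + i) % (2**31),
                    replicate_id=rep,
                )
                cells |= set(plan.cells)
            masks[("MAR", prop, rep)] = MaskPlan(
                mechanism="MAR",
                proportion_label=prop,
                cells=frozenset(cells),
                replicate_id=rep,
                seed=seed,
            )
        if "MNAR" in config.mechanisms:
            seed = _replicate_seed(config.master_seed, "MNAR", "n/a", rep)
            cells = set()
            for i, trait in enumerate(table.trait_names):
                spec = table.spec(trait)
                if spec.is_categorical and not (spec.mnar_tail or {}).get("category"):
                    # default: delete the least frequent category
                    obs = table.data[trait].dropna()
                    cat = obs.value_counts().index[-1]
                    tail = {"category": cat, "fraction": 1.0}
                else:
                    tail = None
                plan = mask_mnar(
                    table,
                    trait,
                    tail_spec=tail,
                    replicate_seed=(seed + i) % (2**31),
                    replicate_id=rep,
                )
                cells |= set(plan.cells)
            masks[("MNAR", "n/a", rep)] = MaskPlan(
                mechanism="MNAR",
                proportion_label="n/a",
                cells=frozenset(cells),
                replicate_id=rep,
                seed=seed,
            )
    return masks


def run_strategy(config: RunConfig) -> StrategyResult:
    """Execute the full four-step strategy and (optionally) write artifacts."""
    settings = enumerate_settings(config)
    logger.info("design: %d settings x %d replicates", len(settings), config.n_replicates)

    near = build_near_complete_case(
        config.table, config.max_missing_per_trait, config.min_observed_other
    )
    near = apply_transforms(near)

    # eigenvectors per tree, restricted to the near-complete species in it
    evs: dict[str, EigenvectorSet] = {}
    for label in config.phylogeny_sources:
        if label == "none":
            continue
        tree = config.trees[label]
        in_tree = [s for s in near.species if s in tree.leaf_labels]
        uncovered = [s for s in near.species if s not in in_tree]
        if uncovered:
            logger.warning("tree %s lacks %d species", label, len(uncovered))
        evs[label] = extract_eigenvectors(
            tree, in_tree, threshold=config.ev_threshold, source_label=label
        )

    predictors = {
        t: select_auxiliary_traits(near, t, alpha=config.alpha)
        for t in near.trait_names
    }

    mar_models: dict = {}
    if "MAR" in config.mechanisms:
        reference = config.reference_table or config.table
        reference = (
            apply_transforms(reference) if not reference.transformed else reference
        )
        for trait in near.trait_names:
            try:
                mar_models[trait] = fit_mar_model(reference, trait, alpha=config.alpha)
            except NoSignificantPredictor:
                logger.info("MAR: no significant predictor for %s; skipped", trait)
            except TraitTableError as exc:
                logger.info("MAR: %s ineligible (%s)", trait, exc)

    masks = _build_masks(config, near, mar_models)

    augmented = {"none": near}
    for label, ev in evs.items():
        augmented[label] = augment_with_eigenvectors(near, ev)

    records: list[EvaluationRecord] = []
    for setting in settings:
        base = augmented[setting.phylogeny_source]
        for rep in range(config.n_replicates):
            key = (setting.mechanism, setting.proportion, rep)
            if key not in masks:
                continue
            plan = masks[key]
            # restrict the plan to species present in this (possibly
            # tree-reduced) table
            cells = frozenset(
                (sp, tr) for sp, tr in plan.cells if sp in base.data.index
            )
            local = MaskPlan(
                mechanism=plan.mechanism,
                proportion_label=plan.proportion_label,
                cells=cells,
                replicate_id=plan.replicate_id,
                seed=plan.seed,
            )
            masked = apply_mask(base, local)
            cfg = config.make_config(
                setting.method,
                setting.phylogeny_source,
                _method_seed(config.master_seed, setting, rep),
            )
            try:
                result = impute(masked, cfg, predictors)
            except TraitTableError as exc:
                logger.warning("failed: %s rep %d (%s)", setting.label, rep, exc)
                continue
            records.extend(
                score_plan(result, base, local, setting.method, setting.phylogeny_source)
            )

    mean_table = aggregate_replicates(records)
    ratios = error_ratio_table(mean_table)
    summary = majority_vote(mean_table)
    result = StrategyResult(
        near_complete=near,
        records=records,
        mean_table=mean_table,
        error_ratios=ratios,
        summary=summary,
        eigenvectors=evs,
        predictors=predictors,
        mar_eligible=sorted(mar_models),
        settings=settings,
    )
    if config.outdir is not None:
        _write_artifacts(config, result)
    return result


def _write_artifacts(config: RunConfig, result: StrategyResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records_frame(result.records).to_csv(outdir / "evaluation_records.csv", index=False)
    result.mean_table.to_csv(outdir / "mean_errors.csv", index=False)
    result.error_ratios.to_csv(outdir / "error_ratios.csv", index=False)
    with open(outdir / "strategy_summary.json", "w") as fh:
        json.dump(result.summary.to_dict(), fh, indent=2)
    manifest = {
        "version": __version__,
        "master_seed": config.master_seed,
        "n_replicates": config.n_replicates,
        "methods": list(config.methods),
        "phylogeny_sources": list(config.phylogeny_sources),
        "mechanisms": list(config.mechanisms),
        "mcar_proportions": list(config.mcar_proportions),
        "mar_target_proportion": config.mar_target_proportion,
        "ev_threshold": config.ev_threshold,
        "alpha": config.alpha,
        "n_settings": len(result.settings),
        "mar_eligible_traits": result.mar_eligible,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def apply_best_method(
    original: TraitTable,
    summary: StrategySummary,
    tree: PhyloTree | None,
    config: RunConfig,
) -> tuple[ImputedTable, pd.DataFrame]:
    """Step 4: impute the original incomplete table with the winning method.

    Subsets the original to species with at least one observed trait (and
    present in the winner's tree, when the winner uses phylogeny); traits
    already complete in the subset are skipped automatically since they
    have no missing cells.  Returns the completed table and the
    complete-case / original / imputed comparison report.
    """
    source = summary.best_phylogeny_source
    if source != "none" and tree is None:
        raise TraitTableError(f"winner uses tree {source!r} but no tree was supplied")
    work = apply_transforms(original) if not original.transformed else original
    has_any = work.missing_mask().sum(axis=1) < len(work.trait_names)
    species = [s for s in work.species if has_any[s]]
    if source != "none":
        species = [s for s in species if s in tree.leaf_labels]
    if not species:
        raise TraitTableError("empty subset: no species with data (and tree coverage)")
    subset = work.subset(species)
    for trait in subset.trait_names:
        frac = subset.missing_fraction(trait)
        logger.info("subset missingness %-20s %.2f", trait, frac)

    if source != "none":
        ev = extract_eigenvectors(
            tree,
            [s for s in species if s in tree.leaf_labels],
            threshold=config.ev_threshold,
            source_label=source,
        )
        subset = augment_with_eigenvectors(subset, ev)

    predictors = {}
    for t in subset.trait_names:
        try:
            predictors[t] = select_auxiliary_traits(subset, t, alpha=config.alpha)
        except TraitTableError:
            predictors[t] = [x for x in subset.trait_names if x != t]
    cfg = config.make_config(summary.best_method, source, config.master_seed)
    result = impute(subset, cfg, predictors)

    complete_rows = work.missing_mask().sum(axis=1) == 0
    complete_case = work.subset(list(work.data.index[complete_rows]))
    from .traits import invert_transforms

    report = compare_datasets(
        invert_transforms(work.subset(species)),
        ImputedTable(
            table=invert_transforms(result.table),
            imputed_cells=result.imputed_cells,
            config=result.config,
        ),
        invert_transforms(complete_case),
    )
    return result, report
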
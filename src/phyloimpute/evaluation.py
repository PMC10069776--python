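"""Scoring imputations and selecting the best-suited method.

Performance is scored only on cells that were deliberately masked and have
an observed true value: mean squared error (MSE, on the model scale) for
numeric traits and proportion falsely classified (PFC) for categorical
traits.  Per-replicate records are averaged per combination of
(mechanism, proportion, method, phylogeny source, trait), and the winner is
chosen by majority vote: each trait votes for the combination with its
lowest mean error, first under MAR (the most realistic mechanism); an exact
vote tie falls through to MNAR, then MCAR (votes summed over proportions).

The error ratio err(without phylogeny) / err(with phylogeny) quantifies what
the tree contributed: values above 1 mean phylogeny helped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .imputers import ImputedTable
from .missingness import MaskPlan
from .traits import TraitTable, TraitTableError

__all__ = [
    "EvaluationRecord",
    "StrategySummary",
    "score_numeric",
    "score_categorical",
    "score_plan",
    "aggregate_replicates",
    "error_ratio",
    "error_ratio_table",
    "majority_vote",
    "compare_datasets",
]

GROUP_KEYS = ["mechanism", "proportion", "method", "phylogeny_source", "trait"]
COMBO_KEYS = ["method", "phylogeny_source"]


@dataclass(frozen=True)
class EvaluationRecord:
    mechanism: str
    proportion: str
    method: str
    phylogeny_source: str
    trait: str
    metric: str  # MSE | PFC
    value: float
    replicate_id: int

    def __post_init__(self) -> None:
        if self.metric not in ("MSE", "PFC"):
            raise TraitTableError(f"unknown metric {self.metric!r}")
        if self.value < 0:
            raise TraitTableError("error value must be non-negative")
        if self.metric == "PFC" and self.value > 1:
            raise TraitTableError("PFC must lie in [0, 1]")


def _evaluable_cells(
    truth: TraitTable, plan: MaskPlan, trait: str, imputed: ImputedTable
) -> list[str]:
    species = plan.cells_for(trait)
    out = []
    for sp in species:
        if sp not in imputed.table.data.index:
            continue
        if pd.isna(truth.data.at[sp, trait]):
            continue
        out.append(sp)
    return out


def score_numeric(
    imputed: ImputedTable, truth: TraitTable, plan: MaskPlan, trait: str
) -> float:
    """MSE over deliberately-masked cells with observed truth (model scale)."""
    if not truth.spec(trait).is_numeric:
        raise TraitTableError(f"MSE requested for categorical trait {trait!r}")
    cells = _evaluable_cells(truth, plan, trait, imputed)
    if not cells:
        raise TraitTableError(f"no evaluable cells for trait {trait!r}")
    t = truth.data.loc[cells, trait].astype(float).values
    v = imputed.table.data.loc[cells, trait].astype(float).values
    return float(np.mean((v - t) ** 2))


def score_categorical(
    imputed: ImputedTable, truth: TraitTable, plan: MaskPlan, trait: str
) -> float:
    """Proportion falsely classified over deliberately-masked cells."""
    if not truth.spec(trait).is_categorical:
        raise TraitTableError(f"PFC requested for numeric trait {trait!r}")
    cells = _evaluable_cells(truth, plan, trait, imputed)
    if not cells:
        raise TraitTableError(f"no evaluable cells for trait {trait!r}")
    t = truth.data.loc[cells, trait].values
    v = imputed.table.data.loc[cells, trait].values
    return float(np.mean(t != v))


def score_plan(
    imputed: ImputedTable,
    truth: TraitTable,
    plan: MaskPlan,
    method: str,
    phylogeny_source: str,
) -> list[EvaluationRecord]:
    """One record per masked trait of the plan (skipping empty evaluations)."""
    records = []
    for trait in plan.traits():
        spec = truth.spec(trait)
        cells = _evaluable_cells(truth, plan, trait, imputed)
        if not cells:
            continue
        if spec.is_numeric:
            metric, value = "MSE", score_numeric(imputed, truth, plan, trait)
        else:
            metric, value = "PFC", score_categorical(imputed, truth, plan, trait)
        records.append(
            EvaluationRecord(
                mechanism=plan.mechanism,
                proportion=plan.proportion_label,
                method=method,
                phylogeny_source=phylogeny_source,
                trait=trait,
                metric=metric,
                value=value,
                replicate_id=plan.replicate_id,
            )
        )
    return records


def records_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def aggregate_replicates(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Mean error per (mechanism, proportion, method, source, trait).

    Attaches replicate count and standard error of the mean.
    """
    if not records:
        raise TraitTableError("no records to aggregate")
    df = records_frame(records)
    mixed = df.groupby(GROUP_KEYS)["metric"].nunique()
    if (mixed > 1).any():
        raise TraitTableError("mixed metrics within an aggregation group")
    out = (
        df.groupby(GROUP_KEYS + ["metric"], as_index=False)
        .agg(
            mean_error=("value", "mean"),
            n_replicates=("value", "size"),
            se=("value", lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0),
        )
        .sort_values(GROUP_KEYS, kind="stable")
        .reset_index(drop=True)
    )
    return out


def error_ratio(err_without: float, err_with: float) -> float:
    """err(no phylogeny) / err(with phylogeny); > 1 means phylogeny helped."""
    if err_with == 0:
        raise TraitTableError("error ratio undefined: error with phylogeny is zero")
    return float(err_without) / float(err_with)


def error_ratio_table(mean_table: pd.DataFrame) -> pd.DataFrame:
    """Per (method, trait, mechanism, proportion, tree) error ratios.

    Rows where either error is unavailable, or the with-phylogeny error is
    zero, are skipped.
    """
    base = mean_table[mean_table["phylogeny_source"] == "none"]
    phylo = mean_table[mean_table["phylogeny_source"] != "none"]
    keys = ["mechanism", "proportion", "method", "trait"]
    merged = phylo.merge(
        base[keys + ["mean_error"]], on=keys, suffixes=("", "_none")
    )
    merged = merged[merged["mean_error"] > 0].copy()
    merged["error_ratio"] = merged["mean_error_none"] / merged["mean_error"]
    cols = keys + ["phylogeny_source", "mean_error_none", "mean_error", "error_ratio"]
    return merged[cols].reset_index(drop=True)


@dataclass
class StrategySummary:
    """Outcome of the majority vote, with the full tie-break trace."""

    best_method: str
    best_phylogeny_source: str
    votes: dict  # stage -> {combo label: votes}
    tie_break_trace: list[str] = field(default_factory=list)

    @property
    def winner_label(self) -> str:
        return f"{self.best_method}+{self.best_phylogeny_source}"

    def to_dict(self) -> dict:
        return {
            "best_method": self.best_method,
            "best_phylogeny_source": self.best_phylogeny_source,
            "votes": {k: dict(v) for k, v in self.votes.items()},
            "tie_break_trace": list(self.tie_break_trace),
        }


def _stage_votes(mean_table: pd.DataFrame, mechanism: str) -> dict:
    """Per-trait winners under one mechanism (votes summed over proportions).

    For each trait, mean errors are first averaged over the mechanism's
    proportion settings, then the combination with the lowest value gets
    that trait's vote; exact ties give each tied combination a vote.
    """
    sub = mean_table[mean_table["mechanism"] == mechanism]
    votes: dict[str, float] = {}
    for trait, grp in sub.groupby("trait"):
        per_combo = grp.groupby(COMBO_KEYS)["mean_error"].mean()
        best = per_combo[per_combo == per_combo.min()]
        for (method, source) in best.index:
            label = f"{method}+{source}"
            votes[label] = votes.get(label, 0) + 1
    return votes


def majority_vote(mean_table: pd.DataFrame) -> StrategySummary:
    """Select the best-suited combination by MAR-first majority vote."""
    if mean_table.empty:
        raise TraitTableError("empty mean table")
    trace: list[str] = []
    all_votes: dict[str, dict] = {}
    candidates: set[str] | None = None
    for mechanism in ("MAR", "MNAR", "MCAR"):
        votes = _stage_votes(mean_table, mechanism)
        if not votes:
            trace.append(f"{mechanism}: no eligible traits, skipped")
            continue
        if candidates is not None:
            votes = {c: votes.get(c, 0) for c in candidates}
        all_votes[mechanism] = votes
        top = max(votes.values())
        leaders = sorted(c for c, v in votes.items() if v == top)
        trace.append(
            f"{mechanism}: votes {dict(sorted(votes.items()))}; leaders {leaders}"
        )
        if len(leaders) == 1:
            method, source = leaders[0].split("+", 1)
            trace.append(f"winner {leaders[0]} decided under {mechanism}")
            return StrategySummary(
                best_method=method,
                best_phylogeny_source=source,
                votes=all_votes,
                tie_break_trace=trace,
            )
        candidates = set(leaders)
        trace.append(f"tie among {leaders}; falling through")
    if candidates is None:
        raise TraitTableError("no mechanism produced any votes")
    raise TraitTableError(
        f"persistent tie among combinations: {sorted(candidates)} (trace: {trace})"
    )


# ---------------------------------------------------------------------------
# Dataset comparison (original vs imputed vs complete-case)


def _numeric_summary(values: pd.Series) -> dict:
    v = values.dropna().astype(float)
    n = len(v)
    out = {"N": n}
    if n == 0:
        return out
    out.update(
        {
            "min": float(v.min()),
            "max": float(v.max()),
            "range": float(v.max() - v.min()),
            "median": float(v.median()),
            "mean": float(v.mean()),
        }
    )
    if n > 1:
        sd = float(v.std(ddof=1))
        se = sd / np.sqrt(n)
        tq = float(stats.t.ppf(0.975, df=n - 1))
        out.update(
            {
                "se_mean": se,
                "ci95_half_width": tq * se,
                "variance": float(v.var(ddof=1)),
                "sd": sd,
            }
        )
    return out


def compare_datasets(
    original: TraitTable,
    imputed: ImputedTable,
    complete_case: TraitTable,
) -> pd.DataFrame:
    """Tidy per-(trait, dataset) summary statistics on the original scale.

    Numeric traits: N, min, max, range, median, mean, SE, 0.95 CI
    half-width (Student-t), variance, SD.  Categorical traits: one row per
    category with count and proportion.
    """
    datasets = {
        "complete_case": complete_case,
        "original": original,
        "imputed": imputed.table,
    }
    rows = []
    for trait in original.trait_names:
        spec = original.spec(trait)
        for label, tab in datasets.items():
            if trait not in tab.data.columns:
                continue
            col = tab.data[trait]
            if spec.is_numeric:
                row = {"trait": trait, "dataset": label, "category": ""}
                row.update(_numeric_summary(col))
                rows.append(row)
            else:
                obs = col.dropna()
                counts = obs.value_counts()
                for cat in spec.categories:
                    rows.append(
                        {
                            "trait": trait,
                            "dataset": label,
                            "category": cat,
                            "N": int(counts.get(cat, 0)),
                            "proportion": float(counts.get(cat, 0)) / len(obs)
                            if len(obs)
                            else np.nan,
                        }
                    )
    return pd.DataFrame(rows)
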
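"""End-to-end runs and selection-quality metrics.

A *stage* pairs one or more known batches (validation recorded) with one
unknown batch sampled at a comparable age; the pipeline selects the unknown
individuals predicted to be low producers, either by zone matching or by the
regression baseline. *Continuous* selection chains stages: individuals
selected at one sampling age are removed before the next age's analysis, and
counts are reported cumulatively.

Two metrics summarise a selection against the unknown batch's (held-out)
validation values:

* egg improvement — 100 · (mean eggs of never-selected birds − original flock
  mean) / original flock mean, rounded half-up to one decimal. The divisor is
  the original stage-0 flock mean and stays fixed across stages.
* under-average rate — the count and integer percentage (half-up) of selected
  birds whose egg number falls strictly below that original mean.

The unknown batch's validation values are used only for these metrics, never
for selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .datasets import Dataset
from .preprocessing import (DEFAULT_CANDIDATE_FRACTION, build_transferred_table,
                            rank_dataset, select_validation_candidates)
from .prediction import (SelectionResult, build_filter_state, compute_m_matrix,
                         select_predicted)
from .regression import fit_ols, predict_eggs, select_lowest
from .zoning import build_zone_table

__all__ = ["Stage", "StagePlan", "StageOutcome", "union_datasets",
           "run_prezone", "run_stage", "run_continuous",
           "compute_improvement", "under_average_rate"]


def _half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def compute_improvement(avg_remaining: float, baseline_avg: float) -> float:
    """Percent change of the remaining flock's mean over the original mean."""
    if baseline_avg <= 0:
        raise ValueError("baseline average must be positive")
    return _half_up(100.0 * (avg_remaining - baseline_avg) / baseline_avg, 1)


def under_average_rate(selected_eggs: np.ndarray,
                       baseline_avg: float) -> tuple[int, int]:
    """(count, integer percent) of selected birds strictly below the flock mean."""
    selected_eggs = np.asarray(selected_eggs)
    if selected_eggs.size == 0:
        raise ValueError("selection is empty")
    count = int(np.sum(selected_eggs < baseline_avg))
    return count, int(_half_up(100.0 * count / selected_eggs.size, 0))


def union_datasets(knowns: list[Dataset], prefixes: list[str] | None = None) -> Dataset:
    """Concatenate known batches into one, disambiguating ids by batch prefix.

    Ranking and candidate extraction then run jointly on the pooled batch.
    """
    if len(knowns) == 1:
        return knowns[0]
    if prefixes is None:
        prefixes = [f"b{k + 1}" for k in range(len(knowns))]
    first = knowns[0]
    for d in knowns[1:]:
        if d.variable_names != first.variable_names:
            raise ValueError("union requires identical variable names across batches")
        if not d.has_validation():
            raise ValueError("every known batch in a union needs validation values")
    ids = [f"{pref}:{oid}" for pref, d in zip(prefixes, knowns) for oid in d.object_ids]
    return Dataset(
        object_ids=ids,
        scores=np.vstack([d.scores for d in knowns]),
        variable_names=list(first.variable_names),
        stage_label=first.stage_label,
        validation=np.concatenate([d.validation for d in knowns]),
    )


def run_prezone(known: Dataset, unknown: Dataset,
                fraction: float = DEFAULT_CANDIDATE_FRACTION) -> SelectionResult:
    """Full zone pipeline: rank → candidates → transfer → zones → cascade."""
    ranks_b = rank_dataset(known)
    candidates = select_validation_candidates(known, fraction, ranks=ranks_b)
    transferred = build_transferred_table(unknown, known)
    zones = build_zone_table(transferred, candidates)
    mm = compute_m_matrix(zones)
    fs = build_filter_state(mm, candidates.cn)
    return select_predicted(mm, fs, candidates.cn)


@dataclass
class Stage:
    """One sampling age: known batch(es) → unknown batch."""

    known: list[Dataset]
    unknown: Dataset
    label: str = ""


@dataclass
class StagePlan:
    stages: list[Stage]

    @property
    def union_mode(self) -> bool:
        return any(len(s.known) > 1 for s in self.stages)


@dataclass
class StageOutcome:
    """Selection plus, when the unknown batch carries validation, its metrics."""

    label: str
    method: str
    selected_ids: list[str]
    n_selected: int
    avg_remaining: float | None = None
    baseline_avg: float | None = None
    improvement_pct: float | None = None
    n_under_avg: int | None = None
    under_avg_pct: int | None = None
    extra: dict = field(default_factory=dict)


def _evaluate(outcome: StageOutcome, unknown: Dataset, selected_ids: list[str],
              baseline_avg: float) -> None:
    eggs = dict(zip(unknown.object_ids, unknown.validation))
    remaining = [eggs[oid] for oid in unknown.object_ids if oid not in set(selected_ids)]
    selected = np.array([eggs[oid] for oid in selected_ids])
    outcome.baseline_avg = baseline_avg
    outcome.avg_remaining = float(np.mean(remaining)) if remaining else float("nan")
    outcome.improvement_pct = compute_improvement(outcome.avg_remaining, baseline_avg)
    outcome.n_under_avg, outcome.under_avg_pct = under_average_rate(selected, baseline_avg)


def run_stage(known: Dataset | list[Dataset], unknown: Dataset,
              fraction: float = DEFAULT_CANDIDATE_FRACTION,
              method: str = "prezone", n_select: int | None = None,
              baseline_avg: float | None = None) -> StageOutcome:
    """Run one stage with either method and evaluate it when possible.

    ``baseline_avg`` defaults to the unknown batch's own mean validation value
    (the stage-0 flock mean); continuous runs pass the original mean in so the
    divisor stays fixed. For the regression baseline, ``n_select`` defaults to
    the zone method's selection count on the same inputs, pairing the two.
    """
    knowns = known if isinstance(known, list) else [known]
    pooled = union_datasets(knowns)
    if pooled.variable_names != unknown.variable_names:
        raise ValueError("known and unknown batches must share variable names")

    if method == "prezone":
        result = run_prezone(pooled, unknown, fraction)
        idx = result.selected
        extra = {"admit_step": dict(zip(
            (unknown.object_ids[i] for i in result.selected), result.admit_step)),
            "target_count": result.target_count, "short": result.short}
    elif method == "regression":
        if n_select is None:
            n_select = run_prezone(pooled, unknown, fraction).n_selected
        model = fit_ols(pooled)
        preds = predict_eggs(model, unknown)
        idx = select_lowest(preds, n_select)
        extra = {"model": model}
    else:
        raise ValueError(f"unknown method {method!r}")

    selected_ids = [unknown.object_ids[i] for i in idx]
    outcome = StageOutcome(label=unknown.stage_label, method=method,
                           selected_ids=selected_ids, n_selected=len(selected_ids),
                           extra=extra)
    if unknown.has_validation():
        if baseline_avg is None:
            baseline_avg = float(np.mean(unknown.validation))
        _evaluate(outcome, unknown, selected_ids, baseline_avg)
    return outcome


def run_continuous(plan: StagePlan, fraction: float = DEFAULT_CANDIDATE_FRACTION,
                   method: str = "prezone",
                   n_select_per_stage: list[int] | None = None) -> pd.DataFrame:
    """Multi-stage selection with removal: selected birds leave the flock.

    Successive unknown batches must cover the same individuals (matched ids).
    Reported ``n_selected`` and under-average counts are cumulative; the
    improvement divisor is the original (stage-0) flock mean throughout.
    Returns one report row per stage.
    """
    if not plan.stages:
        raise ValueError("plan needs at least one stage")
    first_unknown = plan.stages[0].unknown
    if not first_unknown.has_validation():
        raise ValueError("continuous evaluation needs validation on the unknown flock")
    all_ids = set(first_unknown.object_ids)
    eggs = dict(zip(first_unknown.object_ids, first_unknown.validation))
    baseline_avg = float(np.mean(first_unknown.validation))

    removed: list[str] = []
    rows = []
    for t, stage in enumerate(plan.stages):
        unknown = stage.unknown
        if set(unknown.object_ids) != all_ids:
            raise ValueError(
                f"stage {stage.label or t}: unknown ids do not match the flock")
        mask = np.array([oid not in set(removed) for oid in unknown.object_ids])
        active = unknown.subset(mask)
        n_sel = None
        if n_select_per_stage is not None:
            n_sel = n_select_per_stage[t]
        outcome = run_stage(stage.known, active, fraction, method,
                            n_select=n_sel, baseline_avg=baseline_avg)
        removed.extend(outcome.selected_ids)

        remaining = [eggs[oid] for oid in first_unknown.object_ids
                     if oid not in set(removed)]
        avg_remaining = float(np.mean(remaining)) if remaining else float("nan")
        selected_eggs = np.array([eggs[oid] for oid in removed])
        n_under, pct_under = under_average_rate(selected_eggs, baseline_avg)
        rows.append({
            "stage": stage.label or unknown.stage_label or str(t + 1),
            "method": method,
            "n_selected": len(removed),
            "n_selected_this_stage": outcome.n_selected,
            "avg_remaining": avg_remaining,
            "baseline_avg": baseline_avg,
            "improvement_pct": compute_improvement(avg_remaining, baseline_avg),
            "n_under_avg": n_under,
            "under_avg_pct": pct_under,
        })
    return pd.DataFrame(rows)
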
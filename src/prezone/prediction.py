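"""Zone-distance matching and the five-step selection cascade.

An unknown object's zone vector is compared with each low-validation
candidate's by the Manhattan distance on zone labels,

    M[ej, i] = sum_p |a_zones[i, p] - b_zones[ej, p]|,

so M = 0 means the object sits in exactly the candidate's zones on every
biomarker. Selection admits objects in five tiers until at least ``cn``
(the candidate count) are chosen:

    2.1  min_ej M = 0
    2.2  min_ej M = 1
    2.3  min_ej M = 2 and filters F1 and F2
    2.4  min_ej M = 2 and filter F1 or F2
    2.5  filters F3 and F4

The filters rank objects by how well they populate the candidates' nearest
sets: for each candidate, S_ej holds the objects whose distance is within the
cn-th smallest in that row (ties included, so |S_ej| = W_ej >= cn). For each
object, avg_m is its mean distance over the sets containing it (an infinity
sentinel when it appears in none) and count_m how many sets contain it. F1/F2
keep the top third by smallest avg_m / largest count_m; F3/F4 the top quarter.
Cutoffs use the ceiling of U/3 (or U/4) over the U objects in >= 1 set, with
ties at the cutoff value included.

Later tiers never run once the target count is reached; the cascade may still
end short of ``cn`` after tier 2.5 — that is reported, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .zoning import ZoneTable

__all__ = ["MMatrix", "FilterState", "SelectionResult",
           "compute_m_matrix", "build_filter_state", "select_predicted",
           "selection_report"]

ADMIT_STEPS = ("2.1", "2.2", "2.3", "2.4", "2.5")


@dataclass
class MMatrix:
    """cn × n_A integer zone distances, rows = candidates, columns = objects."""

    values: np.ndarray


@dataclass
class FilterState:
    """Per-candidate nearest sets and the derived per-object filters."""

    sets: list[np.ndarray]       # S_ej: object indices, one array per candidate
    avg_m: np.ndarray            # per object; +inf when in no set
    count_m: np.ndarray          # per object: number of sets containing it
    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray
    f4: np.ndarray

    @property
    def set_sizes(self) -> np.ndarray:
        return np.array([s.size for s in self.sets])


@dataclass
class SelectionResult:
    """Selected object indices with the cascade tier that admitted each."""

    selected: list[int]          # indices into the unknown dataset, admission order
    admit_step: list[str]        # parallel to `selected`
    target_count: int

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def short(self) -> bool:
        """True when even tier 2.5 could not reach the target count."""
        return self.n_selected < self.target_count


def compute_m_matrix(z: ZoneTable) -> MMatrix:
    """Manhattan distance between every candidate and unknown zone vector."""
    diff = np.abs(z.a_zones[None, :, :] - z.b_zones[:, None, :])
    return MMatrix(values=diff.sum(axis=2).astype(int))


def _top_mask(eligible: np.ndarray, keyvals: np.ndarray, k: int,
              smallest: bool) -> np.ndarray:
    """Mask of eligible objects within the k best key values, cutoff ties included."""
    mask = np.zeros(keyvals.size, dtype=bool)
    idx = np.flatnonzero(eligible)
    if idx.size == 0 or k <= 0:
        return mask
    vals = np.sort(keyvals[idx])
    if not smallest:
        vals = vals[::-1]
    cut = vals[min(k, idx.size) - 1]
    if smallest:
        mask[idx] = keyvals[idx] <= cut
    else:
        mask[idx] = keyvals[idx] >= cut
    return mask


def build_filter_state(mm: MMatrix, cn: int) -> FilterState:
    """Nearest sets per candidate plus the F1–F4 eligibility filters."""
    if cn < 1:
        raise ValueError("cn must be at least 1")
    values = mm.values
    n_cand, n_obj = values.shape
    sets: list[np.ndarray] = []
    for ej in range(n_cand):
        row = values[ej]
        cutoff = np.sort(row)[min(cn, n_obj) - 1]
        sets.append(np.flatnonzero(row <= cutoff))

    count_m = np.zeros(n_obj, dtype=int)
    sum_m = np.zeros(n_obj, dtype=float)
    for ej, s in enumerate(sets):
        count_m[s] += 1
        sum_m[s] += values[ej, s]
    in_any = count_m >= 1
    avg_m = np.full(n_obj, np.inf)
    avg_m[in_any] = sum_m[in_any] / count_m[in_any]

    u = int(in_any.sum())
    third = math.ceil(u / 3)
    quarter = math.ceil(u / 4)
    return FilterState(
        sets=sets,
        avg_m=avg_m,
        count_m=count_m,
        f1=_top_mask(in_any, avg_m, third, smallest=True),
        f2=_top_mask(in_any, count_m, third, smallest=False),
        f3=_top_mask(in_any, avg_m, quarter, smallest=True),
        f4=_top_mask(in_any, count_m, quarter, smallest=False),
    )


def select_predicted(mm: MMatrix, fs: FilterState, cn: int) -> SelectionResult:
    """Run the five-tier cascade until at least ``cn`` objects are admitted.

    Within a tier, objects are admitted in input order; tiers after the one
    that reaches the target never run. ``min_ej M = 2`` in tiers 2.3/2.4 is
    read as the minimum over candidates, matching the min-based reading the
    zero/one tiers force.
    """
    min_m = mm.values.min(axis=0)
    selected: list[int] = []
    admit_step: list[str] = []
    chosen = np.zeros(min_m.size, dtype=bool)

    tiers = [
        ("2.1", min_m == 0),
        ("2.2", min_m == 1),
        ("2.3", (min_m == 2) & fs.f1 & fs.f2),
        ("2.4", (min_m == 2) & (fs.f1 | fs.f2)),
        ("2.5", fs.f3 & fs.f4),
    ]
    for step, mask in tiers:
        for i in np.flatnonzero(mask & ~chosen):
            chosen[i] = True
            selected.append(int(i))
            admit_step.append(step)
        if len(selected) >= cn:
            break
    return SelectionResult(selected=selected, admit_step=admit_step, target_count=cn)


def selection_report(result: SelectionResult, mm: MMatrix, fs: FilterState,
                     object_ids: list[str]) -> pd.DataFrame:
    """Per-selected-object report: id, tier, min_M, avg_m, count_m, F1–F4."""
    min_m = mm.values.min(axis=0)
    rows = []
    for i, step in zip(result.selected, result.admit_step):
        rows.append({
            "object_id": object_ids[i],
            "admit_step": step,
            "min_M": int(min_m[i]),
            "avg_m": fs.avg_m[i],
            "count_m": int(fs.count_m[i]),
            "F1": bool(fs.f1[i]), "F2": bool(fs.f2[i]),
            "F3": bool(fs.f3[i]), "F4": bool(fs.f4[i]),
        })
    return pd.DataFrame(rows, columns=["object_id", "admit_step", "min_M", "avg_m",
                                       "count_m", "F1", "F2", "F3", "F4"])
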
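"""Zone construction: per-variable partition of the unknown batch.

For each biomarker, the unknown objects are laid out in ascending order of
their transferred score. Each validation candidate owns two anchors on that
axis: a rank-implied position (where its known-batch rank ``bs`` falls among
the transferred ranks) and a score-implied position (where its concentration
``bx`` falls among the transferred scores). Ideally the two anchors point at
the same object; in practice they differ, and the interval between them is
the candidate's *region*:

* Case I — the score anchor lies to the right of the rank anchor: the region
  runs rightward from ``pi`` to the first object whose score reaches ``bx``.
* Case II — the score anchor lies to the left: the region runs leftward from
  ``pi + 1`` down to the first object whose score has dropped to ``bx``.

Regions from different candidates that share at least one position are merged
(transitively); merely adjacent regions stay distinct. The axis then splits
into maximal runs — covered or uncovered — numbered 1, 2, … left to right, so
every object gets exactly one integer zone label per variable, and every
candidate inherits the label of the run its region merged into. Uncovered
runs before the first and after the last region are numbered like any other
run: this is the only convention that leaves no object unlabelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Dataset
from .preprocessing import CandidateSet, TransferredTable

__all__ = ["Region", "ZoneTable", "find_candidate_region",
           "assign_zone_numbers", "build_zone_table", "zone_debug_table"]


@dataclass(frozen=True)
class Region:
    """One candidate's interval on one variable's score-ordered axis.

    ``lo``/``hi`` are 1-based inclusive positions, 1 ≤ lo ≤ hi ≤ n_A.
    """

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (1 <= self.lo <= self.hi):
            raise ValueError(f"malformed region [{self.lo}, {self.hi}]")


@dataclass
class ZoneTable:
    """Integer zone labels: a_zones is n_A × m, b_zones is cn × m."""

    a_zones: np.ndarray
    b_zones: np.ndarray


def find_candidate_region(t_scores_ordered: np.ndarray, t_ranks_ordered: np.ndarray,
                          bx: float, bs: float) -> Region:
    """Locate one candidate's region on a score-ordered variable axis.

    ``t_scores_ordered`` must be ascending; ``t_ranks_ordered`` are the
    transferred ranks in the same order (ascending by construction). ``bx``
    and ``bs`` are the candidate's known-batch score and rank. Positions are
    clamped to [1, n_A] whenever an anchor falls off either end of the axis.
    """
    xs = np.asarray(t_scores_ordered, dtype=float)
    rs = np.asarray(t_ranks_ordered, dtype=float)
    n = xs.size
    if n == 0:
        raise ValueError("empty unknown set")

    # rank anchor: last position whose transferred rank is <= bs
    below = np.flatnonzero(rs <= bs)
    pi = int(below[-1]) + 1 if below.size else 0  # 1-based; 0 = off the left end
    p = min(max(pi, 1), n)

    if p < n and xs[p] <= bx:  # xs[p] is position p+1 (0-based indexing)
        # Case I: walk right until the score reaches bx
        hi = n
        for j in range(p + 1, n + 1):
            if xs[j - 1] >= bx:
                hi = j
                break
        return Region(p, hi)
    if xs[p - 1] >= bx:
        # Case II: walk left from p until the score has dropped to bx
        lo = 1
        for j in range(p, 0, -1):
            if xs[j - 1] <= bx:
                lo = j
                break
        return Region(lo, min(p + 1, n))
    # bx strictly between scores at p and p+1: the k = 1 limit of Case I
    return Region(p, min(p + 1, n))


def assign_zone_numbers(regions: list[Region], n: int) -> tuple[np.ndarray, list[int]]:
    """Merge overlapping regions and number all maximal runs left to right.

    Returns ``(labels, candidate_labels)``: ``labels[i]`` is the zone of
    position ``i + 1``; ``candidate_labels[r]`` is the zone of the merged run
    containing ``regions[r]``. Overlap means sharing ≥ 1 position; adjacency
    alone does not merge. Gaps between covered runs — and terminal gaps —
    are runs of their own.
    """
    if not regions:
        raise ValueError("at least one region is required")
    for r in regions:
        if r.hi > n:
            raise ValueError(f"region [{r.lo}, {r.hi}] exceeds axis length {n}")

    # transitive merge of overlapping intervals
    order = sorted(range(len(regions)), key=lambda r: (regions[r].lo, regions[r].hi))
    merged: list[list[int]] = []          # [lo, hi] per merged run
    member: dict[int, int] = {}           # region index -> merged run index
    for ridx in order:
        reg = regions[ridx]
        if merged and reg.lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], reg.hi)
        else:
            merged.append([reg.lo, reg.hi])
        member[ridx] = len(merged) - 1

    labels = np.zeros(n, dtype=int)
    run_label: list[int] = []
    label = 0
    pos = 1
    for lo, hi in merged:
        if pos < lo:
            label += 1
            labels[pos - 1:lo - 1] = label
        label += 1
        labels[lo - 1:hi] = label
        run_label.append(label)
        pos = hi + 1
    if pos <= n:
        label += 1
        labels[pos - 1:] = label

    return labels, [run_label[member[r]] for r in range(len(regions))]


def build_zone_table(t: TransferredTable, c: CandidateSet) -> ZoneTable:
    """Zone every unknown object and every candidate, variable by variable.

    Per variable: sort unknown objects by transferred score (stable, so ties
    keep input order), place each candidate's region, merge and number runs,
    then map the position labels back to the objects' input order.
    """
    n, m = t.t_scores.shape
    if c.cand_scores.shape[1] != m:
        raise ValueError("candidate set and transferred table disagree on m")
    a_zones = np.empty((n, m), dtype=int)
    b_zones = np.empty((c.cn, m), dtype=int)
    for p in range(m):
        order = np.argsort(t.t_scores[:, p], kind="stable")
        xs = t.t_scores[order, p]
        rs = t.t_ranks[order, p]
        regions = [find_candidate_region(xs, rs, c.cand_scores[ej, p],
                                         c.cand_ranks[ej, p])
                   for ej in range(c.cn)]
        labels, cand_labels = assign_zone_numbers(regions, n)
        a_zones[order, p] = labels
        b_zones[:, p] = cand_labels
    return ZoneTable(a_zones=a_zones, b_zones=b_zones)


def zone_debug_table(a: Dataset, t: TransferredTable, z: ZoneTable,
                     variable_index: int) -> pd.DataFrame:
    """Per-variable zone map (position, object_id, t_score, t_rank, zone)."""
    p = variable_index
    order = np.argsort(t.t_scores[:, p], kind="stable")
    return pd.DataFrame({
        "position": np.arange(1, a.n + 1),
        "object_id": [a.object_ids[i] for i in order],
        "t_score": t.t_scores[order, p],
        "t_rank": t.t_ranks[order, p],
        "zone": z.a_zones[order, p],
    })
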
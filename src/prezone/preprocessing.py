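"""Ranking, validation-candidate extraction, and cross-batch transfer.

The selection algorithm compares an *unknown* batch A (no validation values)
against a *known* batch B (validation recorded). Preprocessing produces:

1. ordinal ranks of every biomarker within each batch (rank 1 = smallest
   concentration, ties broken by input position);
2. the validation candidate set: the lowest-validation ≈10% of the known
   batch, tie-extended at the boundary — these are the low-producer templates
   the unknown birds are matched against;
3. the transferred table: the unknown batch's ranks and scores mapped onto
   the known batch's scale, so positions in the two batches are comparable.

Rank transfer rescales positions by the size ratio, ``Ast = As · n_B / n_A``.
Score transfer matches z-scores: each unknown value is standardized with the
unknown batch's moments and re-expressed with the known batch's, i.e.
``Axt = (Ax − mean_A) · sd_B / sd_A + mean_B`` (sample SD, n−1, throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datasets import Dataset, DegenerateInputError

__all__ = [
    "CandidateSet",
    "TransferredTable",
    "rank_scores",
    "rank_dataset",
    "select_validation_candidates",
    "transfer_ranks",
    "transfer_scores",
    "build_transferred_table",
]

#: Fraction of the known batch taken as low-validation templates (tie-extended).
DEFAULT_CANDIDATE_FRACTION = 0.1

#: Rank direction is fixed: rank 1 = smallest value, in both batches.
RANK_DIRECTION = "ascending"


@dataclass
class CandidateSet:
    """The ``cn`` lowest-validation known objects, ordered by validation value.

    ``cand_scores``/``cand_ranks`` are ``cn × m``; ``cand_validation`` is
    non-decreasing; ``order_index`` is simply 1..cn.
    """

    object_ids: list[str]
    cand_scores: np.ndarray
    cand_ranks: np.ndarray
    cand_validation: np.ndarray

    @property
    def cn(self) -> int:
        return len(self.object_ids)

    @property
    def order_index(self) -> np.ndarray:
        return np.arange(1, self.cn + 1)


@dataclass
class TransferredTable:
    """Unknown-batch ranks and scores on the known batch's scale (n_A × m)."""

    t_ranks: np.ndarray
    t_scores: np.ndarray


def rank_scores(values: np.ndarray) -> np.ndarray:
    """Ordinal ranks 1..n, ascending in value; ties broken by input position.

    The earlier object gets the smaller rank, so each output is an exact
    permutation of 1..n — downstream zoning needs distinct positions.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise ValueError("rank_scores expects a non-empty 1-D vector")
    if not np.all(np.isfinite(values)):
        raise ValueError("rank_scores requires finite values")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=int)
    ranks[order] = np.arange(1, values.size + 1)
    return ranks


def rank_dataset(d: Dataset) -> np.ndarray:
    """Column-wise ordinal ranks of a dataset's score matrix (n × m)."""
    return np.column_stack([rank_scores(d.scores[:, p]) for p in range(d.m)])


def select_validation_candidates(b: Dataset, fraction: float = DEFAULT_CANDIDATE_FRACTION,
                                 ranks: np.ndarray | None = None) -> CandidateSet:
    """Extract the low-validation candidate set from the known batch.

    The base count is ``ceil(n_B · fraction)``; every object whose validation
    value ties the base-count-th smallest is also included, so the resulting
    ``cn`` may exceed the base count (e.g. 77 birds at fraction 0.1 give a
    base count of 8, extended to 9 when the 8th and 9th lowest egg numbers
    are equal). Candidates are ordered by ascending validation, ties by input
    position.
    """
    if not b.has_validation():
        raise ValueError("known dataset must carry a validation variable")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if ranks is None:
        ranks = rank_dataset(b)
    base = math.ceil(b.n * fraction)
    order = np.argsort(b.validation, kind="stable")
    boundary = b.validation[order[base - 1]]
    sel = order[b.validation[order] <= boundary]
    return CandidateSet(
        object_ids=[b.object_ids[j] for j in sel],
        cand_scores=b.scores[sel],
        cand_ranks=ranks[sel],
        cand_validation=b.validation[sel],
    )


def transfer_ranks(ranks_a: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """Rescale unknown-batch ranks onto the known batch's positions: As·n_B/n_A."""
    ranks_a = np.asarray(ranks_a, dtype=float)
    return ranks_a * (n_b / n_a)


def transfer_scores(scores_a: np.ndarray, mean_a: float, sd_a: float,
                    mean_b: float, sd_b: float,
                    variable: str = "") -> np.ndarray:
    """Z-score the unknown batch and re-express on the known batch's moments."""
    if sd_a <= 0:
        raise DegenerateInputError(
            f"variable {variable!r} is constant in the unknown dataset "
            "(zero SD); score transfer is undefined")
    scores_a = np.asarray(scores_a, dtype=float)
    return (scores_a - mean_a) * (sd_b / sd_a) + mean_b


def build_transferred_table(a: Dataset, b: Dataset,
                            ranks_a: np.ndarray | None = None) -> TransferredTable:
    """Map the whole unknown batch onto the known batch's scale, per variable."""
    if a.variable_names != b.variable_names:
        raise ValueError(
            f"variable mismatch: unknown {a.variable_names} vs known {b.variable_names}")
    if ranks_a is None:
        ranks_a = rank_dataset(a)
    t_ranks = transfer_ranks(ranks_a, a.n, b.n)
    t_scores = np.empty_like(a.scores)
    for p, name in enumerate(a.variable_names):
        t_scores[:, p] = transfer_scores(
            a.scores[:, p],
            a.scores[:, p].mean(), a.scores[:, p].std(ddof=1),
            b.scores[:, p].mean(), b.scores[:, p].std(ddof=1),
            variable=name,
        )
    return TransferredTable(t_ranks=t_ranks, t_scores=t_scores)
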
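"""Core data containers and delimited-table I/O.

A :class:`Dataset` holds one batch of individuals sampled at one stage:
an ``n × m`` matrix of biomarker concentrations (here typically serum
apolipoprotein A-I, X protein, apo VLDL-II and vitellogenin, in mg/mL-scale
units) plus, for a *known* batch, a validation variable — the trait being
selected against, e.g. total eggs laid per hen over the recording period.

Files are plain CSV/TSV: first column is the individual's id, the header row
names the biomarker variables, and an optional extra column carries the
validation variable.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "MissingPolicy",
    "DatasetFormatError",
    "DegenerateInputError",
    "read_dataset",
    "write_dataset",
    "summarize_dataset",
]


class DatasetFormatError(ValueError):
    """A cell could not be parsed or the table layout is malformed."""


class DegenerateInputError(ValueError):
    """The data are too small or too degenerate for the requested operation."""


class MissingPolicy(str, enum.Enum):
    """What to do with individuals that have empty biomarker/validation cells."""

    DROP_OBJECT = "drop_object"
    ERROR = "error"


@dataclass
class Dataset:
    """One batch of individuals at one sampling stage.

    Parameters
    ----------
    object_ids
        Opaque string labels, one per individual.
    scores
        ``n × m`` array of biomarker concentrations (float64).
    variable_names
        Names of the ``m`` biomarker variables, in column order.
    stage_label
        Free-text stage tag, e.g. ``"14wk"``.
    validation
        Optional per-individual validation values (egg counts, non-negative
        integers). Present for known batches, absent for unknown ones.
    """

    object_ids: list[str]
    scores: np.ndarray
    variable_names: list[str]
    stage_label: str = ""
    validation: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise DatasetFormatError("scores must be a 2-D n × m array")
        n, m = self.scores.shape
        if n < 2:
            raise DegenerateInputError(f"need at least 2 objects, got {n}")
        if m < 1:
            raise DegenerateInputError("need at least 1 variable")
        if len(self.object_ids) != n:
            raise DatasetFormatError("object_ids length does not match scores")
        if len(self.variable_names) != m:
            raise DatasetFormatError("variable_names length does not match scores")
        if self.validation is not None:
            self.validation = np.asarray(self.validation)
            if self.validation.shape != (n,):
                raise DatasetFormatError("validation must have one value per object")
            if np.any(self.validation < 0):
                raise DatasetFormatError("validation values must be non-negative")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def m(self) -> int:
        return self.scores.shape[1]

    def has_validation(self) -> bool:
        return self.validation is not None

    def subset(self, keep: np.ndarray) -> "Dataset":
        """Return a new Dataset restricted to a boolean/index mask, order kept."""
        keep = np.asarray(keep)
        ids = [self.object_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool \
            else [self.object_ids[i] for i in keep]
        val = None
        if self.validation is not None:
            val = self.validation[keep]
        return Dataset(ids, self.scores[keep], list(self.variable_names),
                       self.stage_label, val)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(
    path: str | Path,
    validation_column: str | None = None,
    missing: MissingPolicy = MissingPolicy.DROP_OBJECT,
    stage_label: str = "",
) -> Dataset:
    """Read one batch/stage table from CSV or TSV.

    The first column is taken as the object id; every other column is a
    biomarker except ``validation_column`` (if given), which is parsed as
    integer egg counts. Under ``MissingPolicy.DROP_OBJECT`` any row with an
    empty biomarker or validation cell is removed and logged by id; under
    ``MissingPolicy.ERROR`` such rows raise :class:`DatasetFormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise DatasetFormatError(f"{path}: need an id column plus at least one variable")
    id_col = df.columns[0]
    data_cols = [c for c in df.columns[1:]]
    if validation_column is not None:
        if validation_column not in data_cols:
            raise DatasetFormatError(
                f"{path}: validation column {validation_column!r} not found")
        data_cols = [c for c in data_cols if c != validation_column]

    def parse(col: str, kind: str) -> np.ndarray:
        out = np.full(len(df), np.nan)
        for r, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                out[r] = float(cell)
            except ValueError:
                raise DatasetFormatError(
                    f"{path}: unparseable {kind} value {cell!r} "
                    f"at row {r + 2}, column {col!r}") from None
        return out

    scores = np.column_stack([parse(c, "numeric") for c in data_cols])
    validation = parse(validation_column, "validation") if validation_column else None

    row_missing = np.isnan(scores).any(axis=1)
    if validation is not None:
        row_missing |= np.isnan(validation)
    if row_missing.any():
        if missing is MissingPolicy.ERROR:
            bad = df[id_col][row_missing].tolist()
            raise DatasetFormatError(f"{path}: missing cells for objects {bad}")
        for oid in df[id_col][row_missing]:
            logger.info("dropping object %r: missing cell(s)", oid)
    keep = ~row_missing
    if keep.sum() < 2:
        raise DegenerateInputError(
            f"{path}: fewer than 2 complete objects after dropping missing rows")

    ids = [str(x) for x in df[id_col][keep]]
    val = None
    if validation is not None:
        vv = validation[keep]
        if not np.allclose(vv, np.round(vv)):
            raise DatasetFormatError(f"{path}: validation column must hold integers")
        val = np.round(vv).astype(int)
    return Dataset(ids, scores[keep], data_cols, stage_label, val)


def write_dataset(d: Dataset, path: str | Path, validation_column: str = "egg") -> None:
    """Write a Dataset back out in the same dialect (CSV or TSV by suffix)."""
    path = Path(path)
    df = pd.DataFrame(d.scores, columns=d.variable_names)
    df.insert(0, "id", d.object_ids)
    if d.validation is not None:
        df[validation_column] = d.validation
    df.to_csv(path, sep=_sep_for(path), index=False)


def summarize_dataset(d: Dataset) -> pd.DataFrame:
    """Per-variable sample mean and sample SD (n−1 denominator).

    Returns a DataFrame with columns ``variable``, ``mean``, ``sd`` in the
    dataset's variable order. The n−1 convention is used uniformly across the
    package, including inside the cross-batch score transfer.
    """
    if d.n < 2:
        raise DegenerateInputError("summary needs at least 2 objects")
    return pd.DataFrame({
        "variable": d.variable_names,
        "mean": d.scores.mean(axis=0),
        "sd": d.scores.std(axis=0, ddof=1),
    })
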
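"""First-order multiple linear regression baseline.

The comparator fits egg number on the raw biomarker concentrations of the
known batch by ordinary least squares (egg = b0 + b1·x1 + … + bm·xm), predicts
egg numbers for the unknown batch, and selects the N individuals with the
lowest predictions — N taken from the zone method's selection so the two
approaches remove the same number of birds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datasets import Dataset, DegenerateInputError

__all__ = ["RegressionModel", "fit_ols", "predict_eggs", "select_lowest"]


@dataclass
class RegressionModel:
    intercept: float
    coefficients: np.ndarray
    variable_names: list[str]
    overall_p: float       # F-test of all slopes = 0
    n_fit: int

    def equation(self) -> str:
        """Human-readable fitted equation plus the overall P-value."""
        terms = "".join(f" {'+' if b >= 0 else '−'} {abs(b):.3g}·x{p + 1}"
                        for p, b in enumerate(self.coefficients))
        return f"egg = {self.intercept:.3g}{terms}  (P = {self.overall_p:.3g})"


def fit_ols(known: Dataset) -> RegressionModel:
    """OLS fit of the validation variable on all biomarkers of the known batch."""
    if not known.has_validation():
        raise ValueError("regression baseline needs a validation variable")
    if known.n <= known.m + 1:
        raise DegenerateInputError(
            f"need more than m+1 = {known.m + 1} objects to fit, got {known.n}")
    design = sm.add_constant(known.scores, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateInputError("singular design matrix (collinear biomarkers)")
    fit = sm.OLS(known.validation.astype(float), design).fit()
    return RegressionModel(
        intercept=float(fit.params[0]),
        coefficients=np.asarray(fit.params[1:]),
        variable_names=list(known.variable_names),
        overall_p=float(fit.f_pvalue),
        n_fit=known.n,
    )


def predict_eggs(model: RegressionModel, unknown: Dataset) -> np.ndarray:
    """Predicted egg numbers for the unknown batch, in input order."""
    if unknown.variable_names != model.variable_names:
        raise ValueError(
            f"variable mismatch: model {model.variable_names} "
            f"vs data {unknown.variable_names}")
    return model.intercept + unknown.scores @ model.coefficients


def select_lowest(predictions: np.ndarray, count: int) -> list[int]:
    """Indices of the ``count`` lowest predictions; boundary ties by input order."""
    predictions = np.asarray(predictions, dtype=float)
    if not (1 <= count <= predictions.size):
        raise ValueError(f"count must lie in [1, {predictions.size}], got {count}")
    order = np.argsort(predictions, kind="stable")
    return sorted(int(i) for i in order[:count])
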
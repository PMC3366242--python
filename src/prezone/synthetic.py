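"""Synthetic flock generator.

Emulates the study conditions the pipeline was designed for: batches of
roughly 60–77 hens, serum biomarker concentrations measured at several ages
with batch/stage-specific means and SDs, per-hen total egg counts over the
laying period, and — crucially — only weak linear correlation (|r| mostly
below 0.25) between every biomarker and egg number.

Concentrations are drawn from normals truncated at zero (concentrations are
non-negative; for variables whose SD approaches the mean the truncation
noticeably raises the realized mean above the nominal one). Egg counts are
rounded normals clipped at zero.

An optional *planted signature* makes the flock's worst layers detectable:
hens in the lowest egg-count decile get their biomarker means shifted by
``signature_effect`` SDs, half of them upward and half downward (each hen
keeps its own direction across stages). The two-sided shift leaves the
Pearson biomarker–egg correlation near zero — the weak-correlation regime the
zone method targets — while giving low producers extreme, matchable profiles.
Realized correlations are checked against ``max_abs_corr`` and the stage is
resampled up to a bounded retry count; exhausting it raises
:class:`InfeasibleSpecError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import Dataset

__all__ = ["StageMoments", "FlockSpec", "InfeasibleSpecError", "generate_flock",
           "REFERENCE_MOMENTS", "REFERENCE_EGG_MEANS", "reference_spec"]


class InfeasibleSpecError(RuntimeError):
    """The correlation bound could not be met within the retry budget."""


@dataclass
class StageMoments:
    """Per-stage biomarker moments: (mean, sd) per variable name."""

    label: str
    moments: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (_, sd) in self.moments.items():
            if sd <= 0:
                raise ValueError(f"variable {name!r}: SD must be positive")


# Published per-batch serum-protein moments for the study breed (mg/mL-scale
# units): apolipoprotein A-I, X protein (IGF-I-like), apo VLDL-II, and — at the
# later ages only — vitellogenin.
REFERENCE_MOMENTS: dict[str, list[StageMoments]] = {
    "A": [
        StageMoments("14wk", {"apoA1": (1.726, 0.347), "Xprot": (0.245, 0.203),
                              "VLDL2": (0.043, 0.080)}),
        StageMoments("24wk", {"apoA1": (2.710, 1.684), "Xprot": (0.720, 0.470),
                              "VLDL2": (0.200, 0.190), "vitell": (0.813, 0.906)}),
    ],
    "B": [
        StageMoments("14wk", {"apoA1": (2.641, 0.732), "Xprot": (0.594, 0.293),
                              "VLDL2": (0.035, 0.049)}),
        StageMoments("24wk", {"apoA1": (2.219, 1.083), "Xprot": (1.292, 0.410),
                              "VLDL2": (0.374, 0.300), "vitell": (1.036, 0.786)}),
    ],
    "C": [
        StageMoments("8wk", {"apoA1": (2.752, 0.894), "Xprot": (0.169, 0.087),
                             "VLDL2": (0.026, 0.033)}),
        StageMoments("14wk", {"apoA1": (2.156, 0.311), "Xprot": (0.416, 0.216),
                              "VLDL2": (0.024, 0.031)}),
        StageMoments("22wk", {"apoA1": (2.631, 0.854), "Xprot": (0.871, 0.490),
                              "VLDL2": (0.316, 0.342), "vitell": (0.494, 0.482)}),
    ],
}

#: Published flock-mean egg counts (25–48 wks of age) per batch.
REFERENCE_EGG_MEANS = {"A": 94.57, "B": 103.91, "C": 85.1}

#: Published batch sizes.
REFERENCE_N = {"A": 76, "B": 77, "C": 60}

#: Egg-count SD: the source tables report only means; ~20% CV is typical for
#: an unselected dual-purpose flock, giving an SD near 19 eggs at mean ≈ 95.
DEFAULT_EGG_SD = 19.0


@dataclass
class FlockSpec:
    """Everything needed to simulate one flock across its sampling stages."""

    n: int
    stages: list[StageMoments]
    egg_mean: float = 94.57
    egg_sd: float = DEFAULT_EGG_SD
    max_abs_corr: float = 0.25
    signature_effect: float = 0.0  # shift of decile birds' means, in SD units
    missing_rate: float = 0.0
    seed: int = 0
    max_retries: int = 200
    batch_label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not (0 <= self.max_abs_corr < 1):
            raise ValueError("max_abs_corr must lie in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.egg_sd <= 0 or self.egg_mean < 0:
            raise ValueError("egg moments must be positive")


def reference_spec(batch: str, seed: int = 0, signature_effect: float = 0.0,
                   n: int | None = None) -> FlockSpec:
    """A FlockSpec mirroring one of the published batches (A, B or C)."""
    return FlockSpec(
        n=n if n is not None else REFERENCE_N[batch],
        stages=REFERENCE_MOMENTS[batch],
        egg_mean=REFERENCE_EGG_MEANS[batch],
        signature_effect=signature_effect,
        seed=seed,
        batch_label=batch,
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _corr_ok(scores: np.ndarray, eggs: np.ndarray, bound: float) -> bool:
    for p in range(scores.shape[1]):
        col = scores[:, p]
        ok = ~np.isnan(col)
        if ok.sum() < 3 or np.std(col[ok]) == 0 or np.std(eggs[ok]) == 0:
            continue
        if abs(np.corrcoef(col[ok], eggs[ok])[0, 1]) > bound:
            return False
    return True


def generate_flock(spec: FlockSpec) -> tuple[dict[str, Dataset], np.ndarray]:
    """Simulate one flock: one Dataset per stage plus the shared egg vector.

    Every stage Dataset carries the same per-hen egg counts as its validation
    variable. Identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    eggs = np.clip(np.round(rng.normal(spec.egg_mean, spec.egg_sd, spec.n)),
                   0, None).astype(int)

    # signature birds: lowest egg decile; each keeps one shift direction
    decile = math.ceil(spec.n * 0.1)
    low_idx = np.argsort(eggs, kind="stable")[:decile]
    signs = np.array([1 if k % 2 == 0 else -1 for k in range(decile)])
    rng.shuffle(signs)

    ids = [f"{spec.batch_label or 'bird'}{i + 1:03d}" for i in range(spec.n)]
    datasets: dict[str, Dataset] = {}
    for stage in spec.stages:
        names = list(stage.moments)
        scores = None
        for _ in range(spec.max_retries):
            cols = []
            for name in names:
                mean, sd = stage.moments[name]
                col = _truncated_normal(rng, mean, sd, spec.n)
                if spec.signature_effect != 0.0:
                    shifted = mean + signs * spec.signature_effect * sd
                    col[low_idx] = np.clip(
                        rng.normal(shifted, sd), 0.0, None)
                cols.append(col)
            cand = np.column_stack(cols)
            if _corr_ok(cand, eggs, spec.max_abs_corr):
                scores = cand
                break
        if scores is None:
            raise InfeasibleSpecError(
                f"stage {stage.label!r}: could not satisfy |r| <= "
                f"{spec.max_abs_corr} within {spec.max_retries} tries")
        if spec.missing_rate > 0:
            mask = rng.random(scores.shape) < spec.missing_rate
            scores = scores.copy()
            scores[mask] = np.nan
        datasets[stage.label] = Dataset(
            object_ids=list(ids), scores=scores, variable_names=names,
            stage_label=stage.label, validation=eggs.copy(),
        )
    return datasets, eggs
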
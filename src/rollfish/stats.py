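"""Summary statistics, replicate correlation, and the ROC cutoff screen.

The ROC screen turns per-sample mean spots/cell into a binary HER2 call:
IHC 2+/3+ samples are treated as truly positive, norm/0/1+ as negative,
and a grid of 100 candidate cutoffs (0.05 to 5.00 in steps of 0.05 spots
per cell) is swept; a sample is called positive when its mean spots/cell
is at or above the cutoff. The operating point maximizing Youden's
J = sensitivity + specificity − 1 is reported alongside the trapezoidal
AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .simgen import IHC_SCORES

__all__ = [
    "ROCResult",
    "CorrelationResult",
    "summarize_counts",
    "replicate_correlation",
    "binarize_ihc",
    "roc_screen",
]

#: IHC scores treated as truly HER2-positive.
POSITIVE_SCORES = frozenset({"2+", "3+"})


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float


@dataclass(frozen=True)
class ROCResult:
    """Result of the cutoff screen.

    ``cutoffs`` are strictly increasing; ``sensitivity`` is non-increasing
    and ``specificity`` non-decreasing along them (enforced at
    construction). ``optimal_*`` is the Youden-J-maximizing operating
    point, ties broken toward the smaller cutoff.
    """

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    optimal_sensitivity: float
    optimal_specificity: float

    def __post_init__(self):
        if np.any(np.diff(self.cutoffs) <= 0):
            raise InvalidInputError("cutoffs must be strictly increasing")
        if np.any(np.diff(self.sensitivity) > 1e-12):
            raise InvalidInputError("sensitivity must be non-increasing in cutoff")
        if np.any(np.diff(self.specificity) < -1e-12):
            raise InvalidInputError("specificity must be non-decreasing in cutoff")
        if not 0.0 <= self.auc <= 1.0:
            raise InvalidInputError("AUC must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def summarize_counts(values) -> dict[str, float]:
    """Distribution summary matching box-plot conventions.

    Returns median, 25th/75th percentiles (box) and 2.5th/97.5th
    percentiles (whiskers), all by linear interpolation between closest
    order statistics. Raises on empty input.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("summarize_counts requires >= 1 value")
    p = np.percentile(v, [2.5, 25, 50, 75, 97.5], method="linear")
    return {
        "p2_5": float(p[0]),
        "p25": float(p[1]),
        "median": float(p[2]),
        "p75": float(p[3]),
        "p97_5": float(p[4]),
    }


def replicate_correlation(x, y) -> CorrelationResult:
    """Pearson correlation between replicate sample means.

    Reports r, R² = r² (the squared product-moment correlation, the
    convention used for replicate reproducibility), and a two-sided
    p-value from the t transform with n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("x and y must be paired (equal length)")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, p_value=float(res.pvalue))


def binarize_ihc(scores) -> np.ndarray:
    """Binarize IHC scores: 2+ and 3+ are positive; norm, 0, 1+ negative."""
    scores = list(scores)
    unknown = set(scores) - set(IHC_SCORES)
    if unknown:
        raise InvalidInputError(f"unknown IHC scores {sorted(unknown)}; allowed: {IHC_SCORES}")
    return np.array([s in POSITIVE_SCORES for s in scores], dtype=bool)


def roc_screen(
    samples: pd.DataFrame,
    *,
    start: float = 0.05,
    step: float = 0.05,
    n_cutoffs: int = 100,
) -> ROCResult:
    """Screen mean-spots-per-cell cutoffs for separating HER2-positive samples.

    ``samples`` needs columns ``ihc_score`` and ``mean_spots_per_cell``.
    For each cutoff t in {start, start+step, ...} (``n_cutoffs`` values,
    default 0.05 to 5.00) a sample is predicted positive iff its mean
    spots/cell >= t (inclusive rule). AUC is trapezoidal over the
    (1−specificity, sensitivity) curve with the (0,0) and (1,1) corners
    appended.
    """
    if start <= 0 or step <= 0 or n_cutoffs < 1:
        raise InvalidParameterError("start, step must be > 0 and n_cutoffs >= 1")
    labels = binarize_ihc(samples["ihc_score"])
    values = np.asarray(samples["mean_spots_per_cell"], dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("need at least one positive and one negative sample")

    cutoffs = start + step * np.arange(n_cutoffs)
    pred = values[None, :] >= cutoffs[:, None]  # (n_cutoffs, n_samples)
    tp = (pred & labels[None, :]).sum(axis=1)
    fp = (pred & ~labels[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg

    fpr = 1.0 - spec
    # cutoffs ascend -> fpr descends; build the curve left to right
    xs = np.concatenate(([0.0], fpr[::-1], [1.0]))
    ys = np.concatenate(([0.0], sens[::-1], [1.0]))
    auc = float(np.trapezoid(ys, xs))

    youden = sens + spec - 1.0
    best = int(np.argmax(youden))  # first occurrence -> smallest cutoff on ties
    return ROCResult(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff=float(cutoffs[best]),
        optimal_sensitivity=float(sens[best]),
        optimal_specificity=float(spec[best]),
    )
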
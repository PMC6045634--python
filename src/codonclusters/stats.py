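"""Study statistics: Pearson correlation with two-tailed p, densitometric
solubility quantification, binary-classifier evaluation (prediction accuracy
and Matthews correlation coefficient), regression-band outlier exclusion and
discrete expression/solubility score averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DomainError, RegressionError, UndefinedStatisticError

__all__ = [
    "CorrelationResult",
    "ConfusionMatrix",
    "OutlierFilterResult",
    "pearson_with_p",
    "solubility_fraction",
    "classify_soluble",
    "prediction_accuracy",
    "mcc",
    "confusion_matrix",
    "regression_outlier_filter",
    "spine_average",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with sample size and two-tailed p.

    ``defined`` is False when the correlation does not exist for the input
    (fewer than 3 points, or zero variance in either variable); r and p are
    then NaN.  Undefined results are a distinct state, never coerced to 0.
    """

    r: float
    n: int
    p_two_tailed: float
    defined: bool = True

    @classmethod
    def undefined(cls, n: int) -> "CorrelationResult":
        return cls(r=float("nan"), n=n, p_two_tailed=float("nan"), defined=False)


def pearson_with_p(
    x: Sequence[float], y: Sequence[float], require_defined: bool = False
) -> CorrelationResult:
    """Pearson product-moment correlation with a two-tailed p-value.

    p is obtained from ``t = r * sqrt((n - 2) / (1 - r^2))`` referred to a
    Student t distribution with n - 2 degrees of freedom.  Inputs with
    n < 3 or zero variance yield an undefined (flagged) result, or raise
    :class:`UndefinedStatisticError` when ``require_defined`` is set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError(f"x and y must be equal-length 1-d arrays ({x.shape} vs {y.shape})")
    n = len(x)

    def _constant(v: np.ndarray) -> bool:
        # scale-relative: a profile flat at +100 up to rounding jitter is
        # constant for all scientific purposes
        return np.ptp(v) <= 1e-12 * max(1.0, float(np.max(np.abs(v))))

    if n < 3 or _constant(x) or _constant(y):
        if require_defined:
            raise UndefinedStatisticError(
                f"Pearson correlation undefined (n={n}, "
                f"var_x={np.var(x):.3g}, var_y={np.var(y):.3g})"
            )
        return CorrelationResult.undefined(n)
    dx = x - x.mean()
    dy = y - y.mean()
    r = float(np.dot(dx, dy) / np.sqrt(np.dot(dx, dx) * np.dot(dy, dy)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p_two_tailed=p, defined=True)


def solubility_fraction(i_sf: float, i_if: float) -> float:
    """Soluble-band intensity over total intensity, Isf / (Isf + Iif)."""
    if i_sf < 0 or i_if < 0:
        raise DomainError("band intensities must be non-negative")
    total = i_sf + i_if
    if total == 0:
        raise UndefinedStatisticError("both band intensities are zero")
    return i_sf / total


def classify_soluble(fraction: float, threshold: float = 0.30) -> bool:
    """Binary solubility call: soluble iff fraction > threshold (strict)."""
    if not 0.0 <= fraction <= 1.0:
        raise DomainError(f"solubility fraction {fraction} outside [0, 1]")
    return fraction > threshold


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise DomainError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_matrix(truth: Sequence[bool], predicted: Sequence[bool]) -> ConfusionMatrix:
    """Tally a 2x2 confusion matrix from parallel boolean sequences."""
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise DomainError("truth and prediction lengths differ")
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def prediction_accuracy(cm: ConfusionMatrix) -> float:
    """(TN + TP) / (TN + FP + FN + TP)."""
    if cm.total == 0:
        raise DomainError("empty confusion matrix")
    return (cm.tn + cm.tp) / cm.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 by convention when any marginal
    (TP+FP, TP+FN, TN+FP, TN+FN) is zero."""
    if cm.total == 0:
        raise DomainError("empty confusion matrix")
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / np.sqrt(denom)


@dataclass(frozen=True)
class OutlierFilterResult:
    """Outcome of the regression-band outlier screen."""

    kept: np.ndarray          # indices into the input arrays
    excluded: np.ndarray
    slope: float
    intercept: float
    band: str                 # "confidence" or "prediction"
    multiple: float

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def regression_outlier_filter(
    x: Sequence[float],
    y: Sequence[float],
    multiple: float = 3.0,
    band: str = "confidence",
    alpha: float = 0.05,
) -> OutlierFilterResult:
    """Exclude points far outside the OLS regression band.

    Fits ordinary least squares y ~ x, computes the 95% band half-width at
    each point's abscissa (``band="confidence"`` for the mean-response band,
    ``"prediction"`` for the observation band) and excludes points whose
    absolute residual exceeds ``multiple`` times that half-width.  Single
    pass; no refitting.

    The two bands behave very differently at screen scale (n ~ 30).  The
    confidence band shrinks as 1/sqrt(n): 3x its half-width is roughly
    1.1 residual standard deviations, so it reliably catches a single gross
    outlier (whose displacement dominates the residual scale) but also
    trims ~15% of well-behaved points.  The prediction band tracks the
    observation scatter: 3x its half-width is ~6 residual standard
    deviations, which a lone outlier can never exceed once it has inflated
    the fit's own residual variance.  Dataset-level analyses that care
    about type-I error should prefer ``band="prediction"`` (see the study
    model, which defaults to it).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 4:
        raise RegressionError(f"need at least 4 points, got {n}")
    if np.ptp(x) == 0:
        raise RegressionError("zero variance in x; regression undefined")
    if band not in ("confidence", "prediction"):
        raise ValueError(f"unknown band type {band!r}")

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X)
    frame = pred.summary_frame(alpha=alpha)
    if band == "confidence":
        lo, hi = frame["mean_ci_lower"].to_numpy(), frame["mean_ci_upper"].to_numpy()
    else:
        lo, hi = frame["obs_ci_lower"].to_numpy(), frame["obs_ci_upper"].to_numpy()
    half_width = (hi - lo) / 2.0
    resid = y - fit.fittedvalues
    # guard: on (near-)exactly linear data both sides are at rounding scale
    atol = 1e-10 * (np.abs(y).max() + np.ptp(x))
    out = np.abs(resid) > multiple * half_width + atol
    return OutlierFilterResult(
        kept=np.nonzero(~out)[0],
        excluded=np.nonzero(out)[0],
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        band=band,
        multiple=multiple,
    )


def spine_average(scores: Sequence[int]) -> float:
    """Mean of discrete 0-5 expression/solubility scores."""
    if len(scores) == 0:
        raise DomainError("empty score list")
    for s in scores:
        if s != int(s) or not 0 <= int(s) <= 5:
            raise DomainError(f"score {s} outside the discrete 0-5 scale")
    return float(np.mean([int(s) for s in scores]))
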
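"""Standard binary-classification performance measures.

Definitions follow the probabilistic framing of binary classification:
examples ``(x, y)`` are drawn from a mixture ``h = pi*h1 + (1-pi)*h0`` of a
positive-class density ``h1`` and a negative-class density ``h0``, and a
thresholded classifier predicts positive iff its score is >= tau.  The
fundamental rates are

* ``gamma`` — true positive rate (sensitivity), ``E_{h1}[yhat]``
* ``eta``   — false positive rate, ``E_{h0}[yhat]``
* ``pi``    — positive class prior
* ``theta`` — probability of a positive prediction, ``pi*gamma + (1-pi)*eta``
* ``rho``   — precision, ``pi*gamma/theta``

and the four composite measures are accuracy, balanced accuracy, F-measure
and the Matthews correlation coefficient, expressed in terms of the rates so
the same formulas serve both count-based estimation and analytic models.

Undefined quantities (e.g. the true positive rate of a data set with no
positives) are carried as NaN, never silently coerced to 0, so downstream
corrections can propagate undefinedness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "RateEstimates",
    "MetricSet",
    "confusion_from_scores",
    "estimate_rates",
    "acc_from_rates",
    "bacc_from_rates",
    "f_from_rates",
    "mcc_from_rates",
    "metrics_from_cm",
]

ArrayLike = Union[float, np.ndarray]

#: Valid flavors of a MetricSet: measured against true labels, against
#: pseudo-labels (labeled=1/unlabeled=0), or corrected back to the
#: traditional scale with real or estimated contamination parameters.
FLAVORS = ("true", "pu", "corrected_real", "corrected_estimated")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a thresholded classifier against a binary label column."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fn, self.fp, self.tn)
        if any(v < 0 for v in counts):
            raise ValueError(f"confusion-matrix counts must be >= 0, got {counts}")
        if sum(counts) == 0:
            raise ValueError("confusion matrix must contain at least one example")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_pos(self) -> int:
        """Examples whose label is positive (row margin)."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def n_pred_pos(self) -> int:
        """Examples predicted positive (column margin)."""
        return self.tp + self.fp


@dataclass(frozen=True)
class RateEstimates:
    """Plug-in rate estimates derived from one confusion matrix.

    ``gamma = tp/(tp+fn)``, ``eta = fp/(fp+tn)``, ``pi = (tp+fn)/n``,
    ``theta = (tp+fp)/n`` and ``rho = tp/(tp+fp)``; a rate whose margin is
    zero is NaN.
    """

    gamma: float
    eta: float
    pi: float
    theta: float
    rho: float

    def is_defined(self, name: str) -> bool:
        return not math.isnan(getattr(self, name))


@dataclass(frozen=True)
class MetricSet:
    """The four composite measures in one evaluation flavor.

    ``clipped`` names the metrics whose corrected value fell outside its
    admissible range and was clipped back (only ever non-empty for the
    corrected flavors).
    """

    acc: float
    bacc: float
    f: float
    mcc: float
    flavor: str = "true"
    clipped: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.flavor not in FLAVORS:
            raise ValueError(f"flavor must be one of {FLAVORS}, got {self.flavor!r}")

    def as_dict(self) -> dict:
        return {
            "acc": self.acc,
            "bacc": self.bacc,
            "f": self.f,
            "mcc": self.mcc,
            "flavor": self.flavor,
            "clipped": list(self.clipped),
        }


def _check_unit_interval(**named: ArrayLike) -> None:
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def confusion_from_scores(scores, labels, tau: float) -> ConfusionMatrix:
    """Threshold ``scores`` at ``tau`` and count against binary ``labels``.

    The prediction is positive iff ``score >= tau`` (half-closed convention:
    boundary scores predict positive).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("scores must be non-empty")
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores and labels must have equal shape, got {scores.shape} vs {labels.shape}"
        )
    if not np.isin(labels, (0, 1)).all():
        bad = np.unique(labels[~np.isin(labels, (0, 1))])
        raise ValueError(f"labels must be binary (0/1), found {bad.tolist()}")
    labels = labels.astype(bool)
    pred = scores >= tau
    return ConfusionMatrix(
        tp=int(np.count_nonzero(pred & labels)),
        fn=int(np.count_nonzero(~pred & labels)),
        fp=int(np.count_nonzero(pred & ~labels)),
        tn=int(np.count_nonzero(~pred & ~labels)),
    )


def estimate_rates(cm: ConfusionMatrix) -> RateEstimates:
    """Standard rate estimators from confusion-matrix counts.

    Rates whose defining margin is empty come back NaN (e.g. gamma with no
    positive examples) rather than a silent zero.
    """
    n = cm.n
    gamma = cm.tp / cm.n_pos if cm.n_pos > 0 else math.nan
    eta = cm.fp / cm.n_neg if cm.n_neg > 0 else math.nan
    rho = cm.tp / cm.n_pred_pos if cm.n_pred_pos > 0 else math.nan
    return RateEstimates(
        gamma=gamma, eta=eta, pi=cm.n_pos / n, theta=cm.n_pred_pos / n, rho=rho
    )


def acc_from_rates(gamma: ArrayLike, eta: ArrayLike, pi: ArrayLike) -> ArrayLike:
    """Accuracy ``pi*gamma + (1-pi)*(1-eta)``."""
    _check_unit_interval(gamma=gamma, eta=eta, pi=pi)
    out = np.asarray(pi, dtype=float) * gamma + (1.0 - np.asarray(pi, dtype=float)) * (
        1.0 - np.asarray(eta, dtype=float)
    )
    return float(out) if out.ndim == 0 else out


def bacc_from_rates(gamma: ArrayLike, eta: ArrayLike) -> ArrayLike:
    """Balanced accuracy ``(1 + gamma - eta)/2``."""
    _check_unit_interval(gamma=gamma, eta=eta)
    out = (1.0 + np.asarray(gamma, dtype=float) - np.asarray(eta, dtype=float)) / 2.0
    return float(out) if out.ndim == 0 else out


def f_from_rates(gamma: ArrayLike, pi: ArrayLike, theta: ArrayLike) -> ArrayLike:
    """F-measure ``2*pi*gamma/(pi + theta)``, the harmonic mean of recall and
    precision; NaN where ``pi + theta == 0``."""
    _check_unit_interval(gamma=gamma, pi=pi, theta=theta)
    gamma = np.asarray(gamma, dtype=float)
    pi_a = np.asarray(pi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pi_a + theta > 0, 2.0 * pi_a * gamma / (pi_a + theta), np.nan)
    return float(out) if out.ndim == 0 else out


def mcc_from_rates(
    gamma: ArrayLike, eta: ArrayLike, pi: ArrayLike, theta: ArrayLike
) -> ArrayLike:
    """Matthews correlation ``sqrt(pi*(1-pi)/(theta*(1-theta))) * (gamma - eta)``.

    This is the Pearson correlation between the true and predicted class
    indicators; NaN where the predictor or the population is degenerate
    (``theta`` or ``pi`` in {0, 1}).
    """
    _check_unit_interval(gamma=gamma, eta=eta, pi=pi, theta=theta)
    gamma = np.asarray(gamma, dtype=float)
    eta = np.asarray(eta, dtype=float)
    pi_a = np.asarray(pi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    denom = theta * (1.0 - theta)
    interior = (denom > 0) & (pi_a > 0) & (pi_a < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            interior, np.sqrt(pi_a * (1.0 - pi_a) / np.where(denom > 0, denom, 1.0)) * (gamma - eta), np.nan
        )
    return float(out) if out.ndim == 0 else out


def metrics_from_cm(cm: ConfusionMatrix, flavor: str = "true") -> MetricSet:
    """The four sample metrics from counts.

    ``mcc`` uses the count form ``(tp*tn - fp*fn)/sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))``,
    algebraically identical to the rate form.  A metric whose margins vanish
    is NaN, except F of a classifier that predicts nothing positive while
    positives exist, which is reported as 0 (with a warning) so threshold
    sweeps remain total.
    """
    n = cm.n
    acc = (cm.tp + cm.tn) / n

    if cm.n_pos > 0 and cm.n_neg > 0:
        bacc = 0.5 * cm.tp / cm.n_pos + 0.5 * cm.tn / cm.n_neg
    else:
        bacc = math.nan

    f_denom = 2 * cm.tp + cm.fn + cm.fp
    if f_denom > 0:
        f = 2 * cm.tp / f_denom
        if cm.n_pred_pos == 0 and cm.n_pos > 0:
            warnings.warn(
                "F-measure of a classifier with no positive predictions is an "
                "undefined harmonic mean; reporting 0 by convention",
                RuntimeWarning,
                stacklevel=2,
            )
    else:
        f = math.nan

    margins = cm.n_pred_pos * cm.n_pos * (cm.tn + cm.fn) * cm.n_neg
    if margins > 0:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(margins)
    else:
        mcc = math.nan

    return MetricSet(acc=acc, bacc=bacc, f=f, mcc=mcc, flavor=flavor)
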
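"""Bias correction of performance metrics estimated on positive-unlabeled data.

When a classifier is evaluated against pseudo-labels (labeled set = 1,
unlabeled set = 0) the standard rate estimators are biased: gamma-hat and
eta-hat converge to the pseudo rates

    gamma_pu = beta*gamma + (1-beta)*eta      (rate on the labeled mixture g)
    eta_pu   = alpha*gamma + (1-alpha)*eta    (rate on the unlabeled mixture f)

where ``alpha`` is the proportion of positives contaminating the unlabeled
set, ``beta`` the proportion of true positives in the labeled set, and the
pseudo prior is the labeled fraction ``c`` rather than the true prior
``pi = c*beta + (1-c)*alpha``.  Only ``theta``, the probability of a positive
prediction, is estimated without bias.

Because the pseudo rates are an invertible linear mixing of the true rates
(whenever ``beta > alpha``), the traditional rates — and hence accuracy,
balanced accuracy, F and MCC — can be recovered exactly given ``(alpha,
beta, c)``.  Balanced accuracy and MCC additionally admit direct monotone
conversions from their pseudo-label values, so the threshold maximizing the
pseudo metric also maximizes the traditional one.

Class-prior / noise estimation itself is out of scope: ``(alpha, beta)`` are
inputs, supplied by any external mixture-proportion estimator through the
:data:`AlphaBetaEstimator` plugin contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple, Union

import numpy as np

from .metrics import (
    MetricSet,
    acc_from_rates,
    bacc_from_rates,
    f_from_rates,
    mcc_from_rates,
)

__all__ = [
    "PUContext",
    "PURateEstimates",
    "CorrectedRates",
    "AlphaBetaEstimator",
    "prior_from_mixture",
    "pu_rates_from_true",
    "correct_rates",
    "pu_metrics",
    "corrected_metrics",
    "bacc_from_pu",
    "mcc_from_pu",
]

ArrayLike = Union[float, np.ndarray]

#: Plugin contract for external mixture-proportion estimators: a callable
#: mapping (labeled scores, unlabeled scores) to an (alpha_hat, beta_hat) pair.
AlphaBetaEstimator = Callable[[np.ndarray, np.ndarray], Tuple[float, float]]

#: Minimum identifiable separation beta - alpha; smaller gaps are rejected
#: rather than allowed to produce exploding corrections.
DEFAULT_MIN_GAP = 1e-6

#: Admissible range of each corrected metric; corrected estimates are clipped
#: into these ranges (bacc below 1/2 indicates pure noise, not signal).
CLIP_RANGES = {"acc": (0.0, 1.0), "bacc": (0.5, 1.0), "f": (0.0, 1.0), "mcc": (-1.0, 1.0)}


@dataclass(frozen=True)
class PUContext:
    """Contamination parameters of a positive-unlabeled evaluation set.

    Parameters
    ----------
    alpha : float
        Proportion of positives in the unlabeled set, in ``[0, 1)``.
    beta : float
        Proportion of true positives in the labeled set, in ``(0, 1]``;
        ``1 - beta`` is the labeling noise.
    c : float
        Labeled fraction ``|L| / (|L| + |U|)``, in ``(0, 1)``.

    The implied true class prior ``pi = c*beta + (1-c)*alpha`` is maintained
    automatically.
    """

    alpha: float
    beta: float
    c: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if not 0.0 < self.c < 1.0:
            raise ValueError(f"c must be in (0, 1), got {self.c}")
        if self.beta <= self.alpha:
            raise ValueError(
                f"correction not identifiable: beta ({self.beta}) must exceed alpha ({self.alpha})"
            )

    @property
    def pi(self) -> float:
        """Implied positive-class prior of the full population."""
        return prior_from_mixture(self.alpha, self.beta, self.c)

    def as_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "c": self.c, "pi": self.pi}


@dataclass(frozen=True)
class PURateEstimates:
    """Pseudo-label rate estimates: what the standard estimators actually
    measure under positive-unlabeled evaluation."""

    gamma_pu: float
    eta_pu: float
    c: float
    theta: float


@dataclass(frozen=True)
class CorrectedRates:
    """Traditional rate estimates recovered from pseudo-label rates.

    ``clipped`` names the rates whose raw corrected value fell outside
    ``[0, 1]`` (possible for noisy inputs or misestimated alpha/beta) and was
    clipped back.
    """

    gamma: ArrayLike
    eta: ArrayLike
    pi: float
    clipped: tuple = ()


def prior_from_mixture(alpha: float, beta: float, c: float) -> float:
    """True prior implied by the partition of the data into labeled and
    unlabeled sets: ``pi = c*beta + (1-c)*alpha``."""
    return c * beta + (1.0 - c) * alpha


def pu_rates_from_true(
    gamma: ArrayLike, eta: ArrayLike, ctx: PUContext
) -> Tuple[ArrayLike, ArrayLike]:
    """Forward map from traditional to pseudo-label rates.

    ``gamma_pu = beta*gamma + (1-beta)*eta`` and
    ``eta_pu = alpha*gamma + (1-alpha)*eta``; both are convex combinations,
    so they stay in ``[0, 1]``, and their gap contracts by exactly
    ``beta - alpha``.
    """
    gamma = np.asarray(gamma, dtype=float)
    eta = np.asarray(eta, dtype=float)
    gamma_pu = ctx.beta * gamma + (1.0 - ctx.beta) * eta
    eta_pu = ctx.alpha * gamma + (1.0 - ctx.alpha) * eta
    if gamma_pu.ndim == 0:
        return float(gamma_pu), float(eta_pu)
    return gamma_pu, eta_pu


def correct_rates(
    gamma_hat: ArrayLike,
    eta_hat: ArrayLike,
    c: float,
    alpha_hat: float,
    beta_hat: float,
    *,
    min_gap: float = DEFAULT_MIN_GAP,
    clip: bool = True,
) -> CorrectedRates:
    """Invert the pseudo-label mixing to recover traditional rate estimates.

    Implements

        gamma_cr = ((1-alpha)*gamma_hat - (1-beta)*eta_hat) / (beta - alpha)
        eta_cr   = (beta*eta_hat - alpha*gamma_hat) / (beta - alpha)
        pi_cr    = c*beta + (1-c)*alpha

    which is the exact inverse of :func:`pu_rates_from_true` when
    ``(alpha_hat, beta_hat)`` equal the true contamination parameters.  With
    sampling noise or misestimated parameters the raw values can leave
    ``[0, 1]``; they are then clipped (when ``clip``) and the event recorded
    in ``CorrectedRates.clipped``.
    """
    if beta_hat - alpha_hat <= min_gap:
        raise ValueError(
            "correction not identifiable: beta_hat - alpha_hat = "
            f"{beta_hat - alpha_hat:.3g} <= min_gap ({min_gap:.3g})"
        )
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    eta_hat = np.asarray(eta_hat, dtype=float)
    gap = beta_hat - alpha_hat
    gamma_cr = ((1.0 - alpha_hat) * gamma_hat - (1.0 - beta_hat) * eta_hat) / gap
    eta_cr = (beta_hat * eta_hat - alpha_hat * gamma_hat) / gap
    pi_cr = prior_from_mixture(alpha_hat, beta_hat, c)

    clipped = []
    if clip:
        if np.any(gamma_cr < 0) or np.any(gamma_cr > 1):
            clipped.append("gamma")
            gamma_cr = np.clip(gamma_cr, 0.0, 1.0)
        if np.any(eta_cr < 0) or np.any(eta_cr > 1):
            clipped.append("eta")
            eta_cr = np.clip(eta_cr, 0.0, 1.0)
    if gamma_cr.ndim == 0:
        gamma_cr, eta_cr = float(gamma_cr), float(eta_cr)
    return CorrectedRates(gamma=gamma_cr, eta=eta_cr, pi=pi_cr, clipped=tuple(clipped))


def pu_metrics(
    gamma_pu: float, eta_pu: float, c: float, theta: float
) -> MetricSet:
    """The four non-traditional metrics a naive practitioner would report.

    These are the standard formulas evaluated with the pseudo rates and the
    labeled fraction ``c`` in place of the prior:

        acc_pu  = c*gamma_pu + (1-c)*(1-eta_pu)
        bacc_pu = (1 + gamma_pu - eta_pu)/2
        F_pu    = 2*c*gamma_pu/(c + theta)
        mcc_pu  = sqrt(c*(1-c)/(theta*(1-theta))) * (gamma_pu - eta_pu)
    """
    return MetricSet(
        acc=acc_from_rates(gamma_pu, eta_pu, c),
        bacc=bacc_from_rates(gamma_pu, eta_pu),
        f=f_from_rates(gamma_pu, c, theta),
        mcc=mcc_from_rates(gamma_pu, eta_pu, c, theta),
        flavor="pu",
    )


def corrected_metrics(
    gamma_cr: float,
    eta_cr: float,
    pi_cr: float,
    theta_hat: float,
    flavor: str = "corrected_real",
) -> MetricSet:
    """Bias-corrected metrics from corrected rates.

    ``theta_hat`` is the uncorrected positive-prediction probability, which
    is already unbiased under positive-unlabeled evaluation and is therefore
    used as-is in the F and MCC formulas.  Each corrected metric is clipped
    into its admissible range (acc, F to [0, 1]; bacc to [1/2, 1]; mcc to
    [-1, 1]); clipping events are recorded in ``MetricSet.clipped``.
    """
    raw = {
        "acc": acc_from_rates(gamma_cr, eta_cr, pi_cr),
        "bacc": bacc_from_rates(gamma_cr, eta_cr),
        "f": f_from_rates(gamma_cr, pi_cr, theta_hat),
        "mcc": mcc_from_rates(gamma_cr, eta_cr, pi_cr, theta_hat),
    }
    clipped = []
    for name, (lo, hi) in CLIP_RANGES.items():
        v = raw[name]
        if not math.isnan(v) and not lo <= v <= hi:
            raw[name] = min(max(v, lo), hi)
            clipped.append(name)
    return MetricSet(**raw, flavor=flavor, clipped=tuple(clipped))


def bacc_from_pu(bacc_pu: ArrayLike, alpha: float, beta: float) -> ArrayLike:
    """Direct conversion of pseudo-label balanced accuracy to the traditional
    scale: ``bacc = (2*bacc_pu - 1)/(2*(beta - alpha)) + 1/2``.

    Strictly increasing in ``bacc_pu``, so maximizing the pseudo bacc over
    thresholds also maximizes the traditional bacc; and ``bacc >= bacc_pu``
    whenever the classifier beats random (``bacc_pu >= 1/2``).
    """
    if beta <= alpha:
        raise ValueError(
            f"correction not identifiable: beta ({beta}) must exceed alpha ({alpha})"
        )
    bacc_pu = np.asarray(bacc_pu, dtype=float)
    out = (2.0 * bacc_pu - 1.0) / (2.0 * (beta - alpha)) + 0.5
    return float(out) if out.ndim == 0 else out


def mcc_from_pu(mcc_pu: ArrayLike, ctx: PUContext) -> ArrayLike:
    """Direct conversion of pseudo-label MCC to the traditional scale:
    ``mcc = mcc_pu * sqrt(pi*(1-pi)/(c*(1-c))) / (beta - alpha)``.

    The scale factor is >= 1, so the traditional MCC always dominates the
    pseudo MCC in magnitude with the same sign.
    """
    pi = ctx.pi
    if not 0.0 < pi < 1.0:
        raise ValueError(f"implied prior must be interior, got pi={pi}")
    scale = math.sqrt(pi * (1.0 - pi) / (ctx.c * (1.0 - ctx.c))) / (ctx.beta - ctx.alpha)
    out = np.asarray(mcc_pu, dtype=float) * scale
    return float(out) if out.ndim == 0 else out
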
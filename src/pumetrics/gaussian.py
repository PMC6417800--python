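"""Analytic two-Gaussian case study of positive-unlabeled evaluation bias.

The positive and negative class-conditional densities are univariate
normals with a shared standard deviation, ``h1 = N(mu1, sigma)`` and
``h0 = N(mu0, sigma)`` with ``mu1 > mu0``, classified by thresholding the
raw score at ``tau``.  Every rate then has a closed form in the normal
survival function, so the eight metric curves (acc, bacc, F, mcc, each
traditional and pseudo-label) are computed exactly — no data set is drawn
and no quadrature is needed.

The default model (``case_study_model()``) uses ``mu0 = -1``, ``mu1 = 1``,
``sigma = 1``, ``beta = 3/4``, ``c = 1/10`` and prior ``pi = 3/10``, which
fixes ``alpha = 1/4`` through the mixture identity
``pi = c*beta + (1-c)*alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .correction import PUContext
from .metrics import acc_from_rates, bacc_from_rates, f_from_rates, mcc_from_rates

__all__ = [
    "GaussianPUModel",
    "ThresholdSweep",
    "case_study_model",
    "analytic_rates",
    "metric_value",
    "sweep",
    "maximize",
]

METRICS = ("acc", "bacc", "f", "mcc")
MODES = ("traditional", "pu")


@dataclass(frozen=True)
class GaussianPUModel:
    """Equal-variance two-Gaussian population with PU contamination."""

    mu0: float = -1.0
    mu1: float = 1.0
    sigma: float = 1.0
    ctx: PUContext = field(default_factory=lambda: PUContext(alpha=0.25, beta=0.75, c=0.1))

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.mu1 <= self.mu0:
            raise ValueError(
                f"positive mean mu1 ({self.mu1}) must exceed negative mean mu0 ({self.mu0})"
            )


def case_study_model(
    beta: float = 0.75,
    c: float = 0.1,
    alpha: Optional[float] = None,
    pi: Optional[float] = None,
    mu0: float = -1.0,
    mu1: float = 1.0,
    sigma: float = 1.0,
) -> GaussianPUModel:
    """Build the default case-study model, deriving ``alpha`` from ``pi``
    (or vice versa) through ``pi = c*beta + (1-c)*alpha``.

    Exactly one of ``alpha`` and ``pi`` may be given; with neither, the
    default prior ``pi = 0.3`` is used (hence ``alpha = 0.25``).
    """
    if alpha is not None and pi is not None:
        raise ValueError("give alpha or pi, not both (they are linked by the mixture identity)")
    if alpha is None:
        pi = 0.3 if pi is None else pi
        alpha = (pi - c * beta) / (1.0 - c)
    return GaussianPUModel(mu0=mu0, mu1=mu1, sigma=sigma, ctx=PUContext(alpha=alpha, beta=beta, c=c))


def analytic_rates(model: GaussianPUModel, tau) -> Tuple:
    """Exact rates at threshold(s) ``tau``.

    Returns ``(gamma, eta, gamma_pu, eta_pu, theta)`` where the traditional
    rates are survival functions of the component normals,

        gamma = 1 - cdf_{h1}(tau),   eta = 1 - cdf_{h0}(tau),

    the pseudo rates are survival functions of the labeled/unlabeled
    mixtures ``g = beta*h1 + (1-beta)*h0`` and ``f = alpha*h1 + (1-alpha)*h0``
    (by linearity, the same convex combinations of gamma and eta), and
    ``theta = pi*gamma + (1-pi)*eta``.
    """
    ctx = model.ctx
    gamma = norm.sf(tau, loc=model.mu1, scale=model.sigma)
    eta = norm.sf(tau, loc=model.mu0, scale=model.sigma)
    gamma_pu = ctx.beta * gamma + (1.0 - ctx.beta) * eta
    eta_pu = ctx.alpha * gamma + (1.0 - ctx.alpha) * eta
    theta = ctx.pi * gamma + (1.0 - ctx.pi) * eta
    return gamma, eta, gamma_pu, eta_pu, theta


def metric_value(model: GaussianPUModel, tau: float, metric: str, mode: str) -> float:
    """One metric curve evaluated at one threshold (used for refinement)."""
    gamma, eta, gamma_pu, eta_pu, theta = analytic_rates(model, tau)
    if mode == "traditional":
        g, e, p = gamma, eta, model.ctx.pi
    elif mode == "pu":
        g, e, p = gamma_pu, eta_pu, model.ctx.c
    else:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if metric == "acc":
        return acc_from_rates(g, e, p)
    if metric == "bacc":
        return bacc_from_rates(g, e)
    if metric == "f":
        return f_from_rates(g, p, theta)
    if metric == "mcc":
        return mcc_from_rates(g, e, p, theta)
    raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")


@dataclass(frozen=True)
class ThresholdSweep:
    """Eight exact metric curves over an ordered threshold grid.

    ``curves`` maps ``(metric, mode)`` with metric in {'acc','bacc','f','mcc'}
    and mode in {'traditional','pu'} to an array aligned with ``taus``.
    """

    taus: np.ndarray
    curves: Dict[Tuple[str, str], np.ndarray]
    model: GaussianPUModel

    def __post_init__(self) -> None:
        for key, curve in self.curves.items():
            if len(curve) != len(self.taus):
                raise ValueError(f"curve {key} length {len(curve)} != grid length {len(self.taus)}")


def sweep(
    model: GaussianPUModel,
    tau_lo: float = -5.0,
    tau_hi: float = 5.0,
    n_grid: int = 10001,
) -> ThresholdSweep:
    """Evaluate all eight curves on an equally spaced closed grid.

    The grid deliberately includes its endpoints: for heavily unlabeled
    populations the pseudo accuracy is strictly increasing in ``tau`` and
    attains its maximum at the upper boundary.
    """
    if not tau_lo < tau_hi:
        raise ValueError(f"need tau_lo < tau_hi, got [{tau_lo}, {tau_hi}]")
    if n_grid < 2:
        raise ValueError(f"n_grid must be >= 2, got {n_grid}")
    taus = np.linspace(tau_lo, tau_hi, n_grid)
    gamma, eta, gamma_pu, eta_pu, theta = analytic_rates(model, taus)
    pi, c = model.ctx.pi, model.ctx.c
    with np.errstate(divide="ignore", invalid="ignore"):
        curves = {
            ("acc", "traditional"): acc_from_rates(gamma, eta, pi),
            ("acc", "pu"): acc_from_rates(gamma_pu, eta_pu, c),
            ("bacc", "traditional"): bacc_from_rates(gamma, eta),
            ("bacc", "pu"): bacc_from_rates(gamma_pu, eta_pu),
            ("f", "traditional"): f_from_rates(gamma, pi, theta),
            ("f", "pu"): f_from_rates(gamma_pu, c, theta),
            ("mcc", "traditional"): mcc_from_rates(gamma, eta, pi, theta),
            ("mcc", "pu"): mcc_from_rates(gamma_pu, eta_pu, c, theta),
        }
    return ThresholdSweep(taus=taus, curves=curves, model=model)


def maximize(
    sw: ThresholdSweep, metric: str, mode: str, refine: bool = True
) -> Tuple[float, float]:
    """Maximum of one curve and its maximizing threshold.

    Grid argmax with ties broken toward the smallest threshold; when
    ``refine`` the maximizer is polished by bounded scalar minimization
    within the grid cells bracketing the argmax, which matters for smooth
    interior optima that fall between grid points.
    """
    curve = sw.curves[(metric, mode)]
    finite = np.where(np.isnan(curve), -np.inf, curve)
    i = int(np.argmax(finite))
    tau_star, value = float(sw.taus[i]), float(curve[i])
    if refine:
        lo = float(sw.taus[max(i - 1, 0)])
        hi = float(sw.taus[min(i + 1, len(sw.taus) - 1)])
        res = minimize_scalar(
            lambda t: -metric_value(sw.model, t, metric, mode),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if np.isfinite(res.fun) and -res.fun >= value:
            tau_star, value = float(res.x), float(-res.fun)
    return tau_star, value
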
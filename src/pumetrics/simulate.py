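"""Synthetic positive-unlabeled data sets and the four-scenario evaluation harness.

The construction protocol mirrors how PU benchmarks are built from fully
labeled data: starting from finite pools of positive and negative examples,
a labeled set of size ``n_l`` receives ``round(beta*n_l)`` positives and the
complementary negatives; the contamination ``alpha`` of the unlabeled set is
then *determined* by the remainder of the pools (the proportion of positives
among the examples not selected for labeling), and the unlabeled set of size
``n_u`` receives ``round(alpha*n_u)`` positives.  The labeled:unlabeled
ratio defaults to 1:10.

Each data set is evaluated in four scenarios over a threshold grid:

1. ``pu`` — standard metrics against pseudo-labels (labeled=1, unlabeled=0),
   what a practitioner unaware of the contamination would report;
2. ``true`` — standard metrics against the true labels (available here
   because the PU setting is simulated);
3. ``corrected_real`` — pseudo-label rates corrected with the realized
   ``(alpha, beta)``;
4. ``corrected_estimated`` — the same correction with externally estimated
   ``(alpha_hat, beta_hat)``.

For every scenario and metric the harness records the maximum over the grid,
its argmax threshold, and the benchmarking error: the scenario's maximized
metric minus the true performance at that same threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .correction import CLIP_RANGES, correct_rates, prior_from_mixture
from .metrics import acc_from_rates, bacc_from_rates, f_from_rates, mcc_from_rates

__all__ = [
    "PUDataset",
    "ScenarioReport",
    "ExperimentConfig",
    "sample_gaussian_population",
    "make_pu_datasets",
    "evaluate_scenarios",
    "perturb_context",
    "corrected_metric_se",
    "run_experiment",
]

METRICS = ("acc", "bacc", "f", "mcc")
SCENARIOS = ("pu", "true", "corrected_real", "corrected_estimated")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class PUDataset:
    """A labeled/unlabeled split with known ground truth.

    Pseudo-labels are implied: every labeled example is pseudo-positive,
    every unlabeled example pseudo-negative.  True labels are retained so
    the simulated evaluation can be scored traditionally.
    """

    labeled_scores: np.ndarray
    labeled_labels: np.ndarray
    unlabeled_scores: np.ndarray
    unlabeled_labels: np.ndarray

    @property
    def n_l(self) -> int:
        return len(self.labeled_scores)

    @property
    def n_u(self) -> int:
        return len(self.unlabeled_scores)

    @property
    def c(self) -> float:
        """Labeled fraction |L|/(|L|+|U|)."""
        return self.n_l / (self.n_l + self.n_u)

    @property
    def realized_beta(self) -> float:
        """Achieved proportion of true positives in the labeled set."""
        return float(np.mean(self.labeled_labels))

    @property
    def realized_alpha(self) -> float:
        """Achieved proportion of true positives in the unlabeled set."""
        return float(np.mean(self.unlabeled_labels))

    @property
    def scores(self) -> np.ndarray:
        """All scores, labeled block first."""
        return np.concatenate([self.labeled_scores, self.unlabeled_scores])

    @property
    def pseudo_labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(self.n_l, dtype=int), np.zeros(self.n_u, dtype=int)]
        )

    @property
    def true_labels(self) -> np.ndarray:
        return np.concatenate([self.labeled_labels, self.unlabeled_labels]).astype(int)


def sample_gaussian_population(
    n: int,
    pi: float,
    mu0: float = -1.0,
    mu1: float = 1.0,
    sigma: float = 1.0,
    seed=None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` scored examples from a two-Gaussian population.

    Labels are Bernoulli(``pi``); scores come from ``N(mu1, sigma)`` for
    positives and ``N(mu0, sigma)`` for negatives.  Deterministic under a
    fixed ``seed`` (anything acceptable to :func:`numpy.random.default_rng`).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must be in (0, 1), got {pi}")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < pi).astype(int)
    means = np.where(labels == 1, mu1, mu0)
    scores = rng.normal(means, sigma)
    return scores, labels


def make_pu_datasets(
    pos_pool: Sequence[float],
    neg_pool: Sequence[float],
    n_l: int,
    n_u: int,
    beta: float,
    seed=None,
) -> PUDataset:
    """Assemble a labeled/unlabeled split from positive and negative pools.

    ``round(beta*n_l)`` positives (and the complement negatives) are drawn
    without replacement into the labeled set; the unlabeled contamination
    ``alpha`` is the proportion of positives among the *remaining* pool
    examples, and the unlabeled set draws ``round(alpha*n_u)`` positives.
    Rounding is half-up on the positive counts.  The realized alpha/beta are
    exposed on the returned data set and may differ from the requested
    values by integer rounding.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    if n_l < 1 or n_u < 1:
        raise ValueError(f"need n_l, n_u >= 1, got n_l={n_l}, n_u={n_u}")
    pos_pool = np.asarray(pos_pool, dtype=float)
    neg_pool = np.asarray(neg_pool, dtype=float)
    rng = np.random.default_rng(seed)

    n_l_pos = _round_half_up(beta * n_l)
    n_l_neg = n_l - n_l_pos
    if n_l_pos > len(pos_pool):
        raise ValueError(
            f"positive pool too small: labeled set needs {n_l_pos}, pool has {len(pos_pool)}"
        )
    if n_l_neg > len(neg_pool):
        raise ValueError(
            f"negative pool too small: labeled set needs {n_l_neg}, pool has {len(neg_pool)}"
        )

    pos_perm = rng.permutation(len(pos_pool))
    neg_perm = rng.permutation(len(neg_pool))
    labeled_pos = pos_pool[pos_perm[:n_l_pos]]
    labeled_neg = neg_pool[neg_perm[:n_l_neg]]
    rem_pos = pos_pool[pos_perm[n_l_pos:]]
    rem_neg = neg_pool[neg_perm[n_l_neg:]]

    # alpha is fixed by the remainder: the unlabeled set inherits the
    # positive proportion of what the labeling step left behind.
    alpha = len(rem_pos) / (len(rem_pos) + len(rem_neg))
    n_u_pos = _round_half_up(alpha * n_u)
    n_u_neg = n_u - n_u_pos
    if n_u_pos > len(rem_pos):
        raise ValueError(
            f"positive pool too small: unlabeled set needs {n_u_pos}, {len(rem_pos)} remain"
        )
    if n_u_neg > len(rem_neg):
        raise ValueError(
            f"negative pool too small: unlabeled set needs {n_u_neg}, {len(rem_neg)} remain"
        )

    labeled_scores = np.concatenate([labeled_pos, labeled_neg])
    labeled_labels = np.concatenate(
        [np.ones(n_l_pos, dtype=int), np.zeros(n_l_neg, dtype=int)]
    )
    unlabeled_scores = np.concatenate([rem_pos[:n_u_pos], rem_neg[:n_u_neg]])
    unlabeled_labels = np.concatenate(
        [np.ones(n_u_pos, dtype=int), np.zeros(n_u_neg, dtype=int)]
    )
    return PUDataset(
        labeled_scores=labeled_scores,
        labeled_labels=labeled_labels,
        unlabeled_scores=unlabeled_scores,
        unlabeled_labels=unlabeled_labels,
    )


def _counts_over_grid(
    scores: np.ndarray, labels: np.ndarray, taus: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, int, int]:
    """Vectorized confusion counts over a threshold grid.

    Returns ``(tp, fp, n_pos, n_neg)`` arrays/ints with tp[i] the number of
    positives scoring >= taus[i] (prediction convention: score >= tau is
    positive).
    """
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    tp = len(pos) - np.searchsorted(pos, taus, side="left")
    fp = len(neg) - np.searchsorted(neg, taus, side="left")
    return tp, fp, len(pos), len(neg)


@dataclass(frozen=True)
class ScenarioReport:
    """Maximized metrics, argmax thresholds and benchmarking errors for one
    data set under the four evaluation scenarios.

    ``maxima[scenario][metric] = (tau_star, value)``;
    ``errors[scenario][metric]`` is the scenario's maximized value minus the
    true metric at the scenario's own argmax threshold (absent for the
    ``true`` scenario, where it is zero by construction).
    """

    maxima: Dict[str, Dict[str, Tuple[float, float]]]
    errors: Dict[str, Dict[str, float]]
    context: Dict[str, float]
    seed: Optional[int] = None


def _clip_curves(curves: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    return {
        m: np.clip(curve, *CLIP_RANGES[m]) for m, curve in curves.items()
    }


def _metric_curves(
    gamma: np.ndarray, eta: np.ndarray, pi: float, theta: np.ndarray
) -> Dict[str, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        return {
            "acc": acc_from_rates(gamma, eta, pi),
            "bacc": bacc_from_rates(gamma, eta),
            "f": f_from_rates(gamma, np.full_like(theta, pi), theta),
            "mcc": mcc_from_rates(gamma, eta, np.full_like(theta, pi), theta),
        }


def evaluate_scenarios(
    ds: PUDataset,
    scores: Optional[np.ndarray] = None,
    alpha: Optional[float] = None,
    beta: Optional[float] = None,
    alpha_hat: Optional[float] = None,
    beta_hat: Optional[float] = None,
    tau_grid: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> ScenarioReport:
    """Sweep a threshold grid and report all four evaluation scenarios.

    ``scores`` defaults to the data set's raw scores (for the synthetic
    Gaussian pools this is the Bayes-sufficient statistic); a fitted
    classifier's scores can be passed instead.  ``alpha``/``beta`` default
    to the realized contamination of ``ds``; scenario 4 is included only
    when ``alpha_hat``/``beta_hat`` are supplied.  Corrected rate and metric
    curves are clipped into their admissible ranges, as are the pseudo-label
    curves' corrected counterparts.
    """
    scores = ds.scores if scores is None else np.asarray(scores, dtype=float)
    if len(scores) != ds.n_l + ds.n_u:
        raise ValueError(
            f"need one score per example: got {len(scores)} for {ds.n_l + ds.n_u}"
        )
    if tau_grid is None:
        tau_grid = np.linspace(scores.min(), scores.max(), 201)
    taus = np.asarray(tau_grid, dtype=float)
    alpha = ds.realized_alpha if alpha is None else alpha
    beta = ds.realized_beta if beta is None else beta
    c = ds.c
    n = ds.n_l + ds.n_u

    # pseudo-label counts: labeled set are the pseudo positives
    tp_pu, fp_pu, npos_pu, nneg_pu = _counts_over_grid(scores, ds.pseudo_labels, taus)
    gamma_pu = tp_pu / npos_pu
    eta_pu = fp_pu / nneg_pu
    theta = (tp_pu + fp_pu) / n  # unbiased under PU: marginal of x is unchanged

    # true-label counts
    tp_t, fp_t, npos_t, nneg_t = _counts_over_grid(scores, ds.true_labels, taus)
    gamma_t = tp_t / npos_t
    eta_t = fp_t / nneg_t
    pi_hat = npos_t / n

    curves: Dict[str, Dict[str, np.ndarray]] = {
        "pu": _metric_curves(gamma_pu, eta_pu, c, theta),
        "true": _metric_curves(gamma_t, eta_t, pi_hat, theta),
    }

    corrections = {"corrected_real": (alpha, beta)}
    if alpha_hat is not None and beta_hat is not None:
        corrections["corrected_estimated"] = (alpha_hat, beta_hat)
    for scenario, (a, b) in corrections.items():
        cr = correct_rates(gamma_pu, eta_pu, c, a, b)
        curves[scenario] = _clip_curves(
            _metric_curves(np.asarray(cr.gamma), np.asarray(cr.eta), cr.pi, theta)
        )

    maxima: Dict[str, Dict[str, Tuple[float, float]]] = {}
    errors: Dict[str, Dict[str, float]] = {}
    for scenario, metric_curves in curves.items():
        maxima[scenario] = {}
        errors[scenario] = {}
        for m, curve in metric_curves.items():
            finite = np.where(np.isnan(curve), -np.inf, curve)
            i = int(np.argmax(finite))
            maxima[scenario][m] = (float(taus[i]), float(curve[i]))
            if scenario != "true":
                # benchmarking error: pick the threshold by this scenario's
                # criterion, then compare with true performance there
                errors[scenario][m] = float(curve[i] - curves["true"][m][i])

    context = {
        "alpha": alpha,
        "beta": beta,
        "c": c,
        "pi": prior_from_mixture(alpha, beta, c),
        "realized_alpha": ds.realized_alpha,
        "realized_beta": ds.realized_beta,
    }
    if "corrected_estimated" in corrections:
        context["alpha_hat"], context["beta_hat"] = corrections["corrected_estimated"]
    return ScenarioReport(maxima=maxima, errors=errors, context=context, seed=seed)


def perturb_context(
    alpha: float,
    beta: float,
    rel_error: float,
    rng: np.random.Generator,
    min_gap: float = 0.01,
) -> Tuple[float, float]:
    """Stand-in for an external mixture-proportion estimator: multiplicative
    relative perturbation of the true ``(alpha, beta)``.

    Each parameter is scaled by ``1 + U(-rel_error, rel_error)`` and clipped
    into its admissible range; if the perturbed gap falls below ``min_gap``,
    ``beta_hat`` is raised to restore it (capped at 1).
    """
    alpha_hat = float(np.clip(alpha * (1.0 + rng.uniform(-rel_error, rel_error)), 0.0, 0.999))
    beta_hat = float(np.clip(beta * (1.0 + rng.uniform(-rel_error, rel_error)), 1e-3, 1.0))
    if beta_hat - alpha_hat < min_gap:
        beta_hat = min(alpha_hat + min_gap, 1.0)
        alpha_hat = beta_hat - min_gap
    return alpha_hat, beta_hat


def corrected_metric_se(
    metric: str,
    gamma_pu: float,
    eta_pu: float,
    theta: float,
    c: float,
    alpha: float,
    beta: float,
    n_l: int,
    n_u: int,
) -> float:
    """Delta-method standard error of a corrected metric.

    The pseudo rates are binomial proportions — ``gamma_pu`` on the labeled
    set (``n_l`` trials), ``eta_pu`` on the unlabeled set (``n_u``), and
    ``theta`` on all ``n_l + n_u`` — whose variances are propagated
    numerically through the correction and metric formulas.  Useful for
    judging whether a corrected estimate is within sampling error of the
    true value; note the correction inflates variance by roughly
    ``1/(beta - alpha)``.
    """

    def evaluate(g_pu: float, e_pu: float, th: float) -> float:
        cr = correct_rates(g_pu, e_pu, c, alpha, beta)
        g = float(np.clip(cr.gamma, 0.0, 1.0))
        e = float(np.clip(cr.eta, 0.0, 1.0))
        if metric == "acc":
            return acc_from_rates(g, e, cr.pi)
        if metric == "bacc":
            return bacc_from_rates(g, e)
        if metric == "f":
            return f_from_rates(g, cr.pi, th)
        if metric == "mcc":
            return mcc_from_rates(g, e, cr.pi, th)
        raise ValueError(f"unknown metric {metric!r}")

    n = n_l + n_u
    variances = (
        gamma_pu * (1.0 - gamma_pu) / n_l,
        eta_pu * (1.0 - eta_pu) / n_u,
        theta * (1.0 - theta) / n,
    )
    point = np.array([gamma_pu, eta_pu, theta])
    h = 1e-5
    var = 0.0
    for k, v in enumerate(variances):
        up, dn = point.copy(), point.copy()
        up[k] = min(up[k] + h, 1.0)
        dn[k] = max(dn[k] - h, 0.0)
        grad = (evaluate(*up) - evaluate(*dn)) / (up[k] - dn[k])
        var += grad * grad * v
    return float(np.sqrt(var))


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of a multi-repetition noise-sweep experiment.

    Pools are drawn fresh per repetition from the two-Gaussian population
    with prior ``pi``; ``pool_factor`` scales the pool to
    ``pool_factor * (n_l + n_u)`` examples so the remainder after labeling
    always covers the unlabeled draw.  ``rel_error`` drives the
    scenario-4 perturbation of ``(alpha, beta)``.
    """

    n_l: int = 1000
    n_u: int = 10000
    betas: Tuple[float, ...] = (1.0, 0.9, 0.8, 0.7)
    repetitions: int = 50
    pi: float = 0.3
    mu0: float = -1.0
    mu1: float = 1.0
    sigma: float = 1.0
    pool_factor: float = 3.0
    n_grid: int = 201
    rel_error: float = 0.1
    seed: int = 0
    scorer: Optional[Callable[[np.ndarray], np.ndarray]] = None


def run_experiment(config: ExperimentConfig) -> List[dict]:
    """Run the full repetitions x beta grid and return tidy per-run records.

    Each record carries ``beta``, ``repetition``, ``scenario``, ``metric``,
    the maximized value, its threshold, and the benchmarking error against
    the true curve.  All randomness descends from ``config.seed`` through a
    spawned seed sequence, so identical configs give identical output.
    """
    records: List[dict] = []
    root = np.random.SeedSequence(config.seed)
    n_pool = int(config.pool_factor * (config.n_l + config.n_u))
    for beta in config.betas:
        for rep, child in enumerate(root.spawn(config.repetitions)):
            rng = np.random.default_rng(child)
            scores, labels = sample_gaussian_population(
                n_pool, config.pi, config.mu0, config.mu1, config.sigma, seed=rng
            )
            ds = make_pu_datasets(
                scores[labels == 1], scores[labels == 0],
                config.n_l, config.n_u, beta, seed=rng,
            )
            ds_scores = ds.scores if config.scorer is None else config.scorer(ds.scores)
            alpha_hat, beta_hat = perturb_context(
                ds.realized_alpha, ds.realized_beta, config.rel_error, rng
            )
            report = evaluate_scenarios(
                ds, scores=ds_scores,
                alpha_hat=alpha_hat, beta_hat=beta_hat,
                tau_grid=np.linspace(ds_scores.min(), ds_scores.max(), config.n_grid),
            )
            for scenario, metric_maxima in report.maxima.items():
                for m, (tau_star, value) in metric_maxima.items():
                    records.append(
                        {
                            "beta": beta,
                            "repetition": rep,
                            "scenario": scenario,
                            "metric": m,
                            "tau_star": tau_star,
                            "value": value,
                            "error": report.errors.get(scenario, {}).get(m, 0.0),
                            "realized_alpha": report.context["realized_alpha"],
                            "realized_beta": report.context["realized_beta"],
                        }
                    )
    return records


def summarize_errors(records: List[dict]) -> List[dict]:
    """Aggregate per-run records into median |error| per (metric, scenario,
    beta) — the summary a noise-sweep box plot would show."""
    from collections import defaultdict

    groups: Dict[Tuple[float, str, str], List[float]] = defaultdict(list)
    for r in records:
        if r["scenario"] == "true":
            continue
        groups[(r["beta"], r["scenario"], r["metric"])].append(abs(r["error"]))
    return [
        {
            "beta": beta,
            "scenario": scenario,
            "metric": metric,
            "median_abs_error": float(np.median(errs)),
            "n_runs": len(errs),
        }
        for (beta, scenario, metric), errs in sorted(groups.items())
    ]
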
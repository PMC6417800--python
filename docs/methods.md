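# Methods

## Setting and notation

Binary classification with a thresholded score: the prediction is positive
iff score ≥ τ (half-closed convention, fixed throughout; boundary scores
predict positive). Population *h = π h₁ + (1−π) h₀* with class prior π.
Fundamental rates: true positive rate γ, false positive rate η, precision
ρ = πγ/θ, and θ = πγ + (1−π)η, the probability of a positive prediction.
The four composite measures:

- acc = πγ + (1−π)(1−η)
- bacc = (1 + γ − η)/2
- F = 2πγ/(π + θ)
- mcc = √(π(1−π)/(θ(1−θ))) · (γ − η)

Count estimators are the standard plug-ins from the confusion matrix
(γ̂ = tp/(tp+fn), etc.). The count form of mcc uses the four-factor
denominator √((tp+fp)(tp+fn)(tn+fp)(tn+fn)), the unique count expression
algebraically equal to the rate form; the test suite asserts the two paths
agree to 1e−12 on random matrices.

## PU evaluation and its correction

Pseudo-labels declare the labeled set positive and the unlabeled set
negative. Under the standard selected-completely-at-random assumption the
class-conditional densities are unchanged in both sets and only the mixing
proportions differ: labeled purity β, unlabeled contamination α, labeled
fraction c, with π = cβ + (1−c)α. The plug-in estimators then estimate
γ_pu = βγ + (1−β)η and η_pu = αγ + (1−α)η instead of γ and η, the
pseudo-prior estimate is c, and only θ̂ remains unbiased (the marginal of
the scores is the population marginal).

`correct_rates` inverts the 2×2 mixing (valid iff β > α); `corrected_metrics`
plugs the corrected rates and π_cr into the standard formulas, keeping θ̂
uncorrected (it needs no correction). `bacc_from_pu` and `mcc_from_pu`
implement the direct monotone conversions; the suite verifies on 10,000
random parameter draws that both paths agree to 1e−10, that the round trip
through the forward mixing is exact to 1e−10, and that the
underestimation inequalities (bacc ≥ bacc_pu when bacc_pu ≥ ½;
sign(mcc)·(mcc − mcc_pu) ≥ 0) never fail.

## Numerical and degenerate-input conventions

- **Undefined values** (γ̂ of a set with no positives, mcc with θ̂ ∈ {0,1})
  are NaN, never silent zeros, and propagate. One exception: F of a
  classifier predicting nothing positive while positives exist is reported
  as 0 with a `RuntimeWarning` — the conventional value that keeps
  threshold sweeps total.
- **Clipping**: corrected estimates can leave their admissible ranges under
  sampling noise or misestimated (α, β). Corrected rates are clipped to
  [0,1]; corrected acc and F to [0,1], bacc to [½,1], mcc to [−1,1]. Every
  clip is surfaced (`CorrectedRates.clipped`, `MetricSet.clipped`).
- **Identifiability floor**: corrections with β̂ − α̂ ≤ 1e−6 are rejected
  (`min_gap`, configurable) rather than allowed to amplify noise without
  bound.
- **Tie-break**: grid argmaxes break ties toward the smallest threshold.
  Refinement is bounded scalar minimization (xatol 1e−10) within the two
  grid cells bracketing the argmax, and is only accepted when it does not
  decrease the value, so boundary maxima are preserved.

## Analytic case study

For equal-variance Gaussians h₀ = N(μ₀, σ), h₁ = N(μ₁, σ), every rate is a
normal survival function and the mixture cdfs are the matching convex
combinations, so all eight metric curves are exact. Defaults: μ₀ = −1,
μ₁ = 1, σ = 1, β = 3/4, c = 1/10, π = 3/10, which forces α = 1/4 through
π = cβ + (1−c)α (`case_study_model` accepts either α or π and derives the
other; supplying both is an error). The sweep grid is 10,001 equally spaced
points on the closed interval [−5, 5]; the boundary is included on purpose
because the pseudo accuracy is strictly increasing in τ for these
parameters (c·g(τ) < (1−c)·f(τ) everywhere since the density ratio f/g is
bounded below by 1/3 > c/(1−c)) and tops out at 1 − c at the right edge.
An independent oracle for the accuracy maximizer — the threshold where
π h₁(τ) = (1−π) h₀(τ), i.e. τ* = ½ ln((1−π)/π) for means ±1 — checks the
refined sweep to 1e−6. Reported values are rounded to 2 decimals; full
precision is kept internally.

## Synthetic data and the four-scenario harness

The generator emulates how PU benchmarks are built from fully labeled
sources. Pools of positives and negatives are drawn from the two-Gaussian
population (labels Bernoulli(π), scores from the matching component);
`make_pu_datasets` then fills the labeled set with round(β·n_l) positives
and the complement negatives, takes α as the positive *proportion of the
remainder*, and fills the unlabeled set with round(α·n_u) positives.
Rounding is half-up on positive counts; realized α and β are recorded and
tests never assume the requested values exactly. Defaults: n_l = 1,000,
n_u = 10,000 (the 1:10 labeled:unlabeled ratio typical of practice),
π = 0.3, pool size 3·(n_l+n_u) — large enough that the remainder always
covers the unlabeled draw, small enough to keep a 50-repetition experiment
in seconds. With these defaults α ≈ 0.28 (it is set by the remainder, not
chosen directly), so even β = 1 leaves a contaminated unlabeled set.

The scorer is pluggable; the default is the raw Gaussian score, which is
monotone in the likelihood ratio and hence Bayes-sufficient for this
population. The correction formulas are classifier-agnostic, so nothing in
the harness depends on this choice; a fitted model's scores can be passed
instead. Training pipelines (e.g. bagged neural networks) are deliberately
out of scope.

Each data set is evaluated over a threshold grid (default 201 points
spanning the observed scores) in four scenarios: naive pseudo-label
metrics; true-label metrics (available because the PU setting is
simulated); corrected with the realized (α, β); and corrected with
perturbed (α̂, β̂) standing in for an external estimator — multiplicative
relative error, default ±10% uniform, with the β̂ − α̂ gap floored at 0.01.
For every scenario the harness records each metric's maximum, its argmax,
and the benchmarking error: pick the threshold by the scenario's own
criterion, then compare its value against the true metric at that same
threshold.

`corrected_metric_se` supplies a delta-method standard error for a
corrected metric: the pseudo rates are binomial proportions (γ̂_pu on n_l
trials, η̂_pu on n_u, θ̂ on n_l+n_u) whose variances are propagated
numerically through the correction and metric formulas. This makes "within
sampling error" testable; note the correction inflates standard errors by
roughly 1/(β−α).

## What the synthetic tests do and do not show

Passing tests demonstrate the algebraic exactness of the correction, its
statistical consistency when (α, β) are known, and the qualitative bias
structure (bacc/F/mcc understated, acc overstated, errors growing with
noise) under a well-specified generative model with a monotone scorer. They
do not probe real-data failure modes: violations of the
selection-independent-of-features assumption, class-conditional densities
that differ between labeled and unlabeled sets, multimodal or heavy-tailed
score distributions, or the error structure of any particular
mixture-proportion estimator (the ±10% perturbation is a stand-in, not a
model of one).

## Problem sizes

Default test-suite scales: 10,000 random draws for the round-trip and
conversion identities; 20 repetitions at n_l = 1,000 / n_u = 10,000 for
the sampled-consistency check; 20 repetitions across β ∈ {1, 0.9, 0.8,
0.7} for the noise-monotonicity check; 10,001-point grids for the analytic
sweep. These sizes keep the whole suite under a minute while leaving the
binomial standard errors small relative to the biases being detected.
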
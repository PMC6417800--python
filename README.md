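# pumetrics

Classifier performance metrics under **positive-unlabeled (PU) evaluation**,
with exact bias correction.

In many biomedical problems — protein function, variant pathogenicity,
clinical outcomes — an experiment can establish that an example is positive,
but the absence of evidence is not evidence of absence. Evaluation data then
consist of a *labeled* set **L** (labeled positive, possibly with noise) and
an *unlabeled* set **U** that silently mixes positives and negatives. The
standard practice of treating **L** as the positives and **U** as the
negatives ("pseudo-labels") makes the usual performance metrics — accuracy,
balanced accuracy, F-measure, and the Matthews correlation coefficient
(MCC) — systematically wrong: bacc, F and MCC are understated, accuracy is
overstated, sometimes wildly.

`pumetrics` quantifies and removes that bias. It is a library first (with a
thin `pumetrics` CLI) aimed at anyone benchmarking binary classifiers on
PU-style data.

## The model

Positives and negatives have densities *h₁*, *h₀*; the population is
*h = π h₁ + (1−π) h₀*. The labeled and unlabeled sets are themselves
mixtures,

- *g = β h₁ + (1−β) h₀* — labeled set, purity *β* ∈ (π, 1]
  (1−β is the labeling noise),
- *f = α h₁ + (1−α) h₀* — unlabeled set, contamination *α* ∈ [0, π),

and with labeled fraction *c* = |L|/(|L|+|U|) the prior satisfies
**π = cβ + (1−c)α**.

Against pseudo-labels, the estimated true/false positive rates converge not
to (γ, η) but to

```
γ_pu = βγ + (1−β)η        η_pu = αγ + (1−α)η
```

while θ, the probability of a positive prediction, stays unbiased. Since
β > α this linear mixing is invertible:

```
γ_cr = ((1−α)γ̂ − (1−β)η̂)/(β−α)     η_cr = (βη̂ − αγ̂)/(β−α)     π_cr = cβ + (1−c)α
```

and plugging (γ_cr, η_cr, π_cr, θ̂) into the standard formulas recovers
unbiased acc, bacc, F and MCC. Two metrics also convert *directly* and
*monotonically*:

```
bacc = (2·bacc_pu − 1) / (2(β−α)) + 1/2
mcc  = mcc_pu · sqrt(π(1−π)/(c(1−c))) / (β−α)
```

so a decision threshold tuned by maximizing bacc or MCC on PU data is
already optimal for the traditional metric — only the reported value needs
correcting (and it is always at least the PU value, given better-than-random
performance). Accuracy and F enjoy no such guarantee.

Estimating (α, β) themselves is out of scope: any external
mixture-proportion estimator can be plugged in via the
`AlphaBetaEstimator` contract.

## Worked example

`examples/case_study.py` sweeps the decision threshold for an exactly
solvable population — negatives N(−1,1), positives N(1,1), β = 3/4,
c = 1/10, π = 3/10 — and prints:

```
metric         mode     tau*    max
   acc  traditional     0.42   0.86
   acc           pu     5.00   0.90
  bacc  traditional     0.00   0.84
  bacc           pu    -0.00   0.67
     f  traditional     0.19   0.77
     f           pu     0.50   0.30
   mcc  traditional     0.29   0.66
   mcc           pu     0.29   0.22
```

Read it row-pairwise: bacc and MCC peak at the *same* threshold in both
modes (0.00 and 0.29) but the PU values understate the truth (0.67 vs 0.84,
0.22 vs 0.66); accuracy and F peak at *different* thresholds, and the PU
accuracy is maximized by the trivial always-negative classifier at the
boundary (0.90 = 1 − c). `examples/correct_counts.py` shows the same
correction applied to raw pseudo-label counts, and
`examples/simulate_scenarios.py` runs the sampled benchmark comparing
naive, corrected-with-true-(α,β), and corrected-with-estimated-(α,β)
evaluation across noise levels.

The same workflows are available from the shell:

```bash
pumetrics correct --tp 620 --fn 380 --fp 2750 --tn 7250 --alpha 0.25 --beta 0.75
pumetrics case-study --beta 0.75 --c 0.1 --pi 0.3
pumetrics --seed 3 simulate --repetitions 10 --betas 1,0.9,0.8,0.7 --out runs.tsv
```

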
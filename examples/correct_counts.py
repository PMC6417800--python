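"""Correct metrics computed against pseudo-labels, from raw counts.

A classifier was thresholded and scored against pseudo-labels: the 1,000
labeled-as-positive examples count as positives, the 10,000 unlabeled ones
as negatives.  Suppose an external estimator puts the contamination at
alpha = 0.25 (positives hiding in the unlabeled set) and beta = 0.75
(purity of the labeled set).  The naive metrics and their corrected
counterparts then differ substantially.
"""

from pumetrics import (
    ConfusionMatrix,
    PUContext,
    correct_rates,
    corrected_metrics,
    estimate_rates,
    pu_metrics,
)

# pseudo-label confusion matrix: rows = pseudo class, columns = prediction
cm = ConfusionMatrix(tp=620, fn=380, fp=2750, tn=7250)
rates = estimate_rates(cm)  # these are pseudo rates: gamma_pu, eta_pu, c, theta
c = rates.pi  # pseudo "prior" is just the labeled fraction
ctx = PUContext(alpha=0.25, beta=0.75, c=c)

naive = pu_metrics(rates.gamma, rates.eta, c, rates.theta)
cr = correct_rates(rates.gamma, rates.eta, c, ctx.alpha, ctx.beta)
corrected = corrected_metrics(cr.gamma, cr.eta, cr.pi, rates.theta)

print(f"labeled fraction c = {c:.4f}, implied true prior pi = {ctx.pi:.4f}")
print(f"{'metric':>6} {'naive PU':>10} {'corrected':>10}")
for m in ("acc", "bacc", "f", "mcc"):
    print(f"{m:>6} {getattr(naive, m):>10.4f} {getattr(corrected, m):>10.4f}")
if cr.clipped or corrected.clipped:
    print("clipped:", cr.clipped, corrected.clipped)

# The naive row is what a practitioner unaware of the contamination would
# report; the corrected row estimates the classifier's true
# positive-vs-negative performance.  Balanced accuracy and MCC move up
# (pseudo-label evaluation understates them); accuracy moves down.
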
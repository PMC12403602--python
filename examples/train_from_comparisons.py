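"""Training a classifier from pairwise comparisons alone.

Generates 2-D Gaussian features at 4-sigma class separation with an
imbalanced class prior (pi+ = 0.3), builds 2,000 gold-labeler (GoDaG)
comparison pairs, and trains each risk estimator on the noisy pointwise
split.  At this prior the noisy-positive set is mostly true negatives
(rho+ = 0.62), so the uncorrected baseline's boundary shifts visibly.
Held-out accuracy is measured on fresh data with clean labels.
"""

import numpy as np

from minsupre import (
    FeatureGenConfig,
    LossConfig,
    PriorConfig,
    TrainConfig,
    fit,
    gen_feature_corpus,
    generate_pairwise,
    split_pointwise,
)

PI = 0.3
fc = gen_feature_corpus(FeatureGenConfig(n=8000, pi_plus=PI, seed=0))
print(f"Bayes accuracy of the feature model: {fc.bayes_accuracy:.4f}")

ids = [str(i) for i in range(len(fc.y))]
pt = split_pointwise(generate_pairwise(ids, fc.y, 2000, 1))
Xp = fc.X[[int(i) for i in pt.d_plus]]
Xn = fc.X[[int(i) for i in pt.d_minus]]
hold = gen_feature_corpus(FeatureGenConfig(n=4000, pi_plus=PI, seed=99))

print()
print("method            held-out accuracy")
for method in ("binary_biased", "noisy_unbiased", "rank_pruning",
               "pcomp_unbiased", "pcomp_relu", "pcomp_abs", "pcomp_teacher"):
    model = fit(Xp, Xn, LossConfig(method, PriorConfig(PI)), TrainConfig(seed=0))
    acc = float((model.predict(hold.X) == hold.y).mean())
    print(f"{method:<17} {acc:.4f}")

print()
print("Binary-Biased treats the noisy sets as clean and inherits their")
print("contamination; the Pcomp estimators recover near-Bayes accuracy from")
print("comparisons that never expose a single pointwise label.  Noisy-Unbiased")
print("uses Natarajan's loss correction with the mixture contamination rates,")
print("which is calibrated for balanced priors — at pi+ = 0.3 the noisy-positive")
print("set is 62% true negatives and the correction over-shoots, so it")
print("degenerates to the majority-positive predictor here.")
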
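"""Agreement statistics between two scorers of the same nights.

Cohen's kappa corrects raw agreement for chance; Deming regression
fits a line allowing error in both scorers' measures; Bland-Altman
reports the bias with 95% limits of agreement and an exact paired
sign-flip permutation p-value.
"""

import numpy as np

import sqsleep as sq

# kappa on a hand-computable 2x2 agreement table [[45, 5], [15, 35]]
truth = ["wake"] * 50 + ["sleep"] * 50
rater = ["wake"] * 45 + ["sleep"] * 5 + ["wake"] * 15 + ["sleep"] * 35
print(f"kappa = {sq.cohens_kappa(truth, rater):.2f}  "
      "(observed agreement 0.80, chance 0.50)")

# per-night total-sleep-time estimates, 11 nights
rng = np.random.default_rng(0)
tst_true = rng.uniform(300, 480, 11).round(1)
tst_est = tst_true - rng.normal(8.0, 6.0, 11)  # estimator biased low

fit = sq.deming_fit(tst_true, tst_est)
print(f"Deming slope = {fit.slope:.3f}, intercept = {fit.intercept:.1f}, "
      f"Pearson r = {fit.pearson_r:.3f}")

ba = sq.bland_altman(tst_true, tst_est)
print(f"bias = {ba.mean_diff:+.1f} min (positive = underestimation), "
      f"limits [{ba.limits[0]:.1f}, {ba.limits[1]:.1f}], p = {ba.p_value:.4f}")
# With 11 pairs the permutation test enumerates all 2^11 = 2048 sign
# assignments, so p is an exact multiple of 1/2048.
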
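"""Ordinal severity modeling and diagnostic accuracy of spin density.

Simulates a proportional-odds relationship between proton spin density and
four-level DPN severity (planted odds ratio 2.9 per 100 proton spins), fits
the ordered logistic model, and runs ROC analysis of density for separating
symptomatic DPN from controls using the published group moments.
"""

import numpy as np
from scipy.special import expit

from nervequant import ordinal_regression, roc_analysis

rng = np.random.default_rng(3)

# --- proportional-odds recovery
n = 5000
rho = rng.uniform(200, 500, n)
eta = np.log(2.9) / 100.0 * rho
cuts = np.quantile(eta, [0.25, 0.5, 0.75])
u = rng.random(n)
severity = np.select([u < expit(cuts[0] - eta), u < expit(cuts[1] - eta),
                      u < expit(cuts[2] - eta)], [0, 1, 2], default=3)
fit = ordinal_regression(rho, severity)
lo, hi = fit.or_ci_per_100
print(f"planted OR per 100 spins: 2.90  recovered: {fit.or_per_100:.2f} "
      f"(95% CI {lo:.2f}-{hi:.2f}, p={fit.p:.2g})")

# --- ROC of density for symptomatic DPN vs controls
m = 10_000
controls = rng.normal(288, 67.0, m)
mild = rng.random(m) < 25 / 35
symptomatic = np.where(mild, rng.normal(365, 76.0, m), rng.normal(360, 72.4, m))
roc = roc_analysis(np.r_[symptomatic, controls],
                   np.r_[np.ones(m, int), np.zeros(m, int)],
                   thresholds=(294.0, 336.0, 357.0), n_boot=200, seed=0)
print(f"\nAUC = {roc.auc:.2f} (bootstrap 95% CI "
      f"{roc.auc_ci[0]:.2f}-{roc.auc_ci[1]:.2f})")
print(roc.operating_points.round(1).to_string(index=False))
# Sensitivity/specificity at the >=294 cutoff reproduce the operating point
# of density as an early-DPN biomarker; higher cutoffs trade sensitivity
# for specificity along the same curve.
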
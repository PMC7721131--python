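"""Generate a calibrated synthetic cohort and verify its population targets.

Builds the study-scale preset (n = 7,026; 20 polygenic scores; an SES-like and
a chaos-like composite plus 11 binary life events; rge = 0.38) and compares
the analytic population R-squared of the G / E / G+E models against the
configured targets and an in-sample OLS estimate.
"""

import numpy as np

import geinterplay as gi

cfg = gi.calibrated_preset(seed=1)
cohort = gi.simulate_score_cohort(cfg)
truth = cohort.truth

print(f"cohort: {cohort.predictors.shape[0]} individuals, "
      f"{cohort.predictors.shape[1]} predictors")
print(f"outcome paths: G={truth.a:.4f}  E={truth.b:.4f}  env-specific={truth.c:.4f}")
print(f"latent cor(G, E) = {truth.rho:.2f}; "
      f"population cor(G_ea, E_ea) = {truth.population_rge():.4f}\n")

X = cohort.predictors.to_numpy()
Xc = (X - X.mean(0)) / X.std(0)
y = cohort.outcome.to_numpy()
yc = y - y.mean()
slices = {"G": slice(0, 20), "E": slice(20, 33), "G+E": slice(0, 33)}
print(f"{'model':>6} {'target R2':>10} {'analytic':>10} {'in-sample':>10}")
for model, sl in slices.items():
    Z = Xc[:, sl]
    beta, *_ = np.linalg.lstsq(Z, yc, rcond=None)
    emp = 1 - ((yc - Z @ beta) ** 2).sum() / (yc ** 2).sum()
    print(f"{model:>6} {cfg.target_r2[model]:>10.4f} "
          f"{truth.population_r2(model):>10.4f} {emp:>10.4f}")
print("\nThe analytic column is computed from the truth record's covariance "
      "algebra\nand matches the targets exactly; the in-sample column is the "
      "finite-sample OLS check.")
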
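"""Longitudinal trajectory of a network metric with penalized-spline smoothing.

The metric is modeled as a smooth function of months post-injury plus a
per-subject random intercept, fitted by REML; the basis dimension k is
chosen by BIC.  The effective degrees of freedom (edf) report how nonlinear
the fitted trend is: edf near 1 means a straight line.
"""

import numpy as np

from scnkit import fit_trajectory

timepoints = [0.0, 1.0, 2.0, 3.0, 6.0, 12.0]
months = np.tile(timepoints, 8)
subject = np.repeat([f"S{i}" for i in range(8)], len(timepoints))
rng = np.random.default_rng(3)

# a metric that declines early and partially recovers (nonlinear in time)
truth = 0.55 - 0.08 * np.exp(-((np.array(months) - 3.0) ** 2) / 8.0)
metric = truth + np.repeat(rng.normal(0, 0.01, 8), len(timepoints)) \
    + rng.normal(0, 0.01, months.size)

fit = fit_trajectory(metric, months, subject)
print(f"k selected by BIC: {fit.k_selected}  (BIC by k: "
      + ", ".join(f"{k}:{b:.1f}" for k, b in fit.bic_by_k.items()) + ")")
print(f"edf = {fit.edf:.2f} (>1: the trend is nonlinear)")
print(f"p_smooth = {fit.p_smooth:.4g} (tests 'flat trajectory')")
print("\nfitted population curve at the observed timepoints:")
curve = fit.fitted_curve
for m in timepoints:
    row = curve.iloc[(curve.month - m).abs().argmin()]
    print(f"  month {m:4.0f}: {row.fit:.3f}  (truth {0.55 - 0.08 * np.exp(-((m - 3.0) ** 2) / 8.0):.3f})")
print("\nThe curve dips around 3 months and recovers - the transient "
      "disruption planted in the data, picked up without specifying a shape.")
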
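"""Moderation analysis: does treatment change the brain-behavior coupling?

A linear mixed model
    outcome ~ metric + group + metric:group + C(timepoint) + (1 | subject)
tests whether the slope of a locomotor outcome on a network metric differs
between the injury-only and treatment groups.  Simple slopes decompose a
significant interaction into per-group slopes.
"""

import numpy as np

from scnkit import fit_moderation_model, simple_slopes

# simulated 40-subject cohort with a planted interaction of +9.087:
# the injury-only slope is -6.137, so the treatment slope is 2.950
rng = np.random.default_rng(42)
timepoints = [0.0, 1.0, 2.0, 3.0, 6.0, 12.0]
n_subj = 40
subject = np.repeat([f"S{i:02d}" for i in range(n_subj)], len(timepoints))
group = np.where(np.repeat(np.arange(n_subj) < 20, len(timepoints)),
                 "sci_only", "treatment")
timepoint = np.tile(timepoints, n_subj)
metric = rng.normal(0.5, 0.5, subject.size)          # e.g. global efficiency
g = (group == "treatment").astype(float)
outcome = (30.0 - 6.137 * metric + 2.0 * g + 9.087 * metric * g
           + 0.5 * timepoint
           + np.repeat(rng.normal(0, 0.5, n_subj), len(timepoints))
           + rng.normal(0, 0.5, subject.size))

fit = fit_moderation_model(outcome, metric, group, timepoint, subject)
print(fit.coefficients[["beta", "se", "df", "p"]].round(3))
print(f"\ndf method: {fit.df_method}")
slopes, diff = simple_slopes(fit)
print("\nSimple slopes (outcome per unit of metric, within each group):")
print(slopes[["slope", "se", "p", "ci_low", "ci_high"]].round(3))
print(f"\nslope difference = interaction beta = {diff['estimate']:.3f} "
      f"(p = {diff['p']:.4f})")
print(f"R2 marginal = {fit.r2_marginal:.3f}, conditional = {fit.r2_conditional:.3f}, "
      f"Cohen's f2 of the interaction = {fit.f2_interaction:.3f}")
print("\nThe negative injury-only slope flips to positive under treatment - "
      "the planted moderation the model is built to detect.")
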
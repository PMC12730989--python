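# Methods notes

This note records the modeling assumptions, numerical conventions and design
choices behind `scnkit`, in the spirit of a statistical appendix: what each
component computes, why the defaults are what they are, and what passing the
test suite does and does not establish.

## Synthetic cohorts

The generator emulates a longitudinal two-group injury/treatment study:
`n_per_group = 4` subjects per arm (eight total), assessed at a healthy
baseline and 1, 2, 3, 6 and 12 months, with 110 usable samples per
functional time series (a 120-volume acquisition minus ten discarded
initial volumes). The regional covariance of gray-matter volume (GMV) is
modular: `n_modules = 4` communities with within-module correlation 0.6 and
between-module correlation 0.1, a regime in which binarized networks show
clear small-world organization. The default region count is 60; real
parcellations are an order of magnitude larger (the atlas the design
emulates has 470 regions), but global binary metrics depend on topology
regime rather than raw node count, and 60 regions keeps a full
46-threshold × 100-null sweep interactive. The block correlation matrix is
checked for positive semi-definiteness (minimum eigenvalue ≥ −1e−10);
infeasible within/between combinations are rejected rather than repaired.

Injury and treatment act as per-group mean GMV shifts over time (volume
units; defaults approximate 0.6–1 SD atrophy with partial recovery under
treatment). Covariances are untouched by default; a config flag
(`perturb_covariance`, `covariance_shrink`) uniformly shrinks post-injury
correlations instead. Half of each subject's GMV covariance
(`subject_frac = 0.5`) is a stable per-subject deviation, so individual
departures from the healthy mean persist across timepoints as they do in
real morphometry.

Time series are i.i.d. Gaussian vectors mixed by the symmetric square root
of the reference correlation. There is no temporal autocorrelation,
hemodynamics or motion structure: the analysis consumes only zero-lag
correlations, for which this construction is sufficient by design. Passing
tests therefore demonstrate correct recovery of zero-lag covariance
structure, not robustness to autocorrelated or artifact-laden series.

Locomotor outcomes (path length, step height, stride length; arbitrary
units, since gait units are study-specific) follow a linear mixed model
with fixed effects metric, group, metric×group, linear time, and a
per-subject random intercept. The planted coefficients default to the
moderation pattern the statistics layer is designed to detect (reference
slope −6.137, interaction +9.087 on path length; −4.553 on stride length).
Spinal-cord FA is generated as an affine function of the network metric
with slope 1/`fa_effect` (`fa_effect = 0.549`), so that regressing the
metric on FA recovers the planted positive main effect as FA noise → 0; FA
is clipped to [0, 1]. The other DTI scalars (MD, RD, AD) are filler
covariates with plausible post-injury increases.

All randomness flows from one seed through named `SeedSequence` substreams
(one code per operation, fixed forever), so outputs are bit-reproducible
and adding a new operation cannot perturb existing draws.

## Network construction

GMV residualization regresses each region on intercept + total intracranial
volume across healthy-baseline subjects only; the fitted adjustment is
reapplied unchanged at later timepoints so that longitudinal deviation from
the healthy state is preserved rather than re-centered per visit. TIV is
the only covariate adjusted for. The group covariance SCN_HC is the signed
Pearson correlation of these residuals (no thresholding of the group
matrix); reference SDs use ddof = 1.

The individual-SCN chain is ESD → R = tanh(ESD) → W = 1 − R →
M = W ∘ SCN_HC. The effect-size denominator is the pooled SD,
sqrt((SD_i² + SD_j²)/2). R is computed as tanh but W in the equivalent form
2e^(−2·ESD)/(1 + e^(−2·ESD)) so that saturated entries underflow to a
strictly positive subnormal rather than to zero, keeping W in (0, 1]. A
known subtlety: growing one region's deviation is only guaranteed to weaken
that region's weights when the other regions sit at their healthy means;
if another region already deviates in the same direction, moving toward its
deviation shrinks the pairwise effect size and legitimately strengthens
that edge. The monotonicity test is stated in the well-defined form.

Functional networks keep positive correlations only and Fisher-z transform
them, with r capped at 1 − 1e−7 so duplicate series produce a large finite
edge instead of infinity. Since atanh is strictly monotone on (0, 1),
proportional thresholding yields identical binary graphs from r and from z
(tested); the transform matters only for downstream parametric statistics
on edge weights.

## Graph metrics

Edge count at sparsity s is K = round(s·N(N−1)/2), half away from zero.
Edge ranking uses the signed weight, most-positive first; ties are broken
by ascending (row, column) index, which makes edge sets nested along the
grid (hence E_g non-decreasing in s) and all results reproducible. Negative
weights (possible in individual SCNs) are excluded from ranking by default,
mirroring the positive-only rule of the functional networks; an
absolute-value ranking mode is available. If fewer eligible edges exist
than K, the graph is built sparser than requested with a warning.

Conventions that change the numbers, stated explicitly: disconnected pairs
contribute 1/∞ = 0 to global efficiency, and L_p averages over connected
ordered pairs only (flagged in metric-set notes); nodes of degree < 2
contribute 0 to both mean clustering and local efficiency. All-pairs
distances are computed by repeated boolean matrix products, exact for
unweighted graphs and validated to 1e−12 against a brute-force
Floyd–Warshall oracle and networkx.

Small-world normalization uses Maslov–Sneppen double-edge swaps: 10·|E|
swap attempts per null (numba-accelerated, seeded, degree sequence
preserved exactly, no self-loops or multi-edges), 100 nulls per graph by
default; γ = C_p/⟨C_p,null⟩, λ = L_p/⟨L_p,null⟩, σ = γ/λ. The null count
and swap budget follow common connectome-toolbox practice. Graphs whose
largest component covers < 90% of nodes trigger a warning (normalization is
unstable there); a graph too constrained to swap (e.g. a star) returns a
copy with a warning rather than an error. AUC is trapezoidal integration of
a metric curve against sparsity; per-threshold failures inside a sweep are
recorded in the result, never silently dropped.

## Statistics

**Decision tree.** Normality screening is Shapiro–Wilk and variance
screening Levene, both at α = 0.05 (a conventional choice; the screening
level is not data-driven). Unpaired: any non-normality → Mann–Whitney U;
otherwise unequal variances → Welch t, else Student t. Paired: Shapiro–Wilk
on differences → paired t or Wilcoxon signed-rank. Constant paired
differences are an error rather than a degenerate p-value. Every result
carries its decision trace.

**Moderation models.** `outcome ~ metric + group + metric:group +
C(timepoint) + (1 | subject)`, REML, with the injury-only group as
reference — so the `metric` coefficient is the reference-group slope and
the interaction is the slope difference, and the simple-slope identity
slope(treatment) − slope(reference) = interaction holds by construction.
Timepoint enters categorically to avoid assuming linear time effects.
Estimation uses statsmodels' MixedLM; on top of it the package computes
Satterthwaite-type degrees of freedom: df = 2·f²/Var(f) for
f = cᵀCov(β̂)c, with Cov(β̂) and its derivatives obtained from closed-form
per-cluster (Woodbury) expressions and the variance-parameter covariance
from the numeric Hessian of the REML criterion in (τ, σ²). When the
Hessian is unusable (variance on the zero boundary) the residual df N − p
is used and df are clamped to [1, N − p]. Exact Kenward–Roger adjustment is
deliberately out of scope; the df method is recorded in every result. In
simulation at 40 subjects × 6 timepoints the interaction test holds its
level (5.0% empirical at nominal 5%) and its 95% CI covers a planted effect
94.2% of the time.

Marginal R² is var(Xβ̂) over var(Xβ̂) + τ + σ² and conditional R² adds τ to
the numerator; Cohen's f² compares the full model's marginal R² with an
interaction-free refit on the same data, floored at 0 (sampling noise can
put the reduced fit above the full one). The FA-on-metric models can be fit
with or without the interaction (`include_interaction`), since a combined
main effect is most interpretable when the interaction is absent.

No multiple-testing correction is applied across metrics, thresholds or
outcomes; results are reported at raw p < 0.05. This mirrors the analysis
style the package supports and is a caveat for any real application.

**Trajectories.** The metric is a penalized truncated-power cubic spline in
months (fixed part [1, t]; k − 2 knot terms at equally spaced interior
positions, entering as i.i.d. random coefficients) plus a subject random
intercept, fitted by profiling the REML criterion over the two variance
ratios (grid search then Nelder–Mead; deterministic). k is selected by
minimum BIC (ML log-likelihood at the plug-in estimates, with curve edf
plus two variance components as the parameter count) over candidates
between 3 and the number of distinct times. Reported edf excludes the
intercept, so a linear fit has edf = 1. The flatness test is a Wald
statistic on the smooth coefficients with the covariance rank truncated to
round(edf); because the coefficients are shrunk, the test is conservative
(flat data: ~93% non-rejection at the 5% level in simulation). Slope
standard errors are conditional on the estimated smoothing parameters and
therefore slightly anti-conservative — a known property of plug-in spline
inference. With truly linear data the REML boundary estimate τ_smooth = 0
occurs in most but not all replicates (median edf 1.0; occasional draws
show edf up to ~1.8 when the six time-means deviate from collinearity by
chance), which is expected sampling behavior of boundary REML, not a
defect; tests assert the median.

## Pipeline

Stages (simulate → build-networks → metrics → stats) communicate through
files in the output directory, so each can be re-run alone and a corrupted
intermediate is caught at the next stage boundary with the stage name and
offending file. The orchestrated defaults use a coarser grid (step 0.05)
and 10 nulls to stay interactive; the canonical analysis settings
(step 0.01, 100 nulls) are a parameter away. Metric tables at a fixed
sparsity of 0.1 feed the moderation models, matching the convention of
fitting both at a representative single threshold and on AUCs. Matrices are
written as labeled TSV with JSON sidecars and round-trip exactly
(`float_precision="round_trip"` on read). Manifests record seed, config
hash and SHA-256 checksums of every output; identical (config, seed) runs
reproduce identical checksums.

## Problem sizes used in validation

The shipped validation uses 60-region cohorts for the full small-world
sweep (8 subjects × 46 thresholds × 100 nulls), 500 simulated 40-subject
cohorts for moderation calibration, 200 replicates for trajectory flatness
calibration, and 200 random ≤12-node graphs for brute-force metric
equivalence. These sizes were chosen as the smallest that make the
respective statistical claims sharp; all scale linearly if enlarged.

## Known limitations

- No voxel-level preprocessing, atlas handling, or imaging formats; inputs
  are tabular by design.
- Weighted-graph and nodal/regional metrics are out of scope (global binary
  metrics only), as are modularity and hub analyses.
- The synthetic generator does not model temporal autocorrelation, scanner
  drift, motion, or covariance changes under injury (beyond the optional
  uniform shrink), so tests validate the analysis chain, not its behavior
  on artifact-laden data.
- Kenward–Roger df are approximated by the Satterthwaite construction;
  exact parity with lme4/pbkrtest is not a goal.
- Trajectory slope SEs are conditional on the smoothing parameters.
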
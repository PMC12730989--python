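"""Build the two network kinds: functional and individual structural covariance.

Functional networks are positive Pearson correlations of ROI time series,
Fisher-z transformed.  Individual SCNs weight the group-level healthy
covariance by each subject's deviation from the healthy mean:
ESD -> R = tanh(ESD) -> W = 1 - R -> M = W * SCN_HC.
"""

import numpy as np

from scnkit import (
    CohortConfig,
    build_functional_network,
    build_group_covariance,
    build_individual_scn,
    compute_esd,
    generate_baseline_reference,
    residualize_morphometry,
    simulate_morphometry,
    simulate_timeseries,
    weight_from_esd,
)

config = CohortConfig(n_roi=24, n_modules=3, seed=7)
reference_true = generate_baseline_reference(config)
morpho = simulate_morphometry(config, reference_true)
series = simulate_timeseries(config, reference_true)

# group-level healthy covariance from TIV-adjusted baseline residuals
baseline = [r for r in morpho if r.timepoint == 0.0]
residuals, adjust = residualize_morphometry(baseline)
group_net, reference = build_group_covariance(residuals, baseline)
print(f"group SCN: {group_net.n_roi}x{group_net.n_roi}, "
      f"mean within-module r = {reference.scn_hc[:8, :8][np.triu_indices(8, 1)].mean():.2f}")

# a subject at 12 months: large deviations -> weights shrink toward 0
record = next(r for r in morpho if r.subject_id == "M01" and r.timepoint == 12.0)
w = weight_from_esd(compute_esd(record, reference))
iscn = build_individual_scn(w, reference, subject_id="M01", timepoint=12.0)
print(f"subject M01 at 12 months: median weight W = {np.median(w.w):.3f} "
      f"(1 means 'at the healthy mean')")
print(f"individual SCN edges are bounded by the group SCN: "
      f"max |M| = {np.abs(iscn.values).max():.3f} <= "
      f"max |SCN_HC| = {np.abs(group_net.values).max():.3f}")

# functional network from the same subject's baseline scan
fnet = build_functional_network(series[0])
off = fnet.values[np.triu_indices(fnet.n_roi, 1)]
print(f"functional network: {np.mean(off > 0):.0%} positive edges, "
      f"max Fisher z = {off.max():.2f} (negative correlations are masked)")
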
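"""Sweep proportional thresholds and summarize metric curves by their AUC.

At each sparsity s the top s fraction of edges forms a binary graph; the
seven global metrics (Eg, Eloc, Lp, Cp, gamma, lambda, sigma) trace curves
over s that are summarized by trapezoidal AUC.  gamma/lambda/sigma compare
the graph against degree-preserving Maslov-Sneppen nulls: sigma > 1 is the
small-world signature.
"""

import warnings

import numpy as np

from scnkit import (
    CohortConfig,
    build_functional_network,
    generate_baseline_reference,
    simulate_timeseries,
    sweep_thresholds,
)
from scnkit.types import ThresholdGrid

config = CohortConfig(n_roi=30, n_modules=3, seed=7)
reference = generate_baseline_reference(config)
record = simulate_timeseries(config, reference)[0]  # one healthy baseline scan
network = build_functional_network(record)

grid = ThresholdGrid(0.05, 0.50, 0.05)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # sparse thresholds fragment small graphs
    sweep = sweep_thresholds(network, grid, n_null=50, seed=3)

print("sparsity  Eg     Cp     gamma  sigma")
for i, s in enumerate(grid.values):
    print(f"  {s:.2f}   {sweep['Eg'].values[i]:.3f}  {sweep['Cp'].values[i]:.3f}"
          f"  {sweep['gamma'].values[i]:5.2f}  {sweep['sigma'].values[i]:5.2f}")
print("\nAUC over the grid (threshold-free summaries):")
for name in ("Eg", "Cp", "sigma"):
    print(f"  AUC({name}) = {sweep[name].auc:.3f}")
print("\nsigma stays above 1 across thresholds: the modular synthetic brain "
      "is more clustered than random at comparable wiring cost.")
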
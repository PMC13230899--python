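"""Simulate a host-microbiome cohort and look at the purity-driven bias.

Builds a 400-sample cohort across the 0.2-1.0 host-purity gradient and
prints how far the raw caller-style counts drift from the controlled true
counts in each purity band — the systematic bias the correction model is
trained to remove.
"""

import numpy as np

from snvpurify import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_samples=400, seed=7))

print(f"{'purity band':>12} {'n':>5} {'mean(raw-true)':>15} {'mean|raw-true|':>15}")
edges = [0.2, 0.3, 0.5, 0.7, 0.8, 1.0]
for lo, hi in zip(edges[:-1], edges[1:]):
    sub = [t for t in cohort.truths if lo < t.true_purity <= hi]
    diff = np.array([t.raw_snv_count - t.true_snv_count for t in sub])
    print(f"{lo:>5.1f}-{hi:<6.1f} {len(sub):>5} {diff.mean():>15.1f} "
          f"{np.abs(diff).mean():>15.1f}")

print("\nAt low purity the caller over-reports (spurious low-VAF calls outpace"
      "\ndropped true variants); near purity 1.0 raw and true counts agree.")
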
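"""Generate a synthetic WES cohort with embedded CNVs and known truth.

The read-depth matrix mimics real exome coverage: per-target capture
efficiency, per-sample sequencing depth, rank-3 batch effects, and
Poisson counting noise, with 5 multi-target CNVs planted at copy ratios
0.5 (het deletion) and 1.5 (het duplication).
"""

import numpy as np

from exocnv import SimulationConfig, random_cnv_specs, simulate_cohort

rng = np.random.default_rng(np.random.SeedSequence([7, 1]))
specs = random_cnv_specs(5, n_samples=20, n_targets=200, rng=rng)
config = SimulationConfig(n_samples=20, n_targets=200, cnv_specs=specs, seed=7)
matrix, truth = simulate_cohort(config)

print(f"cohort: {matrix.n_samples} samples x {matrix.n_targets} targets")
print(f"mean depth: {matrix.depths.mean():.1f}x "
      f"(range {matrix.depths.min():.1f}-{matrix.depths.max():.1f})")
print("embedded CNVs (sample, interval, type, copy ratio):")
for spec, call in zip(truth.specs, truth.to_calls()):
    print(f"  {call.sample}  {call.interval.name:>18}  {call.type}  {spec.factor}")
# Each row is one planted event the discovery stage should recover; the
# copy ratio scales the expected depth over the listed targets.
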
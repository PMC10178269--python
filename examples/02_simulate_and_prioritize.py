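"""Generate three synthetic dominant-disease families, push each through
the filter cascade and segregation, and check that the spiked causal
variant is recovered. The funnel counts show how each stage thins the
background variation."""

import numpy as np

from famseg import SimulationConfig, simulate_family
from famseg.filters import FUNNEL_TABLE_COLUMNS
from famseg.pipeline import analyze_simulated_family

cfg = SimulationConfig(n_background_variants=1000, penetrance=0.9, seed=42)
rng = np.random.default_rng(cfg.seed)

for i in range(3):
    fd = simulate_family(cfg, rng, f"FAM{i + 1}")
    report, verdicts = analyze_simulated_family(fd)
    recovered = fd.truth.causal_variant_id in report.survivors["segregating"]
    print(f"--- {fd.pedigree.family_id} "
          f"({len(fd.pedigree.affected_ids)} affected members)")
    for stage in report.executed_stages:
        label = FUNNEL_TABLE_COLUMNS.get(stage, stage)
        print(f"  {label:<55s} {report.counts[stage]:>5d}")
    print(f"  causal variant recovered: {recovered}")

print()
print("Each row counts surviving variants after a filter stage; the final "
      "segregating set should contain the one spiked causal variant plus "
      "any background variant that happens to co-segregate by chance.")
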
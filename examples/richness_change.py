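"""Recover a known -20% richness change from unequal-effort occurrence records.

Simulates a 10x10 landscape where every cell loses 20% of its species
between two 20-year periods and the second period is sampled 3x harder,
then runs the full per-cell estimation + meta-analysis pipeline.

Run: python examples/richness_change.py   (~1 min)
"""

import math

from biotrend import SimConfig, generate_landscape, sample_records
from biotrend.pipeline import COUNTRY, PipelineConfig, run_richness_pipeline

sim = SimConfig(extinction_fraction=0.2, effort_imbalance=3.0, seed=42)
truth = generate_landscape(sim)
records, _ = sample_records(truth)
print(f"{len(records)} records sampled; true per-cell logratio ln(0.8) = {math.log(0.8):.4f}")

cfg = PipelineConfig(scale_factors=(1, 2), bootstrap_B=200, seed=7)
results = run_richness_pipeline(records, cfg)

for scale, res in results.items():
    tag = "country" if scale == COUNTRY else f"{scale:.0f} km"
    if res.analysis is None:
        lr = res.estimates["logratio"].iloc[0]
        print(f"{tag:>8}: single pooled cell, logratio {lr:+.4f}")
        continue
    m = res.analysis.meta
    print(
        f"{tag:>8}: {m.k} cells  Qw {m.qw:+.4f}  ({m.pct_change:+.1f}% change)  "
        f"95% CI [{m.ci_low:+.4f}, {m.ci_high:+.4f}]  tau2 {m.tau2:.4f}"
    )
    if res.analysis.moderator is not None:
        mod = res.analysis.moderator
        print(f"          effort moderator beta {mod.beta:+.4f} (p={mod.p_beta:.3f})")

# At the finest scale the weighted mean logratio should sit near ln(0.8) =
# -0.223 (-20%). Coarser scales show weaker change: losing 20% of species
# from each 10-km cell rarely removes a species from a whole 20-km block,
# which is exactly the scale-dependence the multi-scale analysis exposes.
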
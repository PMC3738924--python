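"""Detect biotic homogenisation via equal-effort similarity distance decay.

Simulates a landscape whose ten commonest species expand into every cell in
the second period (spatial homogenisation), computes equal-effort 1-betasim
for every cell pair in both periods, and fits the logit distance-decay
mixed model with effort covariates.

Run: python examples/similarity_decay.py   (~30 s)
"""

from biotrend import SimConfig, generate_landscape, sample_records
from biotrend.pipeline import PipelineConfig, run_similarity_pipeline

sim = SimConfig(grid_nx=5, grid_ny=5, n_species=150, expansion_k=10,
                effort_mean=400.0, seed=11)
truth = generate_landscape(sim)
records, _ = sample_records(truth)
for p in ("P1", "P2"):
    print(f"true mean pairwise 1-betasim in {p}: {truth.true_similarity(p)['sim'].mean():.3f}")

cfg = PipelineConfig(scale_factors=(1,), similarity_R=50, seed=3)
res = run_similarity_pipeline(records, cfg)

fit = res.fit
eff, se, p = fit.period_effect("P2")
print(f"\n{fit.n_pairs} cell pairs, {fit.n_groups} focal cells")
print(f"distance slope:        {fit.params['distance']:+.4f} logit/km")
print(f"period effect (P2-P1): {eff:+.4f} +/- {se:.4f}  (p = {p:.2e})")

curves = res.curves
for period in ("P1", "P2"):
    c = curves[curves["period"] == period]
    print(
        f"adjusted similarity {period}: {c['sim'].iloc[0]:.3f} at "
        f"{c['distance'].iloc[0]:.0f} km -> {c['sim'].iloc[-1]:.3f} at "
        f"{c['distance'].iloc[-1]:.0f} km"
    )

# A positive period effect means assemblages are more similar to each other
# in the later period at any given distance - biotic homogenisation. The
# effort covariates (n_min, rel_diff and their interaction) absorb the
# tendency of unequal sampling to fake nestedness, so the period contrast
# is not an artefact of recording intensity.
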
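# biotrend

Effort-corrected estimation of **species richness change** and **biotic
homogenisation** from unstandardised occurrence records.

Long-term occurrence databases (museum collections, recording schemes,
atlas projects) are the only window onto biodiversity change before formal
monitoring began, but they were never sampled to a protocol: recording
effort differs wildly between places and eras, and more effort means more
species recorded. `biotrend` implements an inference pipeline that
separates real change from recording artefacts, for anyone analysing
gridded occurrence data — historical ecologists, national recording
schemes, conservation analysts.

## The method

Records are aggregated into per-(grid cell, 20-year period) assemblages at
multiple spatial scales. For each cell and period pair:

1. **Comparison point.** With `n1` and `n2` records, both periods are
   standardised to a shared effort: the smaller sample's species
   accumulation curve is extrapolated (never beyond 3× its own effort,
   using the singleton/doubleton unseen-species estimate
   `f0 = ((n−1)/n)·f1²/(2f2)`), and where the larger sample exceeds
   threefold it is analytically rarefied down to the same point.
2. **Logratio.** Change is `ln(X2/X1)` on comparison-point richness, with
   delta-method variance `sd1²/X1² + sd2²/X2²` from a seeded multinomial
   bootstrap (observed endpoints are bootstrapped too, so noisy singleton
   counts do not get treated as exact).
3. **Meta-analysis.** Cells are combined by inverse-variance random-effects
   meta-analysis (`Qw`, τ² by REML) per scale; a meta-regression on the
   log effort ratio `ΔR = ln(n2/n1)` detects residual effort bias, and
   significant moderator effects are removed cell-wise via partial
   residuals before per-cell z-tests (with Benjamini–Hochberg q-values)
   and a GLS test for spatial autocorrelation (exponential / linear
   structures, LRT + AIC).
4. **Homogenisation.** Pairwise assemblage similarity uses the replacement
   component `1-βsim = a/(a+min(b,c))` at strictly equal effort
   (without-replacement subsampling of `min(n_i, n_j)` records from both
   cells), then a logit distance-decay mixed model (random intercept per
   focal cell) with period and effort covariates; a positive period effect
   is spatial homogenisation.

A synthetic-landscape generator with known truth (skewed abundances,
disc-shaped ranges on a torus, controllable extinction, expansion and
effort imbalance) backs every statistical claim in the test suite. See
`docs/methods.md` for the full model description and limitations.

## Worked example

`python examples/richness_change.py` simulates a 10×10 landscape of 10-km
cells where every cell loses 20% of its species (true logratio
ln 0.8 = −0.2231) and the later period is sampled 3× harder, then runs the
full pipeline:

```
892997 records sampled; true per-cell logratio ln(0.8) = -0.2231
   10 km: 100 cells  Qw -0.2153  (-19.4% change)  95% CI [-0.2334, -0.1971]  tau2 0.0065
          effort moderator beta +0.0164 (p=0.321)
   20 km: 25 cells  Qw -0.0627  (-6.1% change)  95% CI [-0.0771, -0.0483]  tau2 0.0007
 country: single pooled cell, logratio -0.0385
```

The finest scale recovers the −20% truth inside its CI despite the 3×
effort imbalance, and the moderator confirms no residual effort effect.
The weaker change at 20 km and country level is not an artefact: losing
20% of species from each 10-km cell rarely removes a species from a whole
20-km block, which is exactly the scale dependence a multi-scale analysis
is meant to expose.

`python examples/similarity_decay.py` does the same for homogenisation —
ten common species expand into every cell in period 2:

```
506 cell pairs, 22 focal cells
distance slope:        -0.0106 logit/km
period effect (P2-P1): +0.2273 +/- 0.0216  (p = 6.65e-26)
adjusted similarity P1: 0.719 at 10 km -> 0.609 at 57 km
adjusted similarity P2: 0.761 at 10 km -> 0.665 at 57 km
```

Similarity decays with distance in both periods, and the significant
positive period effect — similarity higher at every distance after effort
correction — is the homogenisation signal.

A thin CLI wraps the same functions:
`biotrend simulate --seed 4 --extinction 0.2 --out sim/`, then
`biotrend richness sim/records.csv --out results/`.

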
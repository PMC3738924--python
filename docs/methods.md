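# Methods

`biotrend` estimates temporal change in species richness and in assemblage
similarity from occurrence records that were never collected under a
standardised protocol — museum specimens, atlas schemes, haphazard field
notes. Such data confound real biodiversity change with changes in
recording effort; every component below exists to separate the two.

## Data model

The atomic unit is an occurrence record: an (aggregate) taxon name, planar
x/y coordinates in km, and a calendar year. Records are binned into square
grid cells (half-open, lower-left origin; a coordinate on a boundary belongs
to the upper cell) and into inclusive 20-year periods, by default
P0 1930–1949, P1 1950–1969, P2 1970–1989, P3 1990–2009. Coarser analysis
scales are integer multiples of the finest cell size and are produced by
summing constituent fine cells, so multi-scale results are consistent by
construction; the "country" scale pools every cell.

Raw taxon names are lumped into aggregate taxa through a user-supplied map
(chains are resolved to fixed points at load time; cycles are an error) so
that taxonomic-skill differences between eras cannot masquerade as richness
change. Plant taxa can be classed by pollinator dependency (dependent /
intermediate / independent): a species-level trait wins, otherwise the
consensus of classified congeners, then confamilials; mixed classes at the
resolving level yield "intermediate".

Cells enter an analysis only when *both* periods of a comparison meet the
selection thresholds. The thresholds are fully configurable; the defaults —
≥50 records per cell-period for richness, ≥200 for similarity — are
documented stand-ins chosen to keep singleton-driven bias manageable, not
values with an external source, and real analyses should set them per
dataset.

## Richness change

For one cell and a pre/post period pair with `n1` and `n2` records, both
periods are brought to a shared **comparison point** `cp`:

- if `max(n1,n2) ≤ 3·min(n1,n2)`: `cp = max(n1,n2)`; the smaller sample's
  accumulation curve is extrapolated up to it;
- otherwise `cp = 3·min(n1,n2)`: the smaller sample is extrapolated to
  threefold its effort (the reliability limit of accumulation-curve
  extrapolation) and the larger is rarefied down to the same point.

Interpolation is exact analytic rarefaction,
`E[S(m)] = S_obs − Σ_i C(n−n_i, m)/C(n, m)`, computed with log-gamma
binomials. Extrapolation is the singleton/doubleton-driven form
`S(n+m*) = S_obs + f0·[1 − (1 − f1/(n·f0+f1))^{m*}]` with the
bias-corrected unseen-species estimate
`f0 = ((n−1)/n)·f1²/(2f2)` (or `((n−1)/n)·f1(f1−1)/2` when `f2 = 0`).
An assemblage without singletons is treated as completely sampled
(`f0 = 0`, flat curve). The junction is continuous:
`extrapolate(·, 0) = rarefy(·, n) = S_obs`.

The change statistic is `Q = X2/X1` on the comparison-point richness
values and its natural log, the **logratio** (0 = no change; reported also
as percent change `(e^logratio − 1)·100`). Its sampling variance uses the
first-order delta method, `var = sd1²/X1² + sd2²/X2²`, with both SDs from a
multinomial bootstrap of the record counts (B = 200 by default, seeded).
The bootstrap is applied to *observed* endpoints too: singletons and
doubletons are themselves noisy, and setting the SD of an observed endpoint
to zero would overstate its reliability. The effort moderator is the signed
log effort ratio `delta_r = ln(n2/n1)`; an absolute-value variant can be
configured. Sensitivity modes re-run the estimate under forced
interpolation-only (both periods at `min(n1,n2)`) or extrapolation-only
(smaller extrapolated to `max`, valid only within threefold) plans.

## Meta-analysis

Per scale, cell logratios are combined under a random-effects model
`y_i ~ N(μ, v_i + τ²)` with inverse-variance weights. τ² is estimated by
REML (profile of the restricted likelihood over τ² ≥ 0, checked against the
τ²=0 boundary); the DerSimonian–Laird moment estimator is available by
configuration. `Qw` is the weighted mean. Its CI and test use the
Knapp–Hartung variance estimator (weighted residual mean square, truncated
below at the classical Wald variance) with t quantiles on k−1 df — per-cell
variances are themselves bootstrap estimates, and the classical z interval
undercovers when they are noisy; the classical `se = sqrt(1/Σw)` is still
reported alongside. A
fully sampled cell can bootstrap to zero variance; such variances are
floored at the smallest positive cell variance before weighting.

Residual effort bias is probed by weighted meta-regression of the logratio
on `delta_r`. When the slope is significant (α = 0.05, configurable),
per-cell **partial residuals** `y_i − β̂·(delta_r_i − mean(delta_r))`
replace the raw values; centring keeps the overall level untouched, so the
adjustment removes the effort *gradient* across cells rather than shifting
the mean. Per-cell two-sided z-tests (`z = adjusted/√v`) are reported with
both raw p and Benjamini–Hochberg q; the method itself prescribes no
multiplicity correction, so both are emitted and q is recommended for
map-style summaries.

Spatial structure in the adjusted values is assessed by intercept-only GLS
with (i) independent errors, (ii) exponential correlation `exp(−d/ρ)` and
(iii) linear correlation `max(0, 1 − d/ρ)` on centroid distances, with ρ
profiled by ML. Each spatial model is compared to the null by a 1-df
likelihood-ratio test (conservative for a boundary parameter) and by AIC
(k = 2 null, 3 spatial). The linear structure can be indefinite at some
ranges in 2-D; such ranges are excluded by the likelihood itself (a
non-PD matrix gets −∞).

## Assemblage similarity

Compositional similarity uses only the replacement component,
`1-βsim = a/(a + min(b,c))` on presence sets: nested assemblages score 1,
so richness differences do not leak into the turnover signal. Because a
deeply sampled cell's record pool over-represents common species, each
unordered cell pair is compared at equal effort: `min(n_i, n_j)` records
are drawn *without replacement* from both cells (multivariate
hypergeometric), reduced to presences, scored, and averaged over R = 100
seeded replicates. The per-pair random stream is keyed on (seed, period,
pair), so estimates are symmetric in the pair and independent of
enumeration order. Note the estimate is tied to the common effort level: it
converges to the presence-set value as both cells are sampled more deeply,
and no claim of invariance to overall effort is made.

Distance decay is fitted on the empirical logit
`ln(s'/(1−s'))`, `s' = (s(N−1)+0.5)/N` with N the replicate count — the
boundary adjustment is deliberately tied to Monte-Carlo resolution — by a
linear mixed model with a random intercept per focal cell and fixed effects
distance, period, distance×period, plus the effort covariates `n_min`
(records of the least-sampled cell), `rel_diff = ln(n_max/n_min)` and their
interaction. The covariates model, rather than assume away, the residual
tendency of effort imbalance to fake nestedness. Model comparison uses ML,
reported estimates REML (statsmodels MixedLM); a singular or non-converged
fit falls back to the fixed-effects OLS model, flagged. Reported decay
curves hold effort covariates at their sample means — the
"effort-corrected" view — with CIs from the fixed-effect covariance only.
Because the model carries a distance × period interaction, the reported
period contrast is evaluated at the mean pair distance (the centre of the
data; the main effect alone would be the contrast extrapolated to distance
zero, outside the observed range). A positive period contrast means higher
similarity at a given distance in the later period: biotic homogenisation.

## Synthetic landscapes

The generator emulates the statistical structure the estimators must
survive, not any particular biology:

- **Ranges**: per-species discs with lognormal radii (median 20 km,
  σ_log 0.6) centred uniformly on a torus, so there are no edge-driven
  richness gradients to confound spatial-autocorrelation nulls.
- **Abundances**: one lognormal relative abundance per species
  (μ=0, σ=1.5) — skewed enough that sampled assemblages carry singletons
  and doubletons, the fuel of the unseen-species estimator.
- **Change**: in the second period each cell independently loses each
  species with probability `extinction_fraction` (known mean change, e.g.
  0.2 → per-cell logratio ≈ ln 0.8 up to binomial noise), and the top-k
  globally commonest species become ubiquitous (`expansion_k`, the
  homogenisation knob). A cell emptied by extinction keeps its locally
  commonest species so estimators never see an empty assemblage.
- **Effort**: records per cell-period are lognormal (σ_log 0.4) around a
  mean of 2000, with a between-period multiplier for imbalance
  experiments. The default depth emulates well-recorded atlas cells
  (order 10³ records per 10-km cell-period, the regime national recording
  schemes reach) and keeps default landscapes above both default selection
  thresholds. Sampling is multinomial in the cell's local relative
  abundances; truth tables are computed from the noise-free presence
  matrices and are invariant to the effort model.

What the generator does *not* emulate: recorder-behaviour drift within a
period, spatially biased effort (e.g. roadside recording), detection
differences between taxa, climate- or land-use-driven range shifts, and
taxonomic structure beyond a flat species list. Passing tests therefore
demonstrate that the machinery removes *effort-structure* artefacts it was
designed for, not that it is robust to every failure mode of real
collections.

## Validation sizes and numerical choices

The test suite validates: rarefaction against exhaustive subset enumeration
(n ≤ 12, tolerance 1e-9); extrapolation limits and monotonicity;
the comparison-point rule on an effort grid including the threefold
boundary; bias reduction vs the naive observed-richness ratio on 100
zero-change landscapes with 3× effort imbalance (6×6 cells); CI coverage
of a true −20% change on 100 default landscapes; the meta-analysis against
a hand-derived closed form and statsmodels' `combine_effects`; moderator
recovery of an injected 0.1·delta_r bias; βsim against brute-force set
construction; distance-decay slope recovery; homogenisation detection and
its false-positive rate on 50 landscapes each (4×4 cells, R = 30); and
spatial-model selection power/specificity on 50 replicates each (10×10
centroids, exponential range 3 cells). Replicate counts and landscape sizes
are the package's validation design: large enough for the stated
fraction-of-replicates bounds to be meaningful binomial checks, small
enough to keep the suite routinely runnable.

Numerics: combinatorial terms in log-gamma space; bootstrap SDs with
`ddof=1`; REML profile via bounded scalar minimisation with an explicit
τ²=0 boundary check; GLS range profiled on log ρ between a quarter of the
minimum and eight times the maximum pairwise distance; empirical-logit
boundary rule as above; all random streams are `numpy.random.Generator`s
derived from explicit seeds via `SeedSequence` (pair streams via CRC32 of
the pair key, so parallel enumeration orders agree).

## Known limitations

- **Finite-effort attenuation.** Comparison-point estimates compare
  expected species counts at effort `cp`, not asymptotic richness. When
  sampling is shallow relative to assemblage richness the logratio is
  attenuated toward zero (both periods' curves are far from their
  asymptotes, and renormalised abundances after species loss raise
  per-species detectability). At the default depth the residual bias on a
  −20% change is below the meta-analytic CI width; at 50–200 records per
  cell-period on ~50-species assemblages it can reach a quarter of the
  signal. Interpret shallow-data results as change in *recorded* richness
  at equal effort.
- The delta-method variance of the logratio and the normal z-tests are
  first-order approximations; very small X or variance near zero strains
  them (zero variances are floored, not modelled).
- The 1-df χ² for the spatial LRT is conservative (range parameter on the
  boundary under the null).
- The equal-effort similarity subsample is a Monte-Carlo estimate; its
  resolution (and the logit boundary treatment) is set by R.
- The equal-effort similarity is tied to the common effort m: below its
  plateau it rises nonlinearly with m, and because the decay model carries
  only a *linear* `n_min` term, systematic between-period differences in m
  can leak into the period contrast when cells are shallowly sampled.
  Period comparisons are most trustworthy when the least-sampled cells are
  already well sampled.
- Partial-residual centring removes the effort gradient, not a nonzero
  mean effort effect; with systematically imbalanced effort
  (`mean(delta_r) ≠ 0`) any uncorrected mean bias remains in `Qw`.
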
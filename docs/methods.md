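# Methods

## Observation units and data model

The unit of analysis is a grid cell of configurable edge (default 0.5 km, the
resolution of the annual carbon maps this design targets), carrying five
time-invariant spatial-location covariates — elevation (m), slope (degrees),
and distances to roads, settlements and rivers (km) — an optional categorical
region (administrative states analogue), a tenure label (IT, OA, PA, OTHER),
and annual aboveground carbon density (t C/ha) over a contiguous year range
(default 2003–2016). Coordinates are planar km on a regular grid: every
distance the analysis uses is below a few tens of km, where planar error is
negligible, and the synthetic landscapes are abstract. Ingest accepts a flat
CSV table or a dict of aligned 2D arrays (the raster-stack analogue); layers
must already share extent and resolution — upstream resampling is GIS
plumbing outside this package's scope.

Cells of tenure classes other than the one under study are excluded from the
control pool everywhere (control = unprotected land only), so counterfactuals
are never themselves protected.

## Matching

Coarsened exact matching bins each covariate with half-open intervals
`[anchor + k·w, anchor + (k+1)·w)` (fixed width; explicit cutpoints and
categorical identity are also supported). Units sharing the joint coarsened
key over all five covariates — plus any extra exact keys such as region or a
spatial tile — form a matching sub-group; sub-groups lacking either arm are
pruned. No weighting is applied: the sub-groups enter the effect models as
random-intercept groups rather than as weights.

Default coarsening for landscape-wide (temporal) matching: elevation 100 m,
slope 5°, distances 5 km. The elevation width is the canonical choice for
this design; the slope and distance widths are package defaults, and
`width_search` automates the balance-driven refinement that this kind of
analysis otherwise performs by hand (trying proportionally finer widths until
all covariates pass the balance check). Balance is reported as standardized
mean differences — with the pooled SD fixed at its pre-matching value so
before/after rows are comparable — and Kolmogorov–Smirnov statistics; the
balance check warns rather than errors, since residual imbalance is spanned
by the covariate fixed effects downstream.

Within discontinuity buffers the default bins are coarser (elevation 300 m,
slope 10°, distances 8 km): a buffer already restricts the sample to locally
comparable cells and the binding constraint is the spatial tile. Fine bins
inside km-scale tiles mostly prune the cells that differ in boundary depth,
which is the very contrast the design estimates — with fine bins the
noise-free spatial-effect profile nearly flattens because retained matches
concentrate at the boundary (this concentration is itself a real phenomenon:
matched estimates are conservative in exactly this sense, and the
distance-to-boundary diagnostics quantify it).

## Effect models

Each year is fit by REML with `statsmodels.MixedLM`: fixed effects are the
intercept, the tenure dummy, the five covariates, and region dummies when
several regions are present; the matched sub-group is a random intercept.
Covariate columns (and region dummies) are centred on the control-arm means
of the matched sample, making the intercept the adjusted mean carbon density
of other lands — the baseline the percent effect `100·b1/b0` refers to.
Matching is performed once on the time-invariant covariates and reused across
years, so the annual series reflects outcome dynamics rather than sample
drift.

Inference uses a t reference with between-within degrees of freedom
(`n_strata − 2`) rather than a normal reference: with few matched sub-groups,
normal-based Wald p-values are anti-conservative (the motivation for
lmerTest-style corrections), and the spatial null-calibration results below
depend on this. A singular fit (zero stratum variance or numerical failure)
falls back to the equivalent OLS fit and is flagged; a constant outcome is
handled exactly without a model fit. Degenerate designs (fewer than two
strata, or fewer units than fixed effects plus three) raise instead of
returning numbers.

Falsification (placebo) tests refit the model with one matching covariate as
the outcome and the remaining four as fixed effects, and additionally report
the effect standardized by the covariate's pre-matching pooled SD.

## Geographic discontinuity design

For a tenure class, the signed boundary distance (positive inside) is the
centre-to-centre Euclidean distance to the nearest cell of opposite
membership, computed by exact Euclidean distance transform and verified
against an all-pairs brute-force oracle in the tests. Buffers are two-sided
and symmetric: cells with |distance| ≤ b, inside cells as treatment, outside
unprotected cells as control. The matching radius is twice the buffer depth;
it is enforced as an exact-match key on square tiles of side equal to the
radius, which guarantees any two matched units lie within radius·√2 of each
other.

The tile origin is arbitrary, and which near-boundary strata survive pruning
depends on the alignment of tiles with the boundary. Each buffer is therefore
fit at several evenly offset origins and the estimates averaged (six offsets
for km-scale tiles, where alignment dominates; two for tiles of 10 km or
more, which dominate runtime). The averaged estimate uses the mean of the
per-origin standard errors, which overstates the SE of an average of
positively correlated fits, so the reported intervals are conservative.
Buffers where no origin yields at least two matched strata are reported as
absent rather than estimated.

The profile reports the percent effect on two bases — `100·b1/b0` (relative
to the outside baseline) and `100·b1/(b0+b1)` (relative to the inside mean) —
because the percentage base for spatial effects is genuinely ambiguous in
practice; both are exported.

## Sensitivity analysis

Effects are summarised by the E-value chain `d = b1/σ`, `ER = exp(1.81·d)`,
`E = ER + √(ER·(ER−1))`. σ defaults to the pooled SD of the outcome in the
matched sample: the 1.81 constant is the standard conversion of a
standardized mean difference to an approximate log odds ratio (π/√3), which
presumes an outcome SD; the estimate's standard error is available as an
alternative (`sigma_source="se"`). Protective effects (ER < 1) are inverted
to 1/ER before the E-value formula and flagged, per the usual convention.

## Synthetic landscapes

The generator produces, deterministically from (config, seed):

- **Covariates** — Gaussian-smoothed noise fields with configured marginal
  mean/SD and correlation length, clipped to physical ranges. Default
  correlation lengths are short (1.5–2 cells): the grid is a scaled-down
  study area in which a few tens of km stand in for a continental-scale
  basin, and what matters for the statistics is the number of independent
  covariate patches per tenure, not the absolute correlation range. Long-
  range fields at this grid size would make each tenure a single covariate
  patch, destroying the replication the full-scale design enjoys.
- **Tenure** — contiguous circular blobs whose centres are drawn with
  probability ∝ exp(Σ bias·z) over *blob-scale smoothed* covariates:
  territories are sited in broadly high/remote regions, not sorted cell by
  cell, so the marginal tenure-vs-other contrast is detectable (rank tests)
  while fine-scale residuals within a coarsened bin remain unsorted (clean
  falsification). Overlapped Areas arise as IT∩PA footprints, with one PA
  blob centred inside an IT blob by default so OA cells always exist. A
  "bands" geometry provides territories deeper than the widest buffer for
  discontinuity studies. Defaults: bias +2 (smoothed z-scale) toward high
  elevation and large road/settlement distances, +1 toward steep slope.
- **Carbon** — first year
  `b0 + β·(Z−Z̄) + τ[tenure] + g·clip(d_signed, ±15 km) + η + ε`, truncated
  at zero: baseline 100 t C/ha; β gives higher stocks far from access routes;
  τ is the injected tenure premium; g a carbon gradient in the signed
  boundary distance (saturating at 15 km, where vegetation gradients level
  off); η a correlated error field (SD 2 t C/ha, 1 km correlation length —
  an unobservable acting on a *sub-locality* scale, which the matched
  sub-group random intercept should absorb; a field correlated at tenure
  scale would be unmeasured confounding proper, the E-value's domain, not a
  generator default); ε white observation noise (SD 6 t C/ha, redrawn each
  year). Later years multiply the latent surface by
  `1 − loss_rate·exp(−dist_roads/decay)` outside tenure (attenuated inside by
  `protect_factor`), so the tenure-vs-other gap widens over time.

### Packaged scenarios

- `null` — τ = 0, g = 0, no loss: calibration of false positives.
- `temporal-effect` — τ = 15 t C/ha, road-driven loss (4%/yr at the roadside,
  10 km decay), 80×80 grid, six IT and three PA blobs, ten regions:
  parameter recovery and temporal widening. Regions serve as exact-match
  keys, mirroring the use of states as covariates in large heterogeneous
  countries.
- `boundary-gradient` — τ = 10, g = 2 t C/ha per km, a deep band territory
  on a 140×140 grid (every buffer depth up to 15 km lies strictly inside the
  tenure, as real territories are far deeper than 15 km), observation noise
  lowered to 3 t C/ha by power design: the smallest profile increment (the
  0.5→1 km pair, ~+0.3 t C/ha under tile-matched estimation at 0.5 km cells)
  must remain detectable. Noise robustness is the recovery and null
  scenarios' job; this scenario isolates spatial structure.

### What the generator does and does not emulate

It reproduces the features the estimators rely on: non-random placement
correlated with covariates, locally correlated unobservables, boundary
gradients, and access-driven degradation. It does not attempt realistic fire
or logging processes, country-shaped geometries, temporally varying
covariates, or measurement artefacts of satellite carbon maps. Passing tests
therefore demonstrate that the estimators recover known effects under the
structural assumptions of the design — not that those assumptions hold in any
particular real landscape.

## Validation results computed by the test suite

The acceptance tests (tests/test_acceptance.py) and `scripts/acceptance.py`
compute, at desk scale: exact agreement of CEM with brute-force grouping
(200 random instances) and of signed distances with all-pairs search (50×50
mosaics); ≥90% CI coverage and <5% mean bias for the injected 15 t C/ha
effect over 50 seeds at 100×100 (the rare seed whose matching finds no
common support counts as uncovered); ≥90% falsification CI coverage over
covariate×seed cases with a +100 m positive control detected when elevation
is deliberately left unmatched; ≤10% falsely significant spatial effects on
null landscapes over 100 seeds; monotone spatial-effect profiles in ≥90% of
gradient-scenario seeds; E-value identities and dual-implementation
agreement; and a non-decreasing seed-mean annual effect series under
outside-only loss with every seed ending above its start. Problem sizes
(grid dimensions, seed counts) are the package's desk-scale choices and are
set in the tests themselves.

## Known limitations

- CEM on five jointly binned covariates retains a small fraction of cells at
  desk-scale n; degenerate seeds are reported as unusable rather than forced.
- Standard errors assume independent residuals given the random intercept;
  spatial autocorrelation beyond the sub-locality scale is deliberately not
  modelled (no autocorrelation-robust SEs), so confounding-scale fields fall
  to the E-value analysis.
- The origin-averaged discontinuity intervals are conservative by
  construction.
- One-dimensional regression-discontinuity polynomial fits in distance, CEM
  weighting (k2k), and propensity/nearest-neighbour matching are out of
  scope.
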
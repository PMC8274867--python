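# geodisc

Causal effect estimation for land tenure and forest carbon: coarsened exact
matching, annual random-intercept effect models, geographic discontinuity
designs across tenure boundaries, falsification tests, and E-value
sensitivity analysis — with a synthetic-landscape generator that provides
ground truth for validating every stage.

## The problem

Indigenous Territories (IT), Protected Areas (PA) and their overlaps (OA) are
not placed at random: they sit at higher elevations, on steeper slopes and
farther from roads and settlements than unprotected land. Naively comparing
carbon stocks inside and outside these tenures therefore confounds governance
with geography. This package implements a matched, spatially explicit
counterfactual analysis for gridded landscapes (~500 m observation units
carrying five spatial-location covariates, a tenure label, and annual
aboveground carbon density in t C/ha):

1. **Temporal effects.** Coarsened exact matching (CEM) bins each covariate —
   e.g. 100 m elevation intervals — and keeps only matching sub-groups that
   contain at least one treated and one control cell. Each year *t* is fit
   with a linear mixed model

   ```
   y_t = b0_t + b1_t·x_t + β·Z_t + α + e_t
   ```

   where `x_t` is the tenure dummy, `Z_t` the covariates (fixed effects,
   centred on control means so `b0_t` is the adjusted carbon baseline of
   other lands), and `α` a random intercept per matched sub-group. `b1_t`
   is the annual tenure effect in t C/ha; `100·b1/b0` is the percent effect.

2. **Spatial effects.** Geographic discontinuity designs compare symmetric
   buffers (0–0.5 up to 0–15 km) around tenure boundaries, with matching
   additionally constrained by a spatial tile key of side equal to the
   matching radius (twice the buffer depth: 2 km for the 0–1 km buffer,
   30 km for 0–15 km), so matched counterfactuals are geographically
   proximate. Falsification tests refit the model with each covariate as a
   placebo outcome.

3. **Sensitivity.** Each effect is summarised by an E-value via
   `d = b1/σ`, `ER = exp(1.81·d)`, `E = ER + √(ER·(ER−1))` — the minimum
   strength of unmeasured confounding (risk-ratio scale) needed to explain
   the effect away.

The synthetic generator emulates the statistical structure this design
assumes — autocorrelated covariate fields, biased tenure placement, a
boundary carbon gradient, and road-driven annual losses outside tenure — with
every injected parameter recorded as ground truth.

## Worked example

```python
import geodisc as g

cfg = g.scenario_config("temporal-effect")       # tau = 15 t C/ha injected
grid, truth = g.generate_landscape(cfg, seed=0)
matched = g.build_matched_set(grid.table, "IT", extra_exact=("region",))
est = g.fit_effect(matched, grid, year=2003)
sens = g.sensitivity_for(est, matched, grid)
ts = g.temporal_series(grid, matched)
```

This prints, via the fields of the returned objects:

```
matched sample: 16 sub-groups, 18 IT / 21 control cells
2003 temporal effect: b1 = 15.1 t C/ha (95% CI 10.8 to 19.5), baseline b0 = 98.0 t C/ha
percent effect: 15%
sensitivity: d = 1.62, ER = 18.61, E-value = 36.70
2003->2016 change in b1: +12.1 t C/ha
```

The model recovers the injected 15 t C/ha effect (the CI covers the truth);
the percent effect says IT cells hold 15% more carbon than the matched
baseline; the E-value of 36.7 means an unmeasured confounder would need a
~37-fold association with both tenure placement and carbon stocks to explain
the effect away; and the effect widens by 12 t C/ha to 2016 because
road-driven losses erode carbon only outside tenure.

The same objects feed the discontinuity analysis:

```python
prof = g.spatial_profile(grid, g.DiscontinuitySpec(tenure_class="IT"))
prof.to_frame()        # effect, CI, percent (both bases), per buffer x year
```

## Command line

```bash
geodisc simulate --scenario boundary-gradient --seed 1 --out sim/
geodisc temporal --scenario temporal-effect --seed 1 --out results/
geodisc spatial  --scenario boundary-gradient --seed 1 --out results/
geodisc all      --config cfg.yaml --seed 1 --out results/
```

Each run writes tidy CSVs (contrasts, balance, annual effects, spatial
profiles, falsification tests, sensitivity results), a human-readable
summary, and the full configuration with its hash for provenance.

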
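"""Mixed-model effect estimation, percent effects, falsification tests."""

import numpy as np
import pandas as pd
import pytest

from geodisc.cem import CoarseningSpec, build_matched_set
from geodisc.effects import (
    EffectEstimate,
    falsification_test,
    fit_effect,
    percent_effect,
    temporal_series,
)
from geodisc.landscape import COVARIATES, LandscapeGrid
from geodisc.simulate import generate_landscape, scenario_config

from conftest import make_grid


def two_strata_grid(outcome_fn, years=(2003,)):
    """8 units, two elevation strata, 2 treated + 2 control each."""
    tenure = np.array(
        [["IT", "IT", "OTHER", "OTHER"], ["IT", "IT", "OTHER", "OTHER"]], dtype=object
    )
    elev = np.array([[100.0] * 4, [900.0] * 4])
    carbon = {
        y: outcome_fn(tenure, elev) for y in years
    }
    return make_grid(tenure, carbon=carbon, covariates={"elevation": elev}, years=years)


class TestFitEffect:
    def test_exact_linear_structure_recovered(self):
        grid = two_strata_grid(lambda t, e: 10.0 + 5.0 * (t == "IT"))
        m = build_matched_set(grid.table, "IT")
        est = fit_effect(m, grid, year=2003)
        assert est.b1 == pytest.approx(5.0, abs=1e-6)
        assert est.b0 == pytest.approx(10.0, abs=1e-6)

    def test_constant_outcome_degenerate(self):
        grid = two_strata_grid(lambda t, e: np.full(t.shape, 42.0))
        m = build_matched_set(grid.table, "IT")
        est = fit_effect(m, grid, year=2003)
        assert est.b1 == 0.0
        assert est.b0 == 42.0
        assert est.p_value == 1.0

    def test_intercept_is_adjusted_control_mean(self, rng):
        # covariates vary: centering on control means keeps b0 = control mean
        tenure = np.where(rng.random((12, 12)) < 0.4, "IT", "OTHER").astype(object)
        elev = rng.normal(500, 80, (12, 12))
        carbon = {2003: 100.0 + 0.05 * (elev - 500.0)}
        grid = make_grid(tenure, carbon=carbon, covariates={"elevation": elev})
        m = build_matched_set(grid.table, "IT")
        est = fit_effect(m, grid, year=2003)
        idx = grid.table.set_index("cell_id")
        control_mean = idx.loc[m.control_ids, "carbon_2003"].mean()
        assert est.b0 == pytest.approx(control_mean, abs=1.0)

    def test_outcome_shift_moves_intercept_only(self, rng):
        tenure = np.where(rng.random((12, 12)) < 0.4, "IT", "OTHER").astype(object)
        elev = rng.normal(500, 150, (12, 12))
        carbon = {2003: rng.normal(100, 10, (12, 12))}
        grid = make_grid(tenure, carbon=carbon, covariates={"elevation": elev})
        grid2 = make_grid(
            tenure, carbon={2003: carbon[2003] + 50.0}, covariates={"elevation": elev}
        )
        m = build_matched_set(grid.table, "IT")
        e1 = fit_effect(m, grid, year=2003)
        e2 = fit_effect(m, grid2, year=2003)
        assert e2.b1 == pytest.approx(e1.b1, abs=1e-6)
        assert e2.b0 - e1.b0 == pytest.approx(50.0, abs=1e-6)

    def test_matches_ols_when_no_stratum_effect(self, rng):
        import statsmodels.api as sm

        tenure = np.where(rng.random((15, 15)) < 0.4, "IT", "OTHER").astype(object)
        elev = rng.normal(500, 150, (15, 15))
        carbon = {2003: 100.0 + 8.0 * (tenure == "IT") + rng.normal(0, 5, (15, 15))}
        grid = make_grid(tenure, carbon=carbon, covariates={"elevation": elev})
        m = build_matched_set(grid.table, "IT")
        est = fit_effect(m, grid, year=2003)
        a = m.assignments()
        idx = grid.table.set_index("cell_id")
        y = idx.loc[a.cell_id, "carbon_2003"].to_numpy()
        e = idx.loc[a.cell_id, "elevation"].to_numpy()
        ctrl = a.treated.to_numpy() == 0
        X = np.column_stack(
            [np.ones(len(a)), a.treated.to_numpy(float), e - e[ctrl].mean()]
        )
        ols_b1 = sm.OLS(y, X).fit().params[1]
        # no true stratum variance: mixed estimate close to pooled OLS
        assert est.b1 == pytest.approx(ols_b1, abs=0.5)

    def test_ci_contains_point_estimate(self, rng):
        tenure = np.where(rng.random((12, 12)) < 0.4, "IT", "OTHER").astype(object)
        carbon = {2003: rng.normal(100, 10, (12, 12))}
        grid = make_grid(
            tenure, carbon=carbon,
            covariates={"elevation": rng.normal(500, 150, (12, 12))},
        )
        m = build_matched_set(grid.table, "IT")
        est = fit_effect(m, grid, year=2003)
        assert est.ci_b1[0] <= est.b1 <= est.ci_b1[1]
        assert est.ci_b0[0] <= est.b0 <= est.ci_b0[1]

    def test_single_stratum_rejected(self):
        df_grid = two_strata_grid(lambda t, e: 10.0 + 5.0 * (t == "IT"))
        specs = {c: CoarseningSpec(width=1e6) for c in COVARIATES}
        m = build_matched_set(df_grid.table, "IT", specs)
        assert m.n_strata == 1
        with pytest.raises(ValueError):
            fit_effect(m, df_grid, year=2003)


class TestPercentEffect:
    @pytest.mark.parametrize(
        "b1,b0,expected", [(37.0, 39.0, 95), (6.0, 105.0, 6), (0.0, 50.0, 0)]
    )
    def test_rounded_percent_of_baseline(self, b1, b0, expected):
        est = EffectEstimate(
            year=2003, tenure_class="PA", outcome="carbon_2003", b0=b0, b1=b1,
            se_b0=1.0, se_b1=1.0, ci_b0=(0, 0), ci_b1=(0, 0), p_value=0.01,
            beta={}, n_units=10, n_strata=2,
        )
        assert round(percent_effect(est)) == expected

    def test_non_positive_baseline_rejected(self):
        est = EffectEstimate(
            year=2003, tenure_class="PA", outcome="carbon_2003", b0=0.0, b1=5.0,
            se_b0=1.0, se_b1=1.0, ci_b0=(0, 0), ci_b1=(0, 0), p_value=0.01,
            beta={}, n_units=10, n_strata=2,
        )
        with pytest.raises(ValueError):
            percent_effect(est)


class TestTemporalSeries:
    def test_static_outcome_gives_flat_series(self, rng):
        tenure = np.where(rng.random((12, 12)) < 0.4, "IT", "OTHER").astype(object)
        carbon_surface = rng.normal(100, 10, (12, 12))
        years = (2003, 2004, 2005)
        grid = make_grid(
            tenure, carbon={y: carbon_surface for y in years}, years=years,
            covariates={"elevation": rng.normal(500, 150, (12, 12))},
        )
        m = build_matched_set(grid.table, "IT")
        ts = temporal_series(grid, m)
        assert np.allclose(ts.b1, ts.b1[0], atol=1e-8)
        assert ts.effect_change == pytest.approx(0.0, abs=1e-8)

    def test_single_year_series(self):
        tenure = np.full((6, 6), "OTHER", dtype=object)
        tenure[:, :3] = "IT"
        elev = np.tile(np.array([100.0, 100, 100, 100, 900, 900]), (6, 1)).T
        grid = make_grid(tenure, covariates={"elevation": elev})
        m = build_matched_set(grid.table, "IT")
        ts = temporal_series(grid, m, years=(2003,))
        assert len(ts.estimates) == 1

    def test_years_strictly_increasing(self, rng):
        tenure = np.where(rng.random((10, 10)) < 0.4, "IT", "OTHER").astype(object)
        years = (2003, 2004)
        grid = make_grid(
            tenure,
            carbon={y: rng.normal(100, 5, (10, 10)) for y in years},
            years=years,
            covariates={"elevation": rng.normal(500, 150, (10, 10))},
        )
        m = build_matched_set(grid.table, "IT")
        ts = temporal_series(grid, m)
        assert ts.years == sorted(ts.years)


class TestFalsification:
    def test_tested_covariate_excluded_from_fixed_effects(self):
        grid, _ = generate_landscape(scenario_config("temporal-effect"), 0)
        m = build_matched_set(grid.table, "IT", extra_exact=("region",))
        est = falsification_test(m, grid, "elevation")
        assert est.outcome == "elevation"
        assert "elevation" not in est.beta

    def test_matched_placebo_effects_mostly_null(self):
        covered = total = 0
        for seed in range(5):
            grid, _ = generate_landscape(scenario_config("temporal-effect"), seed)
            m = build_matched_set(grid.table, "IT", extra_exact=("region",))
            for cov in COVARIATES:
                est = falsification_test(m, grid, cov)
                total += 1
                covered += est.covers_zero()
        assert covered / total >= 0.8

    def test_unmatched_positive_control_detects_bias(self):
        # deliberately unmatched on the biased covariate: elevation bins so
        # coarse they never prune, bias injected as a +100 m tenure offset
        from geodisc.cem import DEFAULT_SPECS

        specs = dict(DEFAULT_SPECS) | {"elevation": CoarseningSpec(width=1e6)}
        detected = 0
        for seed in range(5):
            grid, _ = generate_landscape(scenario_config("temporal-effect"), seed)
            biased = grid.table.tenure != "OTHER"
            grid.table.loc[biased, "elevation"] += 100.0
            m = build_matched_set(grid.table, "IT", specs, extra_exact=("region",))
            est = falsification_test(m, grid, "elevation")
            detected += (not est.covers_zero()) and est.b1 > 0
        assert detected == 5

    def test_non_covariate_outcome_rejected(self):
        grid, _ = generate_landscape(scenario_config("temporal-effect"), 0)
        m = build_matched_set(grid.table, "IT", extra_exact=("region",))
        with pytest.raises(ValueError):
            falsification_test(m, grid, "carbon_2003")
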
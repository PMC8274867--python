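"""Geographic discontinuity machinery: buffers, tiles, matched profiles, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from geodisc.cem import CoarseningSpec
from geodisc.discontinuity import (
    DiscontinuitySpec,
    boundary_diagnostics,
    buffer_subset,
    discontinuity_match,
    spatial_block_key,
    spatial_profile,
)
from geodisc.landscape import COVARIATES, LandscapeGrid, boundary_distance
from geodisc.simulate import generate_landscape, scenario_config

from conftest import make_grid


class TestSpec:
    def test_radius_rule_doubles_buffer_depth(self):
        spec = DiscontinuitySpec(tenure_class="IT")
        assert spec.radius(1.0) == 2.0
        assert spec.radius(15.0) == 30.0
        assert spec.bounds == (0.5, 1.0, 5.0, 10.0, 15.0)

    def test_bounds_must_increase(self):
        with pytest.raises(ValueError):
            DiscontinuitySpec(tenure_class="IT", bounds=(1.0, 0.5))


class TestBufferSubset:
    def test_half_km_bound_keeps_only_boundary_rings(self, split_grid):
        dist = boundary_distance(split_grid, "IT")
        sub = buffer_subset(split_grid, dist, 0.5)
        assert set(sub["abs_distance"]) == {0.5}
        assert set(sub["side"]) == {"inside", "outside"}
        assert len(sub) == 20  # two 10-cell columns

    def test_nesting_over_bounds(self, rng):
        tenure = np.where(rng.random((20, 20)) < 0.3, "IT", "OTHER").astype(object)
        grid = make_grid(tenure)
        dist = boundary_distance(grid, "IT")
        prev: set = set()
        for bound in (1.0, 5.0, 15.0):
            ids = set(buffer_subset(grid, dist, bound)["cell_id"])
            assert prev <= ids
            prev = ids

    def test_counts_match_brute_force_filter(self, rng):
        tenure = np.where(rng.random((20, 20)) < 0.3, "IT", "OTHER").astype(object)
        grid = make_grid(tenure)
        dist = boundary_distance(grid, "IT")
        sub = buffer_subset(grid, dist, 2.0)
        d = dist.distance
        inside = (d > 0) & (d <= 2.0)
        outside = (d < 0) & (-d <= 2.0)
        assert len(sub) == inside.sum() + outside.sum()

    def test_other_tenure_excluded_from_outside(self):
        tenure = np.full((10, 10), "OTHER", dtype=object)
        tenure[:, :4] = "IT"
        tenure[:, 5] = "PA"  # adjacent protected strip outside the IT boundary
        grid = make_grid(tenure)
        dist = boundary_distance(grid, "IT")
        sub = buffer_subset(grid, dist, 5.0)
        outside_ids = sub.loc[sub.side == "outside", "cell_id"]
        assert (grid.table.set_index("cell_id").loc[outside_ids, "tenure"] == "OTHER").all()

    def test_empty_side_errors(self):
        tenure = np.full((10, 10), "OTHER", dtype=object)
        tenure[:, :5] = "IT"
        tenure[:, 5:] = "PA"  # no unprotected counterfactual anywhere
        grid = make_grid(tenure)
        dist = boundary_distance(grid, "IT")
        with pytest.raises(ValueError):
            buffer_subset(grid, dist, 5.0)


class TestSpatialBlockKey:
    def test_near_cells_share_tile_away_from_edges(self):
        assert spatial_block_key([0.3], [0.3], 2.0)[0] == spatial_block_key([0.7], [0.5], 2.0)[0]

    def test_far_cells_never_share_tile(self):
        assert spatial_block_key([0.0], [0.0], 2.0)[0] != spatial_block_key([50.0], [0.0], 2.0)[0]

    def test_positive_radius_required(self):
        with pytest.raises(ValueError):
            spatial_block_key([0.0], [0.0], 0.0)

    def test_matched_strata_respect_distance_bound(self, rng):
        tenure = np.where(rng.random((30, 30)) < 0.35, "IT", "OTHER").astype(object)
        grid = make_grid(
            tenure, covariates={"elevation": rng.normal(500, 100, (30, 30))}
        )
        dist = boundary_distance(grid, "IT")
        sub = buffer_subset(grid, dist, 2.0)
        radius = 4.0
        m = discontinuity_match(sub, "IT", radius=radius)
        idx = sub.set_index("cell_id")
        for t_ids, c_ids in m.strata.values():
            xy = idx.loc[t_ids + c_ids, ["x", "y"]].to_numpy()
            d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
            assert d.max() <= radius * np.sqrt(2) + 1e-9


class TestDiscontinuityMatch:
    def test_identical_covariates_one_tile_single_stratum(self):
        sub = pd.DataFrame(
            {
                "cell_id": [0, 1],
                "x": [0.25, 0.75],
                "y": [0.25, 0.25],
                "side": ["inside", "outside"],
                "region": ["all", "all"],
                **{c: [10.0, 10.0] for c in COVARIATES},
            }
        )
        m = discontinuity_match(sub, "IT", radius=2.0)
        assert m.n_strata == 1

    def test_matches_brute_force_grouping_with_tile_key(self, rng):
        tenure = np.where(rng.random((25, 25)) < 0.35, "IT", "OTHER").astype(object)
        elev = rng.normal(500, 150, (25, 25))
        grid = make_grid(tenure, covariates={"elevation": elev})
        dist = boundary_distance(grid, "IT")
        sub = buffer_subset(grid, dist, 3.0)
        radius = 6.0
        m = discontinuity_match(sub, "IT", radius=radius)
        # oracle: group by (coarsened key, tile), keep both-arm groups
        from geodisc.discontinuity import DISCONTINUITY_DEFAULT_SPECS
        from geodisc.cem import coarsen

        keys = []
        for _, r in sub.iterrows():
            k = tuple(
                coarsen([r[c]], DISCONTINUITY_DEFAULT_SPECS[c])[0] for c in COVARIATES
            ) + (spatial_block_key([r.x], [r.y], radius)[0],)
            keys.append(k)
        oracle = {}
        for k, cid, side in zip(keys, sub.cell_id, sub.side):
            t, c = oracle.setdefault(k, ([], []))
            (t if side == "inside" else c).append(cid)
        # stratum keys encode the tile through category codes, so compare the
        # partitions rather than raw keys
        oracle_sets = sorted(
            (sorted(t), sorted(c)) for (t, c) in oracle.values() if t and c
        )
        got_sets = sorted((sorted(t), sorted(c)) for (t, c) in m.strata.values())
        assert got_sets == oracle_sets

    def test_spatially_separated_sides_unmatchable(self):
        sub = pd.DataFrame(
            {
                "cell_id": [0, 1],
                "x": [0.0, 100.0],
                "y": [0.0, 0.0],
                "side": ["inside", "outside"],
                "region": ["all", "all"],
                **{c: [10.0, 10.0] for c in COVARIATES},
            }
        )
        m = discontinuity_match(sub, "IT", radius=2.0)
        assert m.is_empty


class TestSpatialProfile:
    def test_flat_effect_without_gradient(self):
        cfg = scenario_config("boundary-gradient", gradient_g=0.0)
        grid, truth = generate_landscape(cfg, 0)
        spec = DiscontinuitySpec(tenure_class="IT", years=(2003,))
        prof = spatial_profile(grid, spec)
        b1s = [b for _, b in prof.b1_series(2003)]
        assert len(b1s) == 5
        assert np.all(np.abs(np.array(b1s) - truth.tau_true["IT"]) < 2.0)

    def test_null_landscape_cis_cover_zero(self):
        grid, _ = generate_landscape(scenario_config("null"), 0)
        spec = DiscontinuitySpec(tenure_class="IT", years=(2003,))
        prof = spatial_profile(grid, spec)
        assert prof.estimates
        covered = [e.covers_zero() for e in prof.estimates.values()]
        assert np.mean(covered) >= 0.8

    def test_profile_frame_reports_both_percent_bases(self):
        cfg = scenario_config("boundary-gradient", rows=60, cols=60)
        grid, _ = generate_landscape(cfg, 1)
        spec = DiscontinuitySpec(tenure_class="IT", bounds=(1.0, 5.0), years=(2003,))
        frame = spatial_profile(grid, spec).to_frame()
        assert {"pct_of_baseline", "pct_of_inside"} <= set(frame.columns)
        assert (frame["pct_of_inside"].abs() <= frame["pct_of_baseline"].abs() + 1e-9).all()

    def test_changes_between_first_and_last_year(self):
        cfg = scenario_config("temporal-effect", rows=60, cols=60)
        grid, _ = generate_landscape(cfg, 0)
        spec = DiscontinuitySpec(tenure_class="IT", bounds=(5.0,), years=(2003, 2016))
        prof = spatial_profile(grid, spec)
        ch = prof.changes()
        if not ch.empty:  # buffer can be skipped on unlucky geometry
            e03 = prof.effect(5.0, 2003)
            e16 = prof.effect(5.0, 2016)
            assert ch.loc[0, "delta_b1"] == pytest.approx(e16.b1 - e03.b1)


class TestBoundaryDiagnostics:
    def test_boundary_adjacent_sample_means_half_km(self, split_grid):
        dist = boundary_distance(split_grid, "IT")
        sub = buffer_subset(split_grid, dist, 0.5)
        m = discontinuity_match(sub, "IT", radius=20.0)
        diag = boundary_diagnostics(m, split_grid, dist)
        assert diag.mean_treated == pytest.approx(0.5)
        assert diag.mean_control == pytest.approx(0.5)
        assert diag.sd_treated == pytest.approx(0.0)

    def test_matched_units_sit_nearer_boundary_than_full_sample(self):
        wins = 0
        for seed in range(5):
            grid, _ = generate_landscape(scenario_config("temporal-effect"), seed)
            dist = boundary_distance(grid, "IT")
            sub = buffer_subset(grid, dist, 15.0)
            m = discontinuity_match(sub, "IT", radius=30.0)
            if m.is_empty:
                continue
            diag = boundary_diagnostics(m, grid, dist)
            full_mean = np.abs(dist.distance).mean()
            wins += (diag.mean_treated + diag.mean_control) / 2 < full_mean
        assert wins >= 4

    def test_empty_matched_set_rejected(self, split_grid):
        from geodisc.cem import MatchedSet

        empty = MatchedSet("IT", {}, {}, 1, 1)
        dist = boundary_distance(split_grid, "IT")
        with pytest.raises(ValueError):
            boundary_diagnostics(empty, split_grid, dist)
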
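import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from avishift import (
    MaxentNicheModel,
    binarize,
    build_background,
    correlation_screen,
    density_filter,
    evaluate_auc,
    fit_niche_model,
    predict_suitability,
    prune_zero_contribution,
    sample_occurrences,
)
from avishift.errors import (
    DegenerateModelError,
    FitError,
    InsufficientDataError,
    NoRegionError,
)
from avishift.niche import land_cell_mask, sample_background_anywhere
from avishift.raster import RasterGrid
from avishift.synthetic import SpeciesTruth


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def brute_force_auc(p, b):
    conc = sum(1 for x in p for y in b if x > y)
    ties = sum(1 for x in p for y in b if x == y)
    return (conc + 0.5 * ties) / (len(p) * len(b))


class TestEvaluateAuc:
    @pytest.mark.parametrize(
        "p, b, expected",
        [
            ([0.9, 0.8], [0.1, 0.2], 1.0),         # perfect separation
            ([0.9, 0.3], [0.1, 0.5], 0.75),        # 3 of 4 pairs concordant
            ([0.5, 0.5], [0.5, 0.5], 0.5),         # all ties
        ],
    )
    def test_known_values(self, p, b, expected):
        assert evaluate_auc(p, b) == expected

    @settings(max_examples=60, deadline=None)
    @given(
        p=st.lists(st.floats(0, 1, width=16), min_size=1, max_size=50),
        b=st.lists(st.floats(0, 1, width=16), min_size=1, max_size=50),
    )
    def test_matches_all_pairs_count_exactly(self, p, b):
        assert evaluate_auc(p, b) == brute_force_auc(p, b)

    def test_empty_list_rejected(self):
        with pytest.raises(InsufficientDataError):
            evaluate_auc([], [0.5])


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

class TestCorrelationScreen:
    def test_duplicated_variable_loses_exactly_one(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=200)
        x2 = rng.normal(size=200)
        df = pd.DataFrame({"X1": x1, "X2": x2, "X3": x1})
        res = correlation_screen(df)
        assert len(res.retained_variables) == 2
        assert {"X1", "X3"} - set(res.retained_variables)  # one of the twins gone
        assert "X2" in res.retained_variables

    def test_hub_variable_removed_first(self):
        # X2, X3 share a factor (r ~ 0.7 < 0.9); their sum X1 correlates
        # > 0.9 with each, so X1 alone carries two high pairs
        rng = np.random.default_rng(1)
        z = rng.normal(size=800)
        x2 = np.sqrt(0.7) * z + np.sqrt(0.3) * rng.normal(size=800)
        x3 = np.sqrt(0.7) * z + np.sqrt(0.3) * rng.normal(size=800)
        x1 = x2 + x3 + 0.05 * rng.normal(size=800)
        df = pd.DataFrame({"X1": x1, "X2": x2, "X3": x3})
        corr = df.corr().abs()
        assert corr.loc["X1", "X2"] > 0.9 and corr.loc["X1", "X3"] > 0.9
        assert corr.loc["X2", "X3"] < 0.9
        res = correlation_screen(df)
        assert res.removal_order[0][0] == "X1"
        assert res.removal_order[0][1] == 2
        assert set(res.retained_variables) == {"X2", "X3"}

    def test_no_high_pairs_is_noop(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(100, 4)),
                          columns=["a", "b", "c", "d"])
        res = correlation_screen(df)
        assert res.retained_variables == ["a", "b", "c", "d"]
        assert res.removal_order == []

    def test_constant_variable_removed_with_warning(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"flat": np.ones(50), "x": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="constant"):
            res = correlation_screen(df)
        assert res.retained_variables == ["x"]

    def test_too_few_sites_rejected(self):
        with pytest.raises(InsufficientDataError):
            correlation_screen(pd.DataFrame({"a": [1, 2], "b": [3, 4]}))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_postcondition_no_retained_pair_above_threshold(self, seed):
        rng = np.random.default_rng(seed)
        # random covariance with occasional near-duplicated columns
        base = rng.normal(size=(80, 3))
        mix = rng.uniform(-1, 1, size=(3, 6))
        df = pd.DataFrame(base @ mix + 0.1 * rng.normal(size=(80, 6)),
                          columns=list("abcdef"))
        res = correlation_screen(df)
        kept = df[res.retained_variables].corr().abs().to_numpy()
        np.fill_diagonal(kept, 0.0)
        assert kept.max() <= 0.9 + 1e-12
        assert set(v for v, _ in res.removal_order).isdisjoint(res.retained_variables)


# ---------------------------------------------------------------------------
# model fitting and projection
# ---------------------------------------------------------------------------

def _toy_design(n=400, seed=0):
    """Presences centred at x=1, background spread wide."""
    rng = np.random.default_rng(seed)
    xp = rng.normal(1.0, 0.4, n)
    xb = rng.uniform(-4, 6, n)
    X = pd.DataFrame({"temp": np.concatenate([xp, xb]),
                      "noise": rng.normal(size=2 * n)})
    y = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    return X, y


class TestMaxentNicheModel:
    def test_recovers_the_generating_optimum(self):
        X, y = _toy_design()
        m = MaxentNicheModel(random_state=0).fit(X, y)
        assert m.fitted_optimum("temp") == pytest.approx(1.0, abs=0.2)
        assert m.mean_test_auc() > 0.85

    def test_replicate_scores_has_k_entries(self):
        X, y = _toy_design()
        m = MaxentNicheModel(k_folds=5, random_state=0).fit(X, y)
        assert len(m.replicate_scores_) == 5
        assert len(m.replicate_coefs_) == 5
        assert m.cv_presence_scores_.shape == (400,)

    def test_constant_feature_names_variable(self):
        X, y = _toy_design()
        X["flat"] = 3.0
        with pytest.raises(FitError, match="flat"):
            MaxentNicheModel().fit(X, y)

    def test_cloglog_closed_form_and_limits(self):
        X, y = _toy_design(seed=1)
        m = MaxentNicheModel(random_state=1).fit(X, y)
        # eta = 0 -> p = 1 - 1/e; push eta via direct formula on the design
        from avishift.niche import _cloglog
        assert _cloglog(np.array([0.0]))[0] == pytest.approx(1 - np.exp(-1))
        assert _cloglog(np.array([-50.0]))[0] == pytest.approx(0.0, abs=1e-12)
        assert _cloglog(np.array([50.0]))[0] == pytest.approx(1.0, abs=1e-12)
        s = m.predict_suitability(X)
        assert np.all((s > 0) & (s < 1))

    def test_json_roundtrip_preserves_predictions(self):
        X, y = _toy_design(seed=2)
        m = MaxentNicheModel(random_state=2).fit(X, y)
        m2 = MaxentNicheModel.from_dict(json.loads(json.dumps(m.to_dict())))
        np.testing.assert_allclose(m2.predict_suitability(X),
                                   m.predict_suitability(X), rtol=1e-12)

    def test_too_few_presences_rejected(self):
        X = pd.DataFrame({"t": np.arange(10.0)})
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(InsufficientDataError):
            MaxentNicheModel().fit(X, y)


class TestGeographicFit:
    def test_constant_climate_gives_uniform_suitability(self):
        vals = np.stack([np.full((10, 10), 5.0), np.arange(100.0).reshape(10, 10)])
        clim = RasterGrid(vals, lon_west=0, lat_north=10, cell_size=1,
                          band_names=("flat", "x"))
        truth = SpeciesTruth("sp", {"x": 50.0}, {"x": 10.0})
        occ = sample_occurrences(truth, clim, 60, seed=0)
        land = land_cell_mask(clim)
        bg = sample_background_anywhere(land, 80, seed=1)
        m = fit_niche_model(occ, bg, clim, variables=["x"], seed=2)
        suit = predict_suitability(m, clim)
        assert suit.values.min() > 0 and suit.values.max() < 1
        # projecting onto a constant-x world flattens the response
        flat = clim.with_values(
            np.stack([vals[0], np.full((10, 10), 50.0)]),
            band_names=("flat", "x"))
        s2 = predict_suitability(m, flat)
        assert np.allclose(s2.values, s2.values.flat[0])

    def test_niche_recovery_from_synthetic_world(self, small_world, cohort):
        cur = small_world["climate_current"]
        truth = cohort[2]
        occ = sample_occurrences(truth, cur, 500, seed=7)
        land = land_cell_mask(cur)
        bg = sample_background_anywhere(land, 1000, seed=8)
        m = fit_niche_model(occ, bg, cur, seed=9)
        err = abs(m.fitted_optimum("bio1") - truth.niche_optimum["bio1"])
        assert err < 0.5 * truth.niche_breadth["bio1"]
        assert m.mean_test_auc() > 0.8

    def test_missing_band_raises_projection_error(self, small_world, cohort):
        from avishift.errors import ProjectionError
        cur = small_world["climate_current"]
        occ = sample_occurrences(cohort[0], cur, 100, seed=0)
        bg = sample_background_anywhere(land_cell_mask(cur), 300, seed=1)
        m = fit_niche_model(occ, bg, cur, seed=2)
        stripped = RasterGrid(cur.values[1:], lon_west=cur.lon_west,
                              lat_north=cur.lat_north, cell_size=cur.cell_size,
                              band_names=cur.band_names[1:])
        with pytest.raises(ProjectionError):
            predict_suitability(m, stripped)


class TestBackground:
    def test_background_confined_to_occupied_region(self, small_world, cohort):
        regions = small_world["regions"]
        land = np.ones((regions.n_rows, regions.n_cols), dtype=bool)
        # all presences in region 2 (north-east block)
        rows, cols = np.nonzero(regions.values == 2)
        lon, lat = regions.center_of(rows[:10], cols[:10])
        pts = pd.DataFrame({"species_id": "sp", "lon": lon, "lat": lat})
        br, bc = build_background(pts, regions, land, 200, seed=0)
        assert np.all(regions.values[br, bc] == 2)

    def test_presences_everywhere_gives_full_support(self, small_world):
        regions = small_world["regions"]
        land = np.ones((regions.n_rows, regions.n_cols), dtype=bool)
        # one presence in each of the four region blocks
        lons, lats = [], []
        for rid in np.unique(regions.values):
            r, c = map(lambda a: a[0], np.nonzero(regions.values == rid))
            lon, lat = regions.center_of(r, c)
            lons.append(lon)
            lats.append(lat)
        pts = pd.DataFrame({"species_id": "sp", "lon": lons, "lat": lats})
        n_land = int(land.sum())
        br, bc = build_background(pts, regions, land, n_land * 2, seed=0)
        assert br.size == n_land  # exhaustion: every eligible cell returned

    def test_points_outside_all_regions_raise(self, small_world):
        regions = small_world["regions"]
        land = np.ones((regions.n_rows, regions.n_cols), dtype=bool)
        pts = pd.DataFrame({"species_id": "sp", "lon": [500.0], "lat": [89.0]})
        with pytest.raises(NoRegionError):
            build_background(pts, regions, land, 100, seed=0)


class TestPruneAndDensity:
    def test_zero_coefficient_variable_pruned(self):
        X, y = _toy_design(seed=3)
        m = MaxentNicheModel(random_state=3).fit(X, y)
        m.coef_ = m.coef_.copy()
        m.coef_[2:4] = 0.0  # zero out the 'noise' variable by hand
        assert prune_zero_contribution(m) == ["temp"]

    def test_generating_variable_survives_pruning(self, small_world, cohort):
        cur = small_world["climate_current"]
        occ = sample_occurrences(cohort[2], cur, 400, seed=11)
        bg = sample_background_anywhere(land_cell_mask(cur), 800, seed=12)
        m = fit_niche_model(occ, bg, cur, seed=13)
        assert "bio1" in prune_zero_contribution(m)

    def test_infinite_tolerance_is_degenerate(self):
        X, y = _toy_design(seed=4)
        m = MaxentNicheModel(random_state=4).fit(X, y)
        with pytest.raises(DegenerateModelError):
            prune_zero_contribution(m, tolerance=np.inf)

    @pytest.mark.parametrize(
        "presence_cols, n_loc, keep",
        [
            # DRM spanning 2 blocks of 3 degrees, 1 locality -> density 0.5
            ([(0, 0), (0, 35)], 1, False),
            # within 1 block, 5 localities -> density 5
            ([(2, 1), (3, 2)], 5, True),
            # 4 blocks, 4 localities -> density exactly 1: strict "< 1" keeps it
            ([(0, 0), (0, 35), (5, 0), (5, 35)], 4, True),
        ],
    )
    def test_locality_density_rule(self, presence_cols, n_loc, keep):
        # grid spanning 8 degrees of lon (40 cols x 0.2), 2 deg lat... make 6x40
        vals = np.zeros((31, 40))
        for r, c in presence_cols:
            vals[r, c] = 1.0
        grid = RasterGrid(vals, lon_west=0.0, lat_north=6.2, cell_size=0.2)
        from avishift.ranges import BinaryRange
        drm = BinaryRange(grid, threshold=0.5, species_id="sp")
        got_keep, density, _ = density_filter(drm, n_loc, block_size=3.0)
        assert got_keep is keep

    def test_empty_drm_excluded_with_reason(self):
        grid = RasterGrid(np.zeros((10, 10)), lon_west=0, lat_north=1, cell_size=0.1)
        from avishift.ranges import BinaryRange
        keep, density, reason = density_filter(BinaryRange(grid, 0.5), 10)
        assert not keep and reason == "no predicted range"
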
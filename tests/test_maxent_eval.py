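import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecoclim.maxent import (MaxentFeatures, MaxentModel, aicc, auc,
                            collinearity_filter, derive_topography, or10,
                            spatial_block_folds, thin_occurrences)


def brute_force_auc(pos, neg):
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_sets_give_half(self):
        assert auc([0.5, 0.7], [0.5, 0.7]) == 0.5

    def test_worked_example(self):
        assert auc([0.9, 0.8], [0.7, 0.85]) == pytest.approx(0.75)

    @given(pos=st.lists(st.floats(0, 1), min_size=1, max_size=20),
           neg=st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, pos, neg):
        assert auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(0)
        pos, neg = rng.random(30), rng.random(40)
        assert auc(pos, neg) + auc(neg, pos) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.5])


class TestOR10:
    def test_all_test_above_training(self):
        assert or10([0.1, 0.2, 0.3], [0.9, 0.95]) == 0.0

    def test_self_omission_with_ten_distinct_scores(self):
        scores = np.linspace(0.1, 1.0, 10)
        assert or10(scores, scores) == pytest.approx(0.1)

    def test_all_test_below_threshold(self):
        assert or10([0.5, 0.6, 0.7], [0.0, 0.01]) == 1.0


class TestAICc:
    @staticmethod
    def _unit_model(coef):
        feats = MaxentFeatures(["x"], [{"kind": "L", "var": "x", "lo": 0.0, "span": 1.0}])
        # alpha chosen so raw(x=1) == 1, hence lnL = 0 on presences at x = 1
        return MaxentModel(feats, np.array([coef]), 1.0, "L", -coef, 0.0, 0.0, {})

    def test_formula_arithmetic(self):
        pres = pd.DataFrame({"x": np.ones(5)})
        assert aicc(self._unit_model(0.5), pres) == pytest.approx(10.0 / 3.0)

    def test_zero_parameters_reduce_to_deviance(self):
        pres = pd.DataFrame({"x": np.ones(5)})
        assert aicc(self._unit_model(0.0), pres) == pytest.approx(0.0)

    def test_undefined_when_presences_too_few(self):
        pres = pd.DataFrame({"x": np.ones(2)})
        assert np.isnan(aicc(self._unit_model(0.5), pres))


class TestSpatialBlocks:
    def test_four_quadrants_four_folds(self):
        pts = pd.DataFrame({"lon": [-1, 1, -1, 1], "lat": [-1, -1, 1, 1]})
        assert set(spatial_block_folds(pts)) == {0, 1, 2, 3}

    def test_identical_points_rejected(self):
        pts = pd.DataFrame({"lon": [1.0] * 5, "lat": [2.0] * 5})
        with pytest.raises(ValueError, match="degenerate"):
            spatial_block_folds(pts)

    def test_median_split_balances_halves(self):
        rng = np.random.default_rng(3)
        pts = pd.DataFrame({"lon": rng.uniform(-10, 10, 80),
                            "lat": rng.uniform(30, 50, 80)})
        folds = spatial_block_folds(pts)
        south = np.isin(folds, [0, 1]).sum()
        west = np.isin(folds, [0, 2]).sum()
        assert abs(south - 40) <= 1 and abs(west - 40) <= 1
        assert all((folds == f).sum() > 0 for f in range(4))


class TestCollinearityFilter:
    def test_duplicated_column_keeps_higher_contribution(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        env = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(0, 1, 200)})
        kept = collinearity_filter(env, {"a": 10.0, "b": 40.0, "c": 5.0})
        assert kept == ["b", "c"] or kept == ["b", "a", "c"][:2]
        assert "b" in kept and "a" not in kept

    def test_independent_columns_all_kept(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame({f"v{i}": rng.normal(0, 1, 500) for i in range(5)})
        contributions = {f"v{i}": float(i) for i in range(5)}
        assert sorted(collinearity_filter(env, contributions)) == sorted(env.columns)

    def test_missing_contribution_rejected(self):
        env = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="b"):
            collinearity_filter(env, {"a": 1.0}, predictors=["a", "b"])


class TestTopography:
    def test_flat_surface(self):
        lats, lons = np.arange(3) * 1.0, np.arange(3) * 1.0
        slope, aspect = derive_topography(np.full((3, 3), 500.0), lats, lons)
        assert slope.max() == 0.0 and aspect.max() == 0.0

    def test_plane_rising_due_north(self):
        lats = np.arange(5) * 1.0
        lons = np.arange(4) * 1.0
        rise_per_cell = 1000.0  # meters per degree of latitude
        elev = np.broadcast_to(np.arange(5)[:, None] * rise_per_cell, (5, 4)).copy()
        slope, aspect = derive_topography(elev, lats, lons)
        inner = (slice(1, -1), slice(1, -1))
        expected = np.degrees(np.arctan(rise_per_cell / 110540.0))
        np.testing.assert_allclose(slope[inner], expected, rtol=1e-6)
        np.testing.assert_allclose(aspect[inner], 180.0, atol=1e-6)  # faces south

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            derive_topography(np.array([[1.0]]), np.array([0.0]), np.array([0.0]))


class TestThinning:
    def test_close_pair_reduced_to_one(self):
        pts = pd.DataFrame({"lon": [0.0, 0.009], "lat": [0.0, 0.0]})  # ~1 km apart
        assert len(thin_occurrences(pts, min_km=10.0)) == 1

    def test_sparse_points_all_retained(self):
        pts = pd.DataFrame({"lon": [0.0, 10.0, 20.0], "lat": [0.0, 10.0, 20.0]})
        assert len(thin_occurrences(pts, min_km=50.0)) == 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_greedy_matches_exhaustive_on_small_sets(self, seed):
        rng = np.random.default_rng(seed)
        pts = pd.DataFrame({"lon": rng.uniform(0, 0.5, 7), "lat": rng.uniform(0, 0.5, 7)})
        min_km = 25.0
        thinned = thin_occurrences(pts, min_km=min_km, seed=seed)
        # validity: no retained pair closer than min_km
        from ecoclim.maxent import haversine_km
        lon, lat = thinned["lon"].values, thinned["lat"].values
        d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
        assert np.all(d[~np.eye(len(thinned), dtype=bool)] >= min_km)
        # optimality: exhaustive maximum independent set has the same size
        lon0, lat0 = pts["lon"].values, pts["lat"].values
        full = haversine_km(lon0[:, None], lat0[:, None], lon0[None, :], lat0[None, :])
        best = 0
        for r in range(len(pts), 0, -1):
            for subset in itertools.combinations(range(len(pts)), r):
                sub = full[np.ix_(subset, subset)]
                if np.all(sub[~np.eye(r, dtype=bool)] >= min_km):
                    best = r
                    break
            if best:
                break
        assert len(thinned) == best
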
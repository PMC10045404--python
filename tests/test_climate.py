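import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoclim.climate import (CLIMATE_VARS, ClimateGrid, MonthlyClimate,
                             SyntheticClimateSpec, apply_scenario,
                             generate_climate_grid, monthly_to_weekly,
                             read_climate, weekly_fields, write_climate)


def flat_cell(tmean=20.0, rain_annual=520.0, rh=60.0, diurnal=0.0):
    return MonthlyClimate(
        tmin=np.full(12, tmean - diurnal / 2), tmax=np.full(12, tmean + diurnal / 2),
        rain=np.full(12, rain_annual / 12.0), rh09=np.full(12, rh), rh15=np.full(12, rh))


class TestGenerator:
    def test_lapse_rate_sets_annual_mean(self):
        spec = SyntheticClimateSpec(lat_min=28, lat_max=32, lon_min=0, lon_max=4,
                                    resolution=4, equator_mean_c=27, lapse_c_per_deg=0.6,
                                    seasonal_amplitude_c=5, noise_sd=0)
        grid = generate_climate_grid(spec)
        assert grid.lats[0] == 30.0
        tmean = 0.5 * (grid.tmin + grid.tmax)
        assert tmean[:, 0, 0].mean() == pytest.approx(27 - 0.6 * 30, abs=1e-9)

    def test_zero_amplitude_and_noise_gives_constant_months(self):
        spec = SyntheticClimateSpec(lat_min=0, lat_max=8, resolution=4,
                                    seasonal_amplitude_c=0, noise_sd=0)
        grid = generate_climate_grid(spec)
        for v in ("tmin", "tmax", "rh09", "rh15"):
            assert np.ptp(getattr(grid, v), axis=0).max() == 0

    def test_same_seed_bit_identical(self):
        spec = SyntheticClimateSpec(noise_sd=0.5, seed=123)
        a, b = generate_climate_grid(spec), generate_climate_grid(spec)
        for v in CLIMATE_VARS:
            assert np.array_equal(getattr(a, v), getattr(b, v))

    def test_seasonal_phase_flips_across_hemispheres(self):
        spec = SyntheticClimateSpec(lat_min=-44, lat_max=44, resolution=8, noise_sd=0)
        grid = generate_climate_grid(spec)
        tmean = 0.5 * (grid.tmin + grid.tmax)
        north, south = grid.lats > 0, grid.lats < 0
        # July (index 6) warm in the north, cool in the south
        assert np.all(tmean[6, north, 0] > tmean[0, north, 0])
        assert np.all(tmean[6, south, 0] < tmean[0, south, 0])

    @pytest.mark.parametrize("kwargs", [
        {"resolution": 0.0}, {"resolution": -1.0},
        {"lat_min": 10, "lat_max": 10}, {"rain_regime": "monsoon"},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_climate_grid(SyntheticClimateSpec(**kwargs))

    def test_generated_grid_satisfies_invariants(self):
        grid = generate_climate_grid(SyntheticClimateSpec(noise_sd=2.0, seed=3))
        grid.validate()
        assert np.all(grid.rain >= 0)
        assert np.all((grid.rh09 >= 0) & (grid.rh09 <= 100))


class TestMonthlyToWeekly:
    def test_constant_temperature_passes_through(self):
        wc = monthly_to_weekly(flat_cell(tmean=20))
        assert wc.tmean.shape == (52,)
        np.testing.assert_allclose(wc.tmean, 20.0, atol=1e-12)

    def test_uniform_daily_rain_splits_to_ten_mm_weeks(self):
        # 520 mm/year at a constant daily rate: every 7-day week carries 10 mm
        days = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)
        mc = flat_cell()
        mc.rain = 520.0 * days / 365.0
        wc = monthly_to_weekly(mc)
        assert wc.rain == pytest.approx(np.full(52, 10.0), abs=1e-9)
        assert wc.rain.sum() == pytest.approx(520.0, rel=1e-12)

    def test_weekly_ordering_invariant(self):
        wc = monthly_to_weekly(flat_cell(tmean=15, diurnal=9))
        assert np.all(wc.tmin <= wc.tmean) and np.all(wc.tmean <= wc.tmax)

    def test_inverted_temperatures_rejected(self):
        mc = flat_cell()
        mc.tmin[3] = mc.tmax[3] + 1.0
        with pytest.raises(ValueError, match="tmin"):
            monthly_to_weekly(mc)

    @given(rain=st.lists(st.floats(0, 500), min_size=12, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_rain_total_conserved_for_any_input(self, rain):
        mc = flat_cell()
        mc.rain = np.array(rain)
        wc = monthly_to_weekly(mc)
        total = mc.rain.sum()
        assert abs(wc.rain.sum() - total) <= 0.005 * total + 1e-9

    def test_grid_level_transform_matches_per_cell(self, small_grid):
        tmean, rain, rh = weekly_fields(small_grid)
        i, j = 1, 1
        wc = monthly_to_weekly(small_grid.cell(i, j))
        np.testing.assert_allclose(tmean[:, i, j], wc.tmean, atol=1e-12)
        np.testing.assert_allclose(rain[:, i, j], wc.rain, atol=1e-12)
        np.testing.assert_allclose(rh[:, i, j], wc.rh, atol=1e-12)


class TestScenario:
    def test_identity_transform(self, small_grid):
        out = apply_scenario(small_grid, 0.0, 1.0)
        np.testing.assert_array_equal(out.tmin, small_grid.tmin)
        np.testing.assert_array_equal(out.rain, small_grid.rain)

    def test_additive_warming_shifts_every_month(self, small_grid):
        out = apply_scenario(small_grid, 5.0, 1.0)
        np.testing.assert_allclose(
            0.5 * (out.tmin + out.tmax), 0.5 * (small_grid.tmin + small_grid.tmax) + 5.0)

    def test_zero_rain_factor_dries_but_keeps_humidity(self, small_grid):
        out = apply_scenario(small_grid, 0.0, 0.0)
        assert out.rain.max() == 0.0
        np.testing.assert_array_equal(out.rh09, small_grid.rh09)

    def test_negative_rain_factor_rejected(self, small_grid):
        with pytest.raises(ValueError):
            apply_scenario(small_grid, 0.0, -0.1)

    def test_warming_strictly_increases_weekly_tmean(self, small_grid):
        base = weekly_fields(small_grid)[0]
        warmed = weekly_fields(apply_scenario(small_grid, 2.0, 1.0))[0]
        assert np.all(warmed > base)


class TestIO:
    @pytest.mark.parametrize("fmt", ["netcdf", "csv"])
    def test_roundtrip(self, tmp_path, fmt, small_grid):
        path = tmp_path / f"grid.{fmt}"
        write_climate(small_grid, path, format=fmt)
        back = read_climate(path, format=fmt)
        for v in CLIMATE_VARS:
            np.testing.assert_allclose(getattr(back, v), getattr(small_grid, v), atol=1e-4)
        np.testing.assert_allclose(back.lats, small_grid.lats)

    def test_csv_missing_variable_named_in_error(self, tmp_path, small_grid):
        import pandas as pd
        path = tmp_path / "grid.csv"
        write_climate(small_grid, path, format="csv")
        df = pd.read_csv(path)
        df[df["var"] != "rh15"].to_csv(path, index=False)
        with pytest.raises(ValueError, match="rh15"):
            read_climate(path, format="csv")

    def test_netcdf_with_missing_month_rejected(self, tmp_path, small_grid):
        path = tmp_path / "grid.nc"
        ds = small_grid.to_dataset().isel(month=slice(0, 11))
        ds.to_netcdf(path, engine="scipy")
        with pytest.raises(ValueError, match="12 months"):
            read_climate(path)
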
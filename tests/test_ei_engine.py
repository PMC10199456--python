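import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoclim import ei_engine as ee
from ecoclim.ei_engine import WCSB_PARAMS as P
from ecoclim.errors import ConfigError, DataError

from conftest import random_monthly_climate


class TestSpeciesParams:
    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ConfigError):
            ee.SpeciesParams(dv0=21, dv1=13.4, dv2=28, dv3=31, pdd=500,
                             sm0=0.05, sm1=0.1, sm2=0.8, sm3=1.4,
                             ttcs=-10, thcs=-0.0005, tths=31, thhs=0.0015,
                             smds=0.05, hds=-0.005, smws=1.4, hws=0.001)

    def test_file_roundtrip_and_validation(self, tmp_path):
        path = tmp_path / "params.txt"
        P.to_file(path)
        assert ee.SpeciesParams.from_file(path) == P
        path.write_text(path.read_text().replace("dv0 = 13.4", ""))
        with pytest.raises(ConfigError, match="missing"):
            ee.SpeciesParams.from_file(path)


class TestWeeklyInterpolation:
    def test_constant_input_preserved(self):
        weekly = ee.interpolate_monthly_to_weekly(np.full(12, 10.0))
        np.testing.assert_allclose(weekly, 10.0)

    def test_constant_monthly_precipitation_scales_to_weekly_total(self):
        weekly = ee.interpolate_monthly_to_weekly(np.full(12, 31.0), kind="total")
        np.testing.assert_allclose(weekly, 31.0 * 12 / 52)
        assert weekly.mean() == pytest.approx(7.15, abs=0.01)
        # annual sum conserved
        assert weekly.sum() == pytest.approx(372.0, rel=5e-3)

    def test_piecewise_linear_is_monotone_between_midpoints(self):
        # July-peaking sinusoid: Jan ~0, Jul ~20
        monthly = 10.0 + 10.0 * np.cos(2 * np.pi * (np.arange(12) + 0.5 - 7) / 12)
        weekly = ee.interpolate_monthly_to_weekly(monthly)
        # rising limb: weeks between the January and July month midpoints
        rising = weekly[3:27]
        assert np.all(np.diff(rising) >= -1e-12)

    def test_monthly_means_of_weekly_series_reproduce_smooth_input(self):
        monthly = 12.0 + 8.0 * np.cos(2 * np.pi * (np.arange(12) + 0.5 - 7) / 12)
        weekly = ee.interpolate_monthly_to_weekly(monthly)
        t_week = (np.arange(52) + 0.5) * 365 / 52
        month_of_week = np.minimum((t_week // (365 / 12)).astype(int), 11)
        span = monthly.max() - monthly.min()
        for m in range(12):
            mean = weekly[month_of_week == m].mean()
            assert mean == pytest.approx(monthly[m], abs=0.02 * span)

    def test_missing_month_rejected(self):
        with pytest.raises(DataError):
            ee.interpolate_monthly_to_weekly(np.full(11, 1.0))
        with pytest.raises(DataError):
            ee.interpolate_monthly_to_weekly(np.r_[np.full(11, 1.0), np.nan])


@pytest.mark.parametrize("tavg,expected", [
    (13.4, 0.0),           # ramp starts at the lower threshold
    (5.0, 0.0),
    (24.5, 1.0),           # optimum plateau
    (17.2, 0.5),           # halfway up the lower ramp
    (31.0, 0.0),
    (29.5, 0.5),
])
def test_temperature_index_trapezoid(tavg, expected):
    assert ee.temperature_index(tavg, P) == pytest.approx(expected)


@pytest.mark.parametrize("sm,expected", [
    (0.05, 0.0),
    (0.45, 1.0),
    (1.1, 0.5),
    (1.4, 0.0),
])
def test_moisture_index_trapezoid(sm, expected):
    assert ee.moisture_index(sm, P) == pytest.approx(expected)


class TestSoilMoisture:
    def test_no_flux_keeps_state(self):
        assert ee.update_soil_moisture(0.5, 0.0, 0.0) == pytest.approx(0.5)

    def test_clamped_at_zero(self):
        assert ee.update_soil_moisture(0.0, 0.0, 30.0) == 0.0

    def test_stated_update_example(self):
        assert ee.update_soil_moisture(0.5, 25.0, 10.0) == pytest.approx(0.6)

    def test_negative_precip_rejected(self):
        with pytest.raises(DataError):
            ee.update_soil_moisture(0.5, -1.0, 10.0)

    def test_annual_cycle_reaches_fixed_orbit(self):
        rng = np.random.default_rng(3)
        precip = rng.uniform(0, 40, size=52)
        tavg = 10 + 10 * np.cos(2 * np.pi * (np.arange(52) - 26) / 52)
        cfg2 = ee.SoilMoistureConfig(n_cycles=2)
        cfg3 = ee.SoilMoistureConfig(n_cycles=3)
        year2 = ee.run_soil_moisture(precip, tavg, cfg2)
        year3 = ee.run_soil_moisture(precip, tavg, cfg3)
        np.testing.assert_allclose(year3, year2, atol=1e-6)


class TestDegreeDaysAndStress:
    def test_degree_days_zero_at_threshold(self):
        assert ee.annual_degree_days(np.full(52, P.dv0), P.dv0) == 0.0

    def test_degree_days_one_degree_year(self):
        assert ee.annual_degree_days(np.full(52, P.dv0 + 1), P.dv0) == pytest.approx(364.0)

    def test_degree_days_clamps_negative_weeks(self):
        tavg = np.r_[np.full(26, P.dv0 + 2), np.full(26, P.dv0 - 5)]
        assert ee.annual_degree_days(tavg, P.dv0) == pytest.approx(364.0)

    def test_cold_stress_zero_without_exceedance(self):
        tmin = np.full(52, -10.0)
        assert ee.accumulate_stress(tmin, P.ttcs, P.thcs, "below") == 0.0

    def test_cold_stress_stated_accumulation(self):
        tmin = np.r_[np.full(10, -20.0), np.full(42, 0.0)]
        s = ee.accumulate_stress(tmin, -10.0, 0.0005, "below")
        assert s == pytest.approx(35.0)

    def test_zero_rate_gives_zero_stress(self):
        assert ee.accumulate_stress(np.full(52, -40.0), -10.0, 0.0, "below") == 0.0

    def test_stress_caps_at_100(self):
        s = ee.accumulate_stress(np.full(52, -60.0), -10.0, 0.1, "below")
        assert s == 100.0

    @pytest.mark.parametrize("stresses,expected", [
        ((0, 0, 0, 0), 1.0),
        ((100, 0, 0, 0), 0.0),
        ((35, 0, 0, 0), 0.65),
        ((50, 50, 0, 0), 0.25),
    ])
    def test_stress_index_product(self, stresses, expected):
        assert ee.stress_index(*stresses) == pytest.approx(expected)


class TestEcoclimaticIndex:
    def test_gate_passes_when_degree_days_sufficient(self):
        res = ee.ecoclimatic_index(50.0, 0.65, 600.0, P, use_pdd=True)
        assert res.ei == pytest.approx(32.5)
        assert res.pdd_satisfied

    def test_gate_zeroes_ei_when_short(self):
        res = ee.ecoclimatic_index(50.0, 0.65, 400.0, P, use_pdd=True)
        assert res.ei == 0.0
        assert not res.pdd_satisfied
        assert res.category == "unsuitable"

    def test_gate_ignored_when_disabled(self):
        res = ee.ecoclimatic_index(50.0, 0.65, 400.0, P, use_pdd=False)
        assert res.ei == pytest.approx(32.5)

    @pytest.mark.parametrize("ei,cat", [
        (0.0, "unsuitable"), (5.0, "marginal"), (9.99, "marginal"),
        (10.0, "suitable"), (29.99, "suitable"), (30.0, "optimal"),
        (45.0, "optimal"), (100.0, "optimal"), (1e-9, "marginal"),
    ])
    def test_categories(self, ei, cat):
        assert ee.categorize_ei(ei) == cat


@settings(derandomize=True, deadline=None, max_examples=40)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_all_indices_bounded_on_random_climates(seed):
    """TI, MI, weekly GI in [0,1]; stresses in [0,100]; SI in [0,1]; EI in [0,100]."""
    rng = np.random.default_rng(seed)
    monthly = random_monthly_climate(rng, n=4)
    res = ee.compute_ei(monthly, P, use_pdd=bool(seed % 2))
    for arr, lo, hi in [(res.gi_a, 0, 100), (res.si, 0, 1), (res.ei, 0, 100),
                        (res.cs, 0, 100), (res.hs, 0, 100),
                        (res.ds, 0, 100), (res.ws, 0, 100)]:
        assert np.all(np.asarray(arr) >= lo) and np.all(np.asarray(arr) <= hi)
    assert np.all(np.asarray(res.dd_total) >= 0)


@settings(derandomize=True, deadline=None, max_examples=25)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.floats(min_value=0.5, max_value=10.0))
def test_stress_monotonicity_in_drivers(seed, delta):
    """Warming minima never increase cold stress; warming maxima never
    decrease heat stress; extra rain never increases dry stress."""
    rng = np.random.default_rng(seed)
    monthly = random_monthly_climate(rng)
    base = ee.compute_ei(monthly, P, use_pdd=False)
    warmer_min = dict(monthly, tmin=monthly["tmin"] + delta)
    assert np.all(ee.compute_ei(warmer_min, P, False).cs <= base.cs + 1e-9)
    warmer_max = dict(monthly, tmax=monthly["tmax"] + delta)
    assert np.all(ee.compute_ei(warmer_max, P, False).hs >= base.hs - 1e-9)
    wetter = dict(monthly, precip=monthly["precip"] + 10 * delta)
    assert np.all(ee.compute_ei(wetter, P, False).ds <= base.ds + 1e-9)


@settings(derandomize=True, deadline=None, max_examples=20)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_pdd_gate_soundness(seed):
    rng = np.random.default_rng(seed)
    monthly = random_monthly_climate(rng, n=8)
    res = ee.compute_ei(monthly, P, use_pdd=True)
    short = np.asarray(res.dd_total) < P.pdd
    assert np.all(np.asarray(res.ei)[short] == 0.0)


class TestEIMap:
    # precip 143 mm/month balances the bucket's evaporation at 22 degC
    # (1.5 * 22 = 33 mm/week = 143 * 12/52), holding soil moisture mid-range
    def _uniform_climate(self, geom, tavg=22.0, precip=143.0):
        shape = (12, *geom.shape)
        return {
            "tavg": np.full(shape, tavg),
            "tmin": np.full(shape, tavg - 4),
            "tmax": np.full(shape, tavg + 4),
            "precip": np.full(shape, precip),
        }

    def test_spatial_invariance_under_uniform_climate(self, small_geom):
        out = ee.ei_map(self._uniform_climate(small_geom), small_geom, P, use_pdd=False)
        assert len(np.unique(out["ei"])) == 1
        assert out["ei"][0, 0] > 30
        assert np.all(out["category"] == 3)

    def test_map_matches_scalar_pipeline_cell_by_cell(self, small_geom):
        rng = np.random.default_rng(11)
        n = small_geom.n_rows * small_geom.n_cols
        cells = random_monthly_climate(rng, n=n)
        rasters = {k: np.moveaxis(v.reshape(*small_geom.shape, 12), -1, 0)
                   for k, v in cells.items()}
        out = ee.ei_map(rasters, small_geom, P, use_pdd=True)
        for idx in range(0, n, 7):  # sample of cells, scalar oracle
            r, c = divmod(idx, small_geom.n_cols)
            single = {k: v[idx] for k, v in cells.items()}
            res = ee.compute_ei(single, P, use_pdd=True)
            assert out["ei"][r, c] == pytest.approx(res.ei, abs=1e-10)
            assert out["si"][r, c] == pytest.approx(res.si, abs=1e-10)

    def test_latitudinal_gradient_gives_monotone_ei(self):
        """With moisture non-limiting, EI is driven by the temperature
        trapezoid and cold stress alone, so a pure latitudinal temperature
        gradient gives EI non-increasing toward the cold edge."""
        from ecoclim.io import GridGeometry
        # moisture plateau spans every reachable soil-moisture state and
        # the moisture stresses are switched off
        p = ee.SpeciesParams(dv0=13.4, dv1=21.0, dv2=28.0, dv3=31.0, pdd=500.0,
                             sm0=-0.2, sm1=-0.1, sm2=10.0, sm3=11.0,
                             ttcs=-10.0, thcs=-0.0005, tths=31.0, thhs=0.0015,
                             smds=0.05, hds=0.0, smws=1.4, hws=0.0)
        geom = GridGeometry(n_rows=20, n_cols=2, origin_lon=0.0, origin_lat=40.0,
                            dlon=0.25, dlat=0.25)
        _, lat = geom.cell_centers()
        season = 8 * np.cos(2 * np.pi * (np.arange(1, 13) - 7) / 12)
        tavg = (18.0 - 0.9 * (lat - 40.0))[None] + season[:, None, None]
        rasters = {"tavg": tavg, "tmin": tavg - 4, "tmax": tavg + 4,
                   "precip": np.full((12, 20, 2), 70.0)}
        out = ee.ei_map(rasters, geom, p, use_pdd=False)
        col = out["ei"][:, 0]  # row 0 is the cold (northern) edge
        assert np.all(np.diff(col) >= -1e-9)
        assert col[-1] > col[0]  # warm edge strictly more suitable

    def test_all_nodata_grid_propagates(self, small_geom):
        clim = self._uniform_climate(small_geom)
        clim["tavg"][:] = np.nan
        out = ee.ei_map(clim, small_geom, P, use_pdd=False)
        assert np.isnan(out["ei"]).all()
        assert np.all(out["category"] == 255)

    def test_shape_mismatch_diagnosed(self, small_geom):
        clim = self._uniform_climate(small_geom)
        clim["tmin"] = clim["tmin"][:, :5, :]
        with pytest.raises(DataError, match="tmin"):
            ee.ei_map(clim, small_geom, P, use_pdd=False)
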
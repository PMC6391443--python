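"""Legacy-effect tests: baselines, recovery trajectories, regression
selection, forest stratification and regional carbon integration."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from droughtlegacy import (
    DroughtCatalog,
    absolute_trajectory,
    cell_areas,
    climate_normal_baseline,
    fit_cwd_npp_regression,
    percent_trajectory,
    regional_integral,
    stratify_by_forest,
)
from droughtlegacy.drought import _EVENT_COLUMNS
from droughtlegacy.legacy import EARTH_RADIUS_M

from conftest import make_annual_field


def make_catalog(events):
    """events: list of (ilat, ilon, start, end, excluded)."""
    rows = [
        (i, j, 40.25 + 0.5 * i, -100.25 + 0.5 * j, s, e, ex, "", False)
        for (i, j, s, e, ex) in events
    ]
    return DroughtCatalog(
        events=pd.DataFrame(rows, columns=_EVENT_COLUMNS),
        threshold=-2.0,
        exclusion_window=4,
    )


class TestClimateNormalBaseline:
    def test_constant_npp_gives_constant_baseline(self):
        npp = make_annual_field(np.full((20, 1, 1), 500.0))
        z = make_annual_field(np.random.default_rng(0).normal(size=(20, 1, 1)))
        out = climate_normal_baseline(npp, z)
        assert out["baseline"].values[0, 0] == pytest.approx(500.0)

    def test_only_normal_years_enter_the_mean(self):
        z_vals = np.zeros((20, 1, 1))
        z_vals[:5] = -2.5  # drought years
        npp_vals = np.full((20, 1, 1), 500.0)
        npp_vals[:5] = 400.0
        out = climate_normal_baseline(
            make_annual_field(npp_vals), make_annual_field(z_vals)
        )
        assert out["baseline"].values[0, 0] == pytest.approx(500.0)
        assert out["n_normal_years"].values[0, 0] == 15

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        npp = rng.uniform(300, 700, (30, 3, 3))
        z = rng.normal(size=(30, 3, 3))
        out = climate_normal_baseline(
            make_annual_field(npp), make_annual_field(z), min_normal_years=1
        )
        for i in range(3):
            for j in range(3):
                sel = (z[:, i, j] >= -1) & (z[:, i, j] <= 1)
                assert out["baseline"].values[i, j] == pytest.approx(
                    npp[sel, i, j].mean(), abs=1e-12
                )

    def test_too_few_normal_years_masks_cell(self):
        z = make_annual_field(np.full((20, 1, 1), 3.0))  # never normal
        npp = make_annual_field(np.full((20, 1, 1), 500.0))
        out = climate_normal_baseline(npp, z, min_normal_years=5)
        assert np.isnan(out["baseline"].values[0, 0])


class TestAbsoluteTrajectory:
    def _baseline(self, value=500.0, shape=(1, 1)):
        arr = np.full(shape, value)
        da = xr.DataArray(arr, dims=("lat", "lon"),
                          coords={"lat": 40.25 + 0.5 * np.arange(shape[0]),
                                  "lon": -100.25 + 0.5 * np.arange(shape[1])})
        return xr.Dataset({"baseline": da, "n_normal_years": xr.zeros_like(da) + 10})

    def test_npp_at_baseline_after_drought_gives_zero_anomalies(self):
        npp_vals = np.full((20, 1, 1), 500.0)
        npp_vals[10] = 420.0  # drought year only
        traj = absolute_trajectory(
            make_annual_field(npp_vals), self._baseline(),
            make_catalog([(0, 0, 10, 10, False)]),
        )
        assert np.allclose(traj["anomaly"].values[:, 0, 0], [-80, 0, 0, 0, 0])

    def test_two_events_at_one_cell_average(self):
        npp_vals = np.full((30, 1, 1), 500.0)
        npp_vals[5] = 496.0   # anomaly -4
        npp_vals[20] = 498.0  # anomaly -2
        traj = absolute_trajectory(
            make_annual_field(npp_vals), self._baseline(),
            make_catalog([(0, 0, 5, 5, False), (0, 0, 20, 20, False)]),
        )
        assert traj["anomaly"].values[0, 0, 0] == pytest.approx(-3.0)
        assert traj["n_events"].values[0, 0] == 2

    def test_excluded_events_never_contribute(self):
        npp_vals = np.full((30, 1, 1), 500.0)
        npp_vals[5] = 100.0
        traj = absolute_trajectory(
            make_annual_field(npp_vals), self._baseline(),
            make_catalog([(0, 0, 5, 5, True), (0, 0, 20, 20, False)]),
        )
        assert traj["n_events"].values[0, 0] == 1
        assert traj["anomaly"].values[0, 0, 0] == pytest.approx(0.0)

    def test_truncated_window_reports_available_years_only(self):
        npp_vals = np.full((10, 1, 1), 500.0)
        traj = absolute_trajectory(
            make_annual_field(npp_vals), self._baseline(),
            make_catalog([(0, 0, 8, 8, False)]),
        )
        assert traj["n_avail"].values[:, 0, 0].tolist() == [1, 1, 0, 0, 0]


class TestRegression:
    def test_exact_line_recovered_and_selected(self):
        rng = np.random.default_rng(2)
        cwd = rng.normal(0, 10, (61, 1, 1))
        npp = 2.0 * cwd + 100.0
        out = fit_cwd_npp_regression(make_annual_field(npp), make_annual_field(cwd))
        assert out["slope"].values[0, 0] == pytest.approx(2.0)
        assert out["intercept"].values[0, 0] == pytest.approx(100.0)
        assert out["r"].values[0, 0] == pytest.approx(1.0)
        assert out["selected"].values[0, 0]

    def test_r_exactly_at_threshold_not_selected(self):
        # construct a series whose sample correlation with cwd is exactly 0.3
        rng = np.random.default_rng(3)
        x = rng.normal(size=61)
        e = rng.normal(size=61)
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        ec = e - e.mean() - (e - e.mean()) @ xc * xc
        ec /= np.linalg.norm(ec)
        y = 0.3 * xc + np.sqrt(1 - 0.3**2) * ec
        out = fit_cwd_npp_regression(
            make_annual_field(y.reshape(-1, 1, 1)), make_annual_field(x.reshape(-1, 1, 1))
        )
        r = out["r"].values[0, 0]
        assert r == pytest.approx(0.3, abs=1e-12)
        assert out["p_adj"].values[0, 0] < 0.05  # significant at n=61 ...
        assert not out["selected"].values[0, 0]  # ... but r > 0.3 is strict

    def test_independent_series_rarely_selected(self):
        rng = np.random.default_rng(4)
        npp = rng.normal(size=(61, 10, 10))
        cwd = rng.normal(size=(61, 10, 10))
        out = fit_cwd_npp_regression(make_annual_field(npp), make_annual_field(cwd))
        assert out["selected"].values.mean() < 0.05

    def test_zero_cwd_variance_masks_cell(self):
        npp = make_annual_field(np.random.default_rng(5).normal(size=(20, 1, 1)))
        cwd = make_annual_field(np.full((20, 1, 1), 3.0))
        out = fit_cwd_npp_regression(npp, cwd)
        assert np.isnan(out["slope"].values[0, 0])
        assert not out["selected"].values[0, 0]


class TestPercentTrajectory:
    def _selected_regression(self, slope, intercept, shape=(1, 1)):
        lat = 40.25 + 0.5 * np.arange(shape[0])
        lon = -100.25 + 0.5 * np.arange(shape[1])
        full = lambda v: xr.DataArray(np.full(shape, float(v)), dims=("lat", "lon"),
                                      coords={"lat": lat, "lon": lon})
        return xr.Dataset(
            {"slope": full(slope), "intercept": full(intercept),
             "r": full(0.9), "p_value": full(0.0), "p_adj": full(0.0),
             "selected": full(1).astype(bool)}
        )

    def test_npp_on_regression_line_gives_zero_percent(self):
        cwd = np.linspace(-50, 50, 20).reshape(-1, 1, 1)
        npp = 2.0 * cwd + 500.0
        traj = percent_trajectory(
            make_annual_field(npp), self._selected_regression(2.0, 500.0),
            make_annual_field(cwd), make_catalog([(0, 0, 10, 10, False)]),
        )
        assert np.allclose(traj["anomaly"].values[:, 0, 0], 0.0, atol=1e-10)

    def test_five_percent_below_prediction(self):
        cwd = np.zeros((20, 1, 1))
        npp = np.full((20, 1, 1), 100.0)
        npp[11] = 95.0  # post-drought year 1
        traj = percent_trajectory(
            make_annual_field(npp), self._selected_regression(0.0, 100.0),
            make_annual_field(cwd), make_catalog([(0, 0, 10, 10, False)]),
        )
        assert traj["anomaly"].values[1, 0, 0] == pytest.approx(-5.0)

    def test_nonpositive_prediction_masked_with_warning(self):
        cwd = np.zeros((20, 1, 1))
        npp = np.full((20, 1, 1), 100.0)
        with pytest.warns(UserWarning, match="non-positive"):
            traj = percent_trajectory(
                make_annual_field(npp), self._selected_regression(0.0, -5.0),
                make_annual_field(cwd), make_catalog([(0, 0, 10, 10, False)]),
            )
        assert np.isnan(traj["anomaly"].values[:, 0, 0]).all()
        assert traj.attrs["n_nonpositive_predictions"] == 5

    def test_unselected_cells_dropped(self):
        cwd = np.zeros((20, 1, 1))
        npp = np.full((20, 1, 1), 100.0)
        reg = self._selected_regression(0.0, 100.0)
        reg["selected"] = reg["selected"] & False
        traj = percent_trajectory(
            make_annual_field(npp), reg, make_annual_field(cwd),
            make_catalog([(0, 0, 10, 10, False)]),
        )
        assert traj["n_events"].values[0, 0] == 0


class TestStratifyByForest:
    def _forest(self, dominant, purity):
        dominant = np.asarray(dominant)
        purity = np.asarray(purity, dtype=float)
        ny, nx = dominant.shape
        lat = 40.25 + 0.5 * np.arange(ny)
        lon = -100.25 + 0.5 * np.arange(nx)
        frac = np.zeros((3, ny, nx))
        for c in range(3):
            frac[c] = np.where(dominant == c, purity, (1 - purity) / 2)
        return xr.Dataset(
            {
                "cover_fraction": (("forest_class", "lat", "lon"), frac),
                "dominant_class": (("lat", "lon"), dominant),
                "purity": (("lat", "lon"), purity),
            },
            coords={"forest_class": ["evergreen_needle", "broadleaf_deciduous", "mixed"],
                    "lat": lat, "lon": lon},
        )

    def _traj(self, ny, nx, seed=0):
        rng = np.random.default_rng(seed)
        lat = 40.25 + 0.5 * np.arange(ny)
        lon = -100.25 + 0.5 * np.arange(nx)
        return xr.Dataset(
            {
                "anomaly": (("lag_year", "lat", "lon"), rng.normal(size=(5, ny, nx))),
                "n_avail": (("lag_year", "lat", "lon"), np.ones((5, ny, nx), int)),
                "n_events": (("lat", "lon"), np.ones((ny, nx), int)),
            },
            coords={"lag_year": np.arange(5), "lat": lat, "lon": lon},
        )

    def test_uniform_class_is_identity(self):
        traj = self._traj(2, 2)
        forest = self._forest(np.zeros((2, 2), int), np.full((2, 2), 0.9))
        out = stratify_by_forest(traj, forest, "evergreen_needle")
        assert np.allclose(out["anomaly"].values, traj["anomaly"].values)

    def test_impossible_purity_gives_empty_result_not_error(self):
        traj = self._traj(2, 2)
        forest = self._forest(np.zeros((2, 2), int), np.full((2, 2), 0.9))
        out = stratify_by_forest(traj, forest, "evergreen_needle", min_purity=1.01)
        assert np.isnan(out["anomaly"].values).all()
        assert (out["n_events"].values == 0).all()

    def test_mixed_map_matches_manual_filter(self):
        rng = np.random.default_rng(6)
        dom = rng.integers(0, 3, (5, 10))
        pur = rng.uniform(0.4, 1.0, (5, 10))
        traj = self._traj(5, 10, seed=7)
        forest = self._forest(dom, pur)
        out = stratify_by_forest(traj, forest, "mixed", min_purity=0.6)
        keep = (dom == 2) & (pur >= 0.6)
        for i in range(5):
            for j in range(10):
                if keep[i, j]:
                    assert np.allclose(out["anomaly"].values[:, i, j],
                                       traj["anomaly"].values[:, i, j])
                else:
                    assert np.isnan(out["anomaly"].values[:, i, j]).all()


class TestRegionalIntegration:
    def test_papers_printed_pair_is_arithmetically_consistent(self):
        # uniform -75.7 gC m-2 over 7.266e12 m2 integrates to -0.55 PgC
        lat, lon = np.array([40.0, 41.0]), np.array([-100.0, -99.0])
        anom = xr.DataArray(np.full((2, 2), -75.7), dims=("lat", "lon"),
                            coords={"lat": lat, "lon": lon})
        areas = xr.DataArray(np.full((2, 2), 7.266e12 / 4), dims=("lat", "lon"),
                             coords={"lat": lat, "lon": lon})
        assert regional_integral(anom, areas) == pytest.approx(-0.55, abs=0.005)

    def test_zero_anomaly_integrates_to_zero(self):
        lat, lon = np.array([40.0]), np.array([-100.0])
        zero = xr.DataArray(np.zeros((1, 1)), dims=("lat", "lon"),
                            coords={"lat": lat, "lon": lon})
        areas = cell_areas(lat, lon, 0.5)
        assert regional_integral(zero, areas) == 0.0

    def test_equatorial_half_degree_cell_area_closed_form(self):
        area = cell_areas(np.array([0.0]), np.array([0.0]), 0.5).values[0, 0]
        expected = (
            EARTH_RADIUS_M**2
            * np.radians(0.5)
            * (np.sin(np.radians(0.25)) - np.sin(np.radians(-0.25)))
        )
        assert area == pytest.approx(expected, rel=1e-9)
        assert area == pytest.approx(3.091e9, rel=1e-3)

    def test_masked_cells_do_not_contribute(self):
        lat, lon = np.array([40.0, 41.0]), np.array([-100.0])
        anom = xr.DataArray(np.array([[100.0], [np.nan]]), dims=("lat", "lon"),
                            coords={"lat": lat, "lon": lon})
        areas = xr.DataArray(np.full((2, 1), 1e13), dims=("lat", "lon"),
                             coords={"lat": lat, "lon": lon})
        assert regional_integral(anom, areas) == pytest.approx(100.0 * 1e13 / 1e15)
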
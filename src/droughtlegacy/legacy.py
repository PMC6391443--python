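"""Drought response and recovery quantification.

Two baselines define the NPP anomaly of the drought year (year 0, the last
year of an extreme-drought run) and the four post-drought years:

* the climate-normal baseline — each cell's mean annual NPP over years with
  standardized CWD in [-1, 1] — giving absolute anomalies in gC m-2 yr-1;
* the regression baseline — per-cell OLS of annual NPP on annual CWD over
  the full record — giving percent departures of NPP from the value its
  climate relationship predicts. Only cells where that relationship is
  significant (FDR-adjusted) with r > 0.3 enter the percent analysis,
  mirroring the site-selection rule of tree-ring legacy studies.

Multiple events at one cell are averaged together, never across cells, so
trajectories preserve spatial heterogeneity until regional integration.
"""

from __future__ import annotations

import warnings

import numpy as np
import xarray as xr

from .drought import DroughtCatalog, normal_year_mask
from .lags import _pearson_p, fdr_adjust

EARTH_RADIUS_M = 6_371_000.0


def climate_normal_baseline(
    annual_npp: xr.DataArray,
    z: xr.DataArray,
    low: float = -1.0,
    high: float = 1.0,
    min_normal_years: int = 5,
) -> xr.Dataset:
    """Per-cell mean annual NPP over climate-normal years.

    Cells with fewer than ``min_normal_years`` normal years are masked: a
    baseline estimated from less data is noise, not a reference.
    """
    normal = normal_year_mask(z, low, high)
    npp = annual_npp.where(normal)
    n_normal = normal.sum("year")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        baseline = npp.mean("year", skipna=True)
    baseline = baseline.where(n_normal >= min_normal_years)
    return xr.Dataset(
        {"baseline": baseline, "n_normal_years": n_normal},
        attrs={"units": str(annual_npp.attrs.get("units", "")), "band": (low, high)},
    )


def _average_events(per_event, avail, cells, shape):
    """Average per-event 5-vectors within each cell; never across cells."""
    ny, nx = shape
    total = np.zeros((5, ny, nx))
    count = np.zeros((5, ny, nx), dtype=int)
    n_events = np.zeros((ny, nx), dtype=int)
    for vec, av, (i, j) in zip(per_event, avail, cells):
        n_events[i, j] += 1
        for k in range(5):
            if av[k]:
                total[k, i, j] += vec[k]
                count[k, i, j] += 1
    with np.errstate(invalid="ignore"):
        traj = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return traj, count, n_events


def absolute_trajectory(
    annual_npp: xr.DataArray,
    baseline: xr.Dataset,
    catalog: DroughtCatalog,
) -> xr.Dataset:
    """Recovery trajectories as NPP minus the climate-normal mean (gC m-2 yr-1).

    anomaly[k] = NPP(end_year + k) - baseline for k = 0..4, from
    non-excluded events only; years past the record end are unavailable
    (truncated events contribute their available years).
    """
    npp = np.asarray(annual_npp.values, dtype=float)
    base = np.asarray(baseline["baseline"].values, dtype=float)
    n_years = annual_npp.sizes["year"]
    ny, nx = base.shape
    per_event, avail, cells = [], [], []
    for row in catalog.active().itertuples():
        i, j, e = row.ilat, row.ilon, row.end_year
        if np.isnan(base[i, j]):
            continue
        vec = np.zeros(5)
        av = np.zeros(5, dtype=bool)
        for k in range(5):
            y = e + k
            if y < n_years and not np.isnan(npp[y, i, j]):
                vec[k] = npp[y, i, j] - base[i, j]
                av[k] = True
        per_event.append(vec)
        avail.append(av)
        cells.append((i, j))
    traj, count, n_events = _average_events(per_event, avail, cells, (ny, nx))
    return _traj_dataset(traj, count, n_events, annual_npp, units="gC m-2 yr-1")


def _traj_dataset(traj, count, n_events, ref: xr.DataArray, units: str) -> xr.Dataset:
    coords = {"lag_year": np.arange(5), "lat": ref["lat"], "lon": ref["lon"]}
    return xr.Dataset(
        {
            "anomaly": (("lag_year", "lat", "lon"), traj),
            "n_avail": (("lag_year", "lat", "lon"), count),
            "n_events": (("lat", "lon"), n_events),
        },
        coords=coords,
        attrs={"units": units},
    )


def fit_cwd_npp_regression(
    annual_npp: xr.DataArray,
    annual_cwd: xr.DataArray,
    alpha: float = 0.05,
    r_threshold: float = 0.3,
    cell_mask: xr.DataArray | None = None,
) -> xr.Dataset:
    """Per-cell OLS of annual NPP on annual CWD over the full record.

    ``selected`` cells have an FDR-adjusted significant correlation with
    r strictly greater than ``r_threshold``; only those carry a usable
    CWD-predicted baseline. Zero-CWD-variance cells are masked.
    """
    ny, nx = annual_npp.sizes["lat"], annual_npp.sizes["lon"]
    n = annual_npp.sizes["year"]
    X = np.asarray(annual_cwd.values, dtype=float).reshape(n, -1)
    Y = np.asarray(annual_npp.values, dtype=float).reshape(n, -1)
    valid = ~(np.isnan(X).any(axis=0) | np.isnan(Y).any(axis=0))
    if cell_mask is not None:
        valid &= np.asarray(cell_mask.values, dtype=bool).reshape(-1)
    xm = X - X.mean(axis=0)
    ym = Y - Y.mean(axis=0)
    sxx = (xm * xm).sum(axis=0)
    syy = (ym * ym).sum(axis=0)
    sxy = (xm * ym).sum(axis=0)
    valid &= sxx > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(valid, sxy / sxx, np.nan)
        r = np.where(valid & (syy > 0), sxy / np.sqrt(sxx * syy), np.nan)
    intercept = np.where(valid, Y.mean(axis=0) - slope * X.mean(axis=0), np.nan)
    p = np.full(r.shape, np.nan)
    ok = np.isfinite(r)
    p[ok] = _pearson_p(r[ok], n)
    p_adj = fdr_adjust(p)
    selected = np.where(np.isnan(p_adj), False, (p_adj < alpha) & (r > r_threshold))

    def grid(v, dtype=float):
        return (("lat", "lon"), np.asarray(v, dtype=dtype).reshape(ny, nx))

    return xr.Dataset(
        {
            "slope": grid(slope),
            "intercept": grid(intercept),
            "r": grid(r),
            "p_value": grid(p),
            "p_adj": grid(p_adj),
            "selected": grid(selected, bool),
        },
        coords={"lat": annual_npp["lat"], "lon": annual_npp["lon"]},
        attrs={"alpha": alpha, "r_threshold": r_threshold},
    )


def percent_trajectory(
    annual_npp: xr.DataArray,
    regression: xr.Dataset,
    annual_cwd: xr.DataArray,
    catalog: DroughtCatalog,
) -> xr.Dataset:
    """Recovery trajectories as percent departure from CWD-predicted NPP.

    anomaly[k] = 100 * (NPP(y_k) - NPPhat(y_k)) / NPPhat(y_k) with
    NPPhat = slope * CWD(y_k) + intercept, for selected cells and
    non-excluded events. Drought-year CWD is the event end-year's annual
    CWD. Cell-years with non-positive predicted NPP are masked (their count
    lands in attrs["n_nonpositive_predictions"]).
    """
    npp = np.asarray(annual_npp.values, dtype=float)
    cwd = np.asarray(annual_cwd.values, dtype=float)
    slope = np.asarray(regression["slope"].values)
    intercept = np.asarray(regression["intercept"].values)
    selected = np.asarray(regression["selected"].values, dtype=bool)
    n_years = annual_npp.sizes["year"]
    ny, nx = slope.shape
    per_event, avail, cells = [], [], []
    n_nonpos = 0
    for row in catalog.active().itertuples():
        i, j, e = row.ilat, row.ilon, row.end_year
        if not selected[i, j]:
            continue
        vec = np.zeros(5)
        av = np.zeros(5, dtype=bool)
        for k in range(5):
            y = e + k
            if y >= n_years or np.isnan(npp[y, i, j]) or np.isnan(cwd[y, i, j]):
                continue
            pred = slope[i, j] * cwd[y, i, j] + intercept[i, j]
            if pred <= 0:
                n_nonpos += 1
                continue
            vec[k] = 100.0 * (npp[y, i, j] - pred) / pred
            av[k] = True
        per_event.append(vec)
        avail.append(av)
        cells.append((i, j))
    traj, count, n_events = _average_events(per_event, avail, cells, (ny, nx))
    out = _traj_dataset(traj, count, n_events, annual_npp, units="percent")
    out.attrs["n_nonpositive_predictions"] = n_nonpos
    if n_nonpos:
        warnings.warn(f"{n_nonpos} cell-years had non-positive predicted NPP; masked")
    return out


def stratify_by_forest(
    trajectories: xr.Dataset,
    forest: xr.Dataset,
    forest_class: str | int,
    min_purity: float = 0.0,
) -> xr.Dataset:
    """Restrict trajectories to cells dominated by one forest class.

    A cell is retained when its dominant class matches and its purity (the
    dominant class's cover fraction) is at least ``min_purity``. An empty
    selection returns an all-masked dataset, not an error.
    """
    classes = [str(c) for c in np.asarray(forest["forest_class"].values)]
    code = classes.index(forest_class) if isinstance(forest_class, str) else int(forest_class)
    dom = np.asarray(forest["dominant_class"].values, dtype=int)
    purity = np.asarray(forest["purity"].values, dtype=float)
    keep = (dom == code) & (purity >= min_purity)
    mask = xr.DataArray(keep, dims=("lat", "lon"),
                        coords={"lat": trajectories["lat"], "lon": trajectories["lon"]})
    out = trajectories.copy()
    out["anomaly"] = trajectories["anomaly"].where(mask)
    out["n_events"] = trajectories["n_events"].where(mask, 0)
    out["n_avail"] = trajectories["n_avail"].where(mask, 0)
    out.attrs["forest_class"] = classes[code] if code < len(classes) else str(code)
    out.attrs["min_purity"] = min_purity
    return out


def cell_areas(lat: np.ndarray, lon: np.ndarray, cell_size: float | None = None) -> xr.DataArray:
    """Spherical areas (m^2) of regular lat/lon cells centered on the coords.

    area = R^2 * dlambda * (sin(phi2) - sin(phi1)) with R = 6,371,000 m,
    phi1/phi2 the cell's bounding latitudes.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if cell_size is None:
        cell_size = float(np.diff(lat)[0]) if lat.size > 1 else float(np.diff(lon)[0])
    half = cell_size / 2.0
    dlam = np.radians(cell_size)
    band = (
        EARTH_RADIUS_M**2
        * dlam
        * (np.sin(np.radians(lat + half)) - np.sin(np.radians(lat - half)))
    )
    area = np.broadcast_to(band[:, None], (lat.size, lon.size)).copy()
    return xr.DataArray(
        area, dims=("lat", "lon"), coords={"lat": lat, "lon": lon},
        attrs={"units": "m2"},
    )


def regional_integral(anomaly: xr.DataArray, areas: xr.DataArray) -> float:
    """Area-integrated anomaly in PgC yr-1 over unmasked cells.

    ``anomaly`` is a (lat, lon) field in gC m-2 yr-1.
    """
    total_g = np.nansum(np.asarray(anomaly.values) * np.asarray(areas.values))
    return float(total_g / 1e15)
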
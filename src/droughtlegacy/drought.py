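"""Climatic-water-deficit drought metrics on gridded monthly fields.

The drought index is CWD = precipitation - potential evapotranspiration
(mm month-1), totalled to calendar years and Z-scored per grid cell over the
full record. Extreme drought years are those with standardized annual
CWD <= -2; climate-normal years have -1 <= Z <= 1. Fields are xarray
DataArrays with dims (time, lat, lon) for monthly data and (year, lat, lon)
for annual data; invalid cells are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.spatial import cKDTree

# Analysis domain: contiguous US and Europe, inclusive bounds on cell centers.
DOMAIN_BOXES = (
    (25.0, 50.0, -125.0, -60.0),   # contiguous US
    (36.0, 70.0, -10.0, 36.0),     # Europe
)


def _check_aligned(a: xr.DataArray, b: xr.DataArray) -> None:
    for axis in ("time", "lat", "lon"):
        if axis in a.dims or axis in b.dims:
            if axis not in a.dims or axis not in b.dims:
                raise ValueError(f"alignment error on axis '{axis}': missing from one input")
            if a.sizes[axis] != b.sizes[axis] or not np.array_equal(
                np.asarray(a[axis]), np.asarray(b[axis])
            ):
                raise ValueError(f"alignment error on axis '{axis}': coordinates differ")


def compute_cwd(precip: xr.DataArray, pet: xr.DataArray) -> xr.DataArray:
    """Elementwise precipitation minus PET; NaN masks intersect.

    Both inputs must share grid and time axes and be in mm month-1.
    """
    _check_aligned(precip, pet)
    pu = precip.attrs.get("units")
    eu = pet.attrs.get("units")
    if pu and eu and pu != eu:
        raise ValueError(f"unit mismatch: precip in {pu}, pet in {eu}")
    cwd = precip - pet
    cwd.attrs["units"] = pu or eu or "mm month-1"
    cwd.attrs["long_name"] = "climatic water deficit (P - PET)"
    return cwd


def regrid_nearest(
    field: xr.DataArray,
    target_lat: np.ndarray,
    target_lon: np.ndarray,
    max_distance_factor: float = 1.5,
) -> xr.DataArray:
    """Nearest-neighbour regrid onto a regular lat/lon target grid.

    Each target cell takes the value of the source cell whose center is
    nearest by great-circle distance; values are replicated, never
    interpolated. Target cells farther from any source center than
    ``max_distance_factor`` times the source cell diagonal are masked and
    counted in the output attrs.
    """
    target_lat = np.asarray(target_lat, dtype=float)
    target_lon = np.asarray(target_lon, dtype=float)
    src_lat = np.asarray(field["lat"], dtype=float)
    src_lon = np.asarray(field["lon"], dtype=float)

    def unit_xyz(lat, lon):
        la, lo = np.radians(lat), np.radians(lon)
        return np.column_stack(
            [np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)]
        )

    sla, slo = np.meshgrid(src_lat, src_lon, indexing="ij")
    tla, tlo = np.meshgrid(target_lat, target_lon, indexing="ij")
    tree = cKDTree(unit_xyz(sla.ravel(), slo.ravel()))
    dist, idx = tree.query(unit_xyz(tla.ravel(), tlo.ravel()))

    # chord-length cutoff from the source grid spacing
    dlat = np.min(np.diff(src_lat)) if src_lat.size > 1 else 1.0
    dlon = np.min(np.diff(src_lon)) if src_lon.size > 1 else 1.0
    diag = np.radians(np.hypot(dlat, dlon))
    out_of_range = dist > max_distance_factor * diag

    values = np.asarray(field.values)
    spatial_shape = (target_lat.size, target_lon.size)
    if field.dims[-2:] != ("lat", "lon"):
        raise ValueError("expected trailing dims (lat, lon)")
    flat = values.reshape(values.shape[:-2] + (-1,))
    out = flat[..., idx]
    if out_of_range.any():
        out = out.astype(float)
        out[..., out_of_range] = np.nan
        warnings.warn(f"{int(out_of_range.sum())} target cells outside source coverage; masked")
    out = out.reshape(values.shape[:-2] + spatial_shape)

    coords = {d: field[d] for d in field.dims[:-2] if d in field.coords}
    coords["lat"] = target_lat
    coords["lon"] = target_lon
    result = xr.DataArray(out, dims=field.dims, coords=coords, attrs=dict(field.attrs))
    result.attrs["n_unmapped_cells"] = int(out_of_range.sum())
    return result


def annual_total(monthly: xr.DataArray) -> xr.DataArray:
    """Per-cell sum over each calendar year's 12 months.

    Requires whole calendar years; a cell-year containing any masked month
    is masked (conservative).
    """
    n = monthly.sizes["time"]
    if n % 12 != 0:
        raise ValueError(f"record length {n} months is not whole calendar years")
    years = n // 12
    vals = np.asarray(monthly.values, dtype=float)
    t_axis = monthly.dims.index("time")
    vals = np.moveaxis(vals, t_axis, 0)
    annual = vals.reshape((years, 12) + vals.shape[1:]).sum(axis=1)  # NaN propagates
    year_coord = _year_labels(monthly, years)
    dims = ("year",) + tuple(d for d in monthly.dims if d != "time")
    coords = {d: monthly[d] for d in dims if d in monthly.coords and d != "year"}
    coords["year"] = year_coord
    out = xr.DataArray(annual, dims=dims, coords=coords, attrs=dict(monthly.attrs))
    if "units" in monthly.attrs and "month-1" in str(monthly.attrs["units"]):
        out.attrs["units"] = str(monthly.attrs["units"]).replace("month-1", "yr-1")
    out.attrs["derivation"] = "sum of months"
    return out


def _year_labels(monthly: xr.DataArray, years: int) -> np.ndarray:
    time = monthly.coords.get("time")
    if time is not None and np.issubdtype(np.asarray(time).dtype, np.datetime64):
        return np.asarray(pd.DatetimeIndex(np.asarray(time)).year).reshape(years, 12)[:, 0]
    return np.arange(years)


def zscore(annual: xr.DataArray, ddof: int = 1) -> xr.DataArray:
    """Standardize an annual field per cell over the full record.

    Uses the sample standard deviation (ddof=1). Cells with zero variance
    (or fewer than two valid years) are masked; their count is recorded in
    ``attrs["n_degenerate_cells"]``. Per-cell mean/sd used are kept in
    ``attrs`` for provenance.
    """
    if annual.sizes["year"] < 2:
        raise ValueError("need at least 2 years to standardize")
    mean = annual.mean("year", skipna=False)
    sd = annual.std("year", ddof=ddof, skipna=False)
    # scale-relative floor: constant series whose yearly sums differ only by
    # float rounding are degenerate, not variable
    floor = 1e-12 * np.maximum(np.abs(mean), 1.0)
    nondegenerate = sd > floor
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z = xr.where(nondegenerate, (annual - mean) / sd, np.nan)
    z = z.transpose(*annual.dims)
    z.attrs["units"] = "1"
    z.attrs["long_name"] = "standardized annual " + str(annual.attrs.get("long_name", "field"))
    degenerate = (~np.asarray(nondegenerate.values)).sum()
    z.attrs["n_degenerate_cells"] = int(degenerate)
    return z


@dataclass
class DroughtCatalog:
    """Extreme-drought events per grid cell.

    ``events`` has one row per event with columns ilat, ilon, lat, lon,
    start_year, end_year (indices into the year axis), excluded,
    exclusion_reason and truncated (the 4 post-drought years run past the
    record end).
    """

    events: pd.DataFrame
    threshold: float
    exclusion_window: int

    def active(self) -> pd.DataFrame:
        """Events admissible for recovery analysis (not excluded)."""
        return self.events[~self.events["excluded"]]

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


_EVENT_COLUMNS = [
    "ilat", "ilon", "lat", "lon", "start_year", "end_year",
    "excluded", "exclusion_reason", "truncated",
]


def identify_drought_events(
    z: xr.DataArray, threshold: float = -2.0, exclusion_window: int = 4
) -> DroughtCatalog:
    """Find extreme-drought events (runs of years with Z <= threshold).

    Consecutive extreme years merge into one event anchored at its last
    year (the "drought year" from which recovery is measured). An event is
    excluded when another extreme year falls within `exclusion_window`
    years after its end, since the later drought's response would
    contaminate the recovery trajectory. Events whose post-drought window
    runs past the record end are kept but flagged truncated.
    """
    zv = np.asarray(z.values)
    n_years = z.sizes["year"]
    lats = np.asarray(z["lat"]) if "lat" in z.coords else np.arange(z.sizes["lat"])
    lons = np.asarray(z["lon"]) if "lon" in z.coords else np.arange(z.sizes["lon"])
    rows = []
    extreme = zv <= threshold  # NaN compares False
    for i in range(z.sizes["lat"]):
        for j in range(z.sizes["lon"]):
            col = extreme[:, i, j]
            if not col.any():
                continue
            # run boundaries
            padded = np.concatenate([[False], col, [False]])
            starts = np.flatnonzero(padded[1:] & ~padded[:-1])
            ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
            for s, e in zip(starts, ends):
                window = col[e + 1 : min(e + 1 + exclusion_window, n_years)]
                excluded = bool(window.any())
                reason = (
                    f"extreme drought within {exclusion_window} years after end_year"
                    if excluded
                    else ""
                )
                truncated = e + exclusion_window >= n_years
                rows.append((i, j, lats[i], lons[j], int(s), int(e), excluded, reason, truncated))
    events = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    if not events.empty:
        events = events.sort_values(["ilat", "ilon", "start_year"]).reset_index(drop=True)
    return DroughtCatalog(events=events, threshold=threshold, exclusion_window=exclusion_window)


def normal_year_mask(z: xr.DataArray, low: float = -1.0, high: float = 1.0) -> xr.DataArray:
    """Boolean field of climate-normal years: low <= Z <= high (closed)."""
    mask = (z >= low) & (z <= high)
    mask.attrs["long_name"] = f"climate-normal years ({low} <= Z <= {high})"
    return mask


def deseasonalize(monthly: xr.DataArray) -> xr.DataArray:
    """Remove each grid cell's calendar-month means over the full record."""
    n = monthly.sizes["time"]
    if n % 12 != 0:
        raise ValueError(f"record length {n} months is not whole calendar years")
    vals = np.asarray(monthly.values, dtype=float)
    t_axis = monthly.dims.index("time")
    vals = np.moveaxis(vals, t_axis, 0)
    shaped = vals.reshape((n // 12, 12) + vals.shape[1:])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        clim = np.nanmean(shaped, axis=0)
    anom = (shaped - clim[None]).reshape(vals.shape)
    anom = np.moveaxis(anom, 0, t_axis)
    out = monthly.copy(data=anom)
    out.attrs["long_name"] = "de-seasonalized " + str(monthly.attrs.get("long_name", "field"))
    return out


def domain_mask(
    lat: np.ndarray, lon: np.ndarray, boxes=DOMAIN_BOXES
) -> xr.DataArray:
    """Boolean (lat, lon) mask of cells whose centers fall in any box.

    Boxes are (lat_min, lat_max, lon_min, lon_max), inclusive.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    la, lo = np.meshgrid(lat, lon, indexing="ij")
    mask = np.zeros(la.shape, dtype=bool)
    for lat_min, lat_max, lon_min, lon_max in boxes:
        mask |= (la >= lat_min) & (la <= lat_max) & (lo >= lon_min) & (lo <= lon_max)
    return xr.DataArray(mask, dims=("lat", "lon"), coords={"lat": lat, "lon": lon})
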
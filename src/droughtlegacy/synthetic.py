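"""Seeded pseudo-model ensembles of climate and NPP grids with known truth.

The generator produces the statistical structure the downstream analysis is
built to detect — nothing more: monthly precipitation and PET with seasonal
cycles, occasional forced extreme-drought years, and an ensemble of monthly
NPP fields that respond linearly (with a configurable lag) to standardized
climatic-water-deficit anomalies, carry AR(1) noise, and suffer a
multiplicative post-drought legacy depression decaying over at most four
years. Because every response parameter is known and recorded, parameter
recovery by the full pipeline is an end-to-end correctness check.

The injected lag is applied as a circular shift of the standardized monthly
CWD anomaly over the (whole-year) record, so per-calendar-month means of the
lagged signal are exactly zero and the injected lag is exactly identifiable
from the noise-free fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .config import FOREST_CLASSES, SyntheticConfig
from .drought import annual_total, compute_cwd, deseasonalize, zscore

# Forcing aims slightly past the detection threshold so detection is not
# borderline at float precision.
_FORCING_TARGET_Z = -2.05


@dataclass
class TruthRecord:
    """Per-cell injected parameters, serialized alongside the data."""

    lag_months: np.ndarray            # (lat, lon) int
    sensitivity: np.ndarray           # (lat, lon) float, gC m-2 month-1 per z-unit
    legacy_profile: np.ndarray        # (lat, lon, 4) fractional depressions
    drought_year_depression: float
    forced_drought_years: tuple[int, ...]
    drought_years: list = field(default_factory=list)  # realized (ilat, ilon, year)

    def to_dict(self) -> dict:
        return {
            "lag_months": self.lag_months.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "legacy_profile": self.legacy_profile.tolist(),
            "drought_year_depression": self.drought_year_depression,
            "forced_drought_years": list(self.forced_drought_years),
            "drought_years": [list(t) for t in self.drought_years],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def _grid_coords(config: SyntheticConfig) -> dict:
    lat = config.lat_start + config.cell_size * np.arange(config.n_lat)
    lon = config.lon_start + config.cell_size * np.arange(config.n_lon)
    time = pd.date_range(
        f"{config.start_year}-01-01", periods=config.n_months, freq="MS"
    ).to_numpy()
    return {"time": time, "lat": lat, "lon": lon}


def _seasonal(n_months: int, mean: float, amplitude: float, phase: float = -np.pi / 2):
    m = np.arange(n_months)
    return mean + amplitude * np.sin(2 * np.pi * m / 12 + phase)


class ForcingError(ValueError):
    """A forced drought year cannot reach the target Z with non-negative precipitation."""


def generate_climate(config: SyntheticConfig) -> xr.Dataset:
    """Generate monthly precipitation, PET and temperature fields.

    Precipitation carries a sinusoidal seasonal cycle modulated by lognormal
    yearly and monthly multiplicative variation; PET is a deterministic
    seasonal cycle; temperature is seasonal plus white noise. Years listed
    in ``forced_drought_years`` have their precipitation scaled down
    (bisection, per cell) until the standardized annual CWD reaches
    Z <= -2.05, so downstream detection at Z <= -2 is never borderline.

    Deterministic under a fixed config/seed.
    """
    rng_climate, _ = _rngs(config)
    coords = _grid_coords(config)
    n, ny, nx = config.n_months, config.n_lat, config.n_lon
    years = config.years

    season = _seasonal(n, config.precip_mean, config.precip_seasonal_amplitude)
    if (season < 0).any():
        raise ValueError("precipitation seasonal cycle dips below zero; adjust mean/amplitude")

    annual_mult = np.ones((years, ny, nx))
    if config.precip_annual_cv > 0:
        annual_mult = rng_climate.lognormal(
            -0.5 * config.precip_annual_cv**2, config.precip_annual_cv, size=(years, ny, nx)
        )
    monthly_mult = np.ones((n, ny, nx))
    if config.precip_monthly_cv > 0:
        monthly_mult = rng_climate.lognormal(
            -0.5 * config.precip_monthly_cv**2, config.precip_monthly_cv, size=(n, ny, nx)
        )
    pr = season[:, None, None] * np.repeat(annual_mult, 12, axis=0) * monthly_mult

    pet_season = _seasonal(n, config.pet_mean, config.pet_seasonal_amplitude)
    if (pet_season < 0).any():
        raise ValueError("PET seasonal cycle dips below zero; adjust mean/amplitude")
    pet = np.broadcast_to(pet_season[:, None, None], (n, ny, nx)).copy()

    tas = (
        _seasonal(n, config.temp_mean, config.temp_seasonal_amplitude)[:, None, None]
        + rng_climate.normal(0, config.temp_noise_sd, size=(n, ny, nx))
    )

    if config.forced_drought_years:
        pr = _force_droughts(pr, pet, config)

    ds = xr.Dataset(
        {
            "pr": (("time", "lat", "lon"), pr, {"units": "mm month-1", "long_name": "precipitation"}),
            "pet": (("time", "lat", "lon"), pet, {"units": "mm month-1", "long_name": "potential evapotranspiration"}),
            "tas": (("time", "lat", "lon"), tas, {"units": "K", "long_name": "near-surface air temperature"}),
        },
        coords=coords,
    )
    return ds


def _force_droughts(pr: np.ndarray, pet: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Scale forced years' precipitation down until annual CWD Z <= -2.05.

    Bisection on a per-cell scale factor applied jointly to every forced
    year; Z of each forced year is monotone increasing in the factor.
    """
    n, ny, nx = pr.shape
    years = config.years
    forced = np.asarray(config.forced_drought_years, dtype=int)
    annual_pr = pr.reshape(years, 12, ny, nx).sum(axis=1).reshape(years, -1)
    annual_pet = pet.reshape(years, 12, ny, nx).sum(axis=1).reshape(years, -1)

    def max_forced_z(scale):  # scale: (cells,)
        x = annual_pr.copy()
        x[forced] *= scale[None, :]
        cwd = x - annual_pet
        mean = cwd.mean(axis=0)
        sd = cwd.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (cwd[forced] - mean[None]) / sd[None]
        return np.nanmax(z, axis=0)

    n_cells = ny * nx
    lo, hi = np.zeros(n_cells), np.ones(n_cells)
    z_at_zero = max_forced_z(lo)
    bad = ~(z_at_zero <= _FORCING_TARGET_Z)
    if bad.any():
        cell = int(np.flatnonzero(bad)[0])
        raise ForcingError(
            f"cannot force drought year(s) {forced.tolist()} to Z <= {_FORCING_TARGET_Z} "
            f"with non-negative precipitation (first failing cell {divmod(cell, nx)})"
        )
    already = max_forced_z(hi) <= _FORCING_TARGET_Z
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        ok = max_forced_z(mid) <= _FORCING_TARGET_Z
        lo = np.where(ok, mid, lo)
        hi = np.where(ok, hi, mid)
    scale = np.where(already, 1.0, lo).reshape(ny, nx)

    out = pr.reshape(years, 12, ny, nx).copy()
    out[forced] *= scale[None, None, :, :]
    return out.reshape(n, ny, nx)


def _rngs(config: SyntheticConfig):
    ss = np.random.SeedSequence(config.seed)
    climate_ss, noise_ss = ss.spawn(2)
    return np.random.default_rng(climate_ss), noise_ss


def standardized_cwd_anomaly(climate: xr.Dataset) -> xr.DataArray:
    """Monthly de-seasonalized CWD scaled to unit variance per cell.

    Standardization uses a single per-cell sd (not per calendar month), so
    the annual sum of the anomaly stays exactly collinear with annual CWD.
    Zero-variance cells get an identically-zero anomaly.
    """
    cwd = compute_cwd(climate["pr"], climate["pet"])
    anom = deseasonalize(cwd)
    sd = anom.std("time", ddof=1)
    chat = xr.where(sd > 0, anom / sd, 0.0).transpose(*anom.dims)
    chat.attrs["units"] = "1"
    return chat


def _realized_drought_years(climate: xr.Dataset, threshold: float = -2.0) -> np.ndarray:
    """Boolean (year, lat, lon): standardized annual CWD <= threshold."""
    z = zscore(annual_total(compute_cwd(climate["pr"], climate["pet"])))
    return np.asarray(z.values) <= threshold


def synthesize_npp(
    climate: xr.Dataset, config: SyntheticConfig
) -> tuple[xr.DataArray, TruthRecord]:
    """Generate the pseudo-model NPP ensemble from a climate realization.

    NPP(t) = seasonal(t) + sensitivity * c(t - lag) + AR(1) noise, where c is
    the standardized monthly CWD anomaly (circularly shifted by the lag),
    then multiplied by (1 - drought_year_depression) in extreme-drought
    years and by (1 - legacy_profile[k-1]) in post-drought year k (k = 1..4,
    counted from the last year of each drought run). NPP is floored at 0.
    Models share climate and response parameters; their AR(1) noise
    realizations differ by sub-seed.
    """
    _, noise_ss = _rngs(config)
    n, ny, nx = config.n_months, config.n_lat, config.n_lon
    years = config.years

    chat = np.asarray(standardized_cwd_anomaly(climate).values)
    lag = config.response_lag_months
    shifted = np.roll(chat, lag, axis=0)  # circular shift over the whole-year record
    season = _seasonal(n, config.npp_mean, config.seasonal_amplitude)
    signal = season[:, None, None] + config.cwd_sensitivity * shifted

    # yearly multiplicative drought / legacy factors
    extreme = _realized_drought_years(climate)  # (years, ny, nx)
    factor = np.ones((years, ny, nx))
    factor[extreme] *= 1.0 - config.drought_year_depression
    profile = np.asarray(config.legacy_profile)
    drought_year_list = []
    for i in range(ny):
        for j in range(nx):
            col = extreme[:, i, j]
            for y in np.flatnonzero(col):
                drought_year_list.append((i, j, int(y)))
            ends = np.flatnonzero(col & ~np.concatenate([col[1:], [False]]))
            for e in ends:
                for k in range(1, 5):
                    y = e + k
                    if y < years and not col[y]:
                        factor[y, i, j] *= 1.0 - profile[k - 1]
    factor_monthly = np.repeat(factor, 12, axis=0)

    phi, sd = config.ar1_coef, config.noise_sd
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    npp = np.empty((config.n_models, n, ny, nx))
    for m, child in enumerate(noise_ss.spawn(config.n_models)):
        rng = np.random.default_rng(child)
        noise = np.zeros((n, ny, nx))
        if sd > 0:
            eps = rng.normal(0, innov_sd, size=(n, ny, nx))
            noise[0] = rng.normal(0, sd, size=(ny, nx))
            for t in range(1, n):
                noise[t] = phi * noise[t - 1] + eps[t]
        npp[m] = np.maximum((signal + noise) * factor_monthly, 0.0)

    coords = {d: climate[d] for d in ("time", "lat", "lon")}
    coords["model"] = [f"pseudo{m:02d}" for m in range(config.n_models)]
    da = xr.DataArray(
        npp,
        dims=("model", "time", "lat", "lon"),
        coords=coords,
        attrs={"units": "gC m-2 month-1", "long_name": "net primary productivity"},
    )
    truth = TruthRecord(
        lag_months=np.full((ny, nx), lag, dtype=int),
        sensitivity=np.full((ny, nx), config.cwd_sensitivity),
        legacy_profile=np.broadcast_to(profile, (ny, nx, 4)).copy(),
        drought_year_depression=config.drought_year_depression,
        forced_drought_years=config.forced_drought_years,
        drought_years=drought_year_list,
    )
    return da, truth


def generate_forest_map(config: SyntheticConfig) -> xr.Dataset:
    """Round-robin fractional forest-cover map over the three forest classes.

    Cell k's dominant class is ``FOREST_CLASSES[k mod 3]`` with fractional
    cover ``forest_purity``; the remainder splits evenly between the other
    two classes.
    """
    ny, nx = config.n_lat, config.n_lon
    frac = np.empty((len(FOREST_CLASSES), ny, nx))
    rest = (1.0 - config.forest_purity) / (len(FOREST_CLASSES) - 1)
    flat_dom = np.arange(ny * nx) % len(FOREST_CLASSES)
    for c in range(len(FOREST_CLASSES)):
        frac[c] = np.where(flat_dom.reshape(ny, nx) == c, config.forest_purity, rest)
    coords = _grid_coords(config)
    ds = xr.Dataset(
        {
            "cover_fraction": (("forest_class", "lat", "lon"), frac),
            "dominant_class": (("lat", "lon"), flat_dom.reshape(ny, nx)),
            "purity": (("lat", "lon"), frac.max(axis=0)),
        },
        coords={
            "forest_class": list(FOREST_CLASSES),
            "lat": coords["lat"],
            "lon": coords["lon"],
        },
    )
    return ds


def generate_ensemble(config: SyntheticConfig):
    """Convenience wrapper: climate, NPP ensemble, forest map and truth."""
    climate = generate_climate(config)
    npp, truth = synthesize_npp(climate, config)
    forest = generate_forest_map(config)
    return climate, npp, forest, truth


def write_ensemble(path_dir, climate: xr.Dataset, npp: xr.DataArray, truth: TruthRecord) -> None:
    """Write CF-style NetCDF (scipy/NetCDF3 engine) plus a truth JSON sidecar."""
    import pathlib

    d = pathlib.Path(path_dir)
    d.mkdir(parents=True, exist_ok=True)
    climate.to_netcdf(d / "climate.nc", engine="scipy")
    npp.to_dataset(name="npp").to_netcdf(d / "npp.nc", engine="scipy")
    truth.to_json(d / "truth.json")
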
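import numpy as np
import pytest

from droughtlegacy import (
    SyntheticConfig,
    annual_total,
    compute_cwd,
    generate_ensemble,
    identify_drought_events,
    zscore,
)


@pytest.fixture(scope="session")
def small_run():
    """A small default-parameter ensemble shared across read-only tests."""
    cfg = SyntheticConfig(n_lat=6, n_lon=6, n_models=2, seed=7)
    climate, npp, forest, truth = generate_ensemble(cfg)
    return cfg, climate, npp, forest, truth


@pytest.fixture(scope="session")
def small_drought_fields(small_run):
    """Annual CWD, its Z-scores and the drought catalog for the small run."""
    _, climate, _, _, _ = small_run
    annual_cwd = annual_total(compute_cwd(climate["pr"], climate["pet"]))
    z = zscore(annual_cwd)
    catalog = identify_drought_events(z)
    return annual_cwd, z, catalog


def make_monthly_field(values, lat=None, lon=None):
    """Wrap a (time, lat, lon) array as the DataArray the package expects."""
    import pandas as pd
    import xarray as xr

    values = np.asarray(values, dtype=float)
    nt, ny, nx = values.shape
    lat = np.asarray(lat if lat is not None else 40.25 + 0.5 * np.arange(ny), dtype=float)
    lon = np.asarray(lon if lon is not None else -100.25 + 0.5 * np.arange(nx), dtype=float)
    time = pd.date_range("1948-01-01", periods=nt, freq="MS").to_numpy()
    return xr.DataArray(
        values, dims=("time", "lat", "lon"),
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={"units": "mm month-1"},
    )


def make_annual_field(values, lat=None, lon=None, units="gC m-2 yr-1"):
    import xarray as xr

    values = np.asarray(values, dtype=float)
    ny_, ny, nx = values.shape
    lat = np.asarray(lat if lat is not None else 40.25 + 0.5 * np.arange(ny), dtype=float)
    lon = np.asarray(lon if lon is not None else -100.25 + 0.5 * np.arange(nx), dtype=float)
    return xr.DataArray(
        values, dims=("year", "lat", "lon"),
        coords={"year": np.arange(ny_), "lat": lat, "lon": lon},
        attrs={"units": units},
    )
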
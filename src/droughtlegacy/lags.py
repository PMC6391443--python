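"""Lag-time mapping between monthly climate and NPP anomalies.

For each grid cell, NPP anomalies are correlated with CWD anomalies at
offsets of 0 to ``max_lag`` months (61 correlations at the default): at lag
k, NPP starting in month k+1 is paired with CWD starting in month 1, so the
overlap shrinks with the lag and there is no padding or wrap-around. The
optimum lag is the offset of the maximum signed correlation (drought lowers
both CWD and NPP, so the physically meaningful maxima are positive).
Significance of per-cell maxima is controlled with Benjamini-Hochberg FDR
across the map, one family per model.

Caveat: the p-value attached to a lag-optimized maximum is the nominal
p-value of that single correlation and ignores the selection over 61 lags,
so it is optimistic; it is reported this way because the mapping convention
treats the lag search as identification, not inference.
"""

from __future__ import annotations

import numpy as np
import xarray as xr
from scipy import stats
from statsmodels.stats.multitest import multipletests

LAG_BIN_LABELS = ("0", "1", "2", "3-6", "7-12", "13-24", ">24")
_LAG_BIN_EDGES = (1, 2, 3, 7, 13, 25)  # right-open starts of bins 1..6


def lagged_correlations(
    npp_anom: np.ndarray, cwd_anom: np.ndarray, max_lag: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p at offsets 0..max_lag for two 1-D series.

    r[k] correlates npp[k:] with cwd[:n-k]. Offsets with a zero-variance
    overlap yield NaN.
    """
    x = np.asarray(npp_anom, dtype=float)
    y = np.asarray(cwd_anom, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("need two equal-length 1-D series")
    n = x.size
    if n <= max_lag + 2:
        raise ValueError(f"series of length {n} too short for max_lag={max_lag}")
    r = np.full(max_lag + 1, np.nan)
    p = np.full(max_lag + 1, np.nan)
    for k in range(max_lag + 1):
        a, b = x[k:], y[: n - k]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0 or np.isnan(sa) or np.isnan(sb):
            continue
        rk = float(np.corrcoef(a, b)[0, 1])
        r[k] = rk
        p[k] = _pearson_p(rk, a.size)
    return r, p


def _pearson_p(r, n):
    """Two-sided p of a Pearson correlation via the t distribution (df = n-2)."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def optimal_lag(r_vector: np.ndarray) -> tuple[float, int]:
    """Maximum signed correlation and its offset; ties break to the smallest lag.

    Returns (nan, -1) when every offset is undefined.
    """
    r = np.asarray(r_vector, dtype=float)
    if np.all(np.isnan(r)):
        return float("nan"), -1
    k = int(np.nanargmax(r))  # first occurrence wins ties
    return float(r[k]), k


def lag_correlation_map(
    npp_anom: xr.DataArray,
    cwd_anom: xr.DataArray,
    max_lag: int = 60,
    alpha: float = 0.05,
    cell_mask: xr.DataArray | None = None,
) -> xr.Dataset:
    """Per-cell optimal lag, maximum r and FDR-adjusted significance.

    Inputs are de-seasonalized monthly (time, lat, lon) fields. The BH
    adjustment treats all valid cells of the map as one family. Cells
    outside ``cell_mask`` (or with undefined correlations) are NaN.
    """
    if npp_anom.sizes != cwd_anom.sizes:
        raise ValueError("npp and cwd fields must share shape")
    nt = npp_anom.sizes["time"]
    if nt <= max_lag + 2:
        raise ValueError(f"series of length {nt} too short for max_lag={max_lag}")
    ny, nx = npp_anom.sizes["lat"], npp_anom.sizes["lon"]
    X = np.asarray(npp_anom.values, dtype=float).reshape(nt, -1)
    Y = np.asarray(cwd_anom.values, dtype=float).reshape(nt, -1)
    valid = ~(np.isnan(X).any(axis=0) | np.isnan(Y).any(axis=0))
    if cell_mask is not None:
        valid &= np.asarray(cell_mask.values, dtype=bool).reshape(-1)

    r_all = np.full((max_lag + 1, X.shape[1]), np.nan)
    for k in range(max_lag + 1):
        a, b = X[k:], Y[: nt - k]
        am = a - a.mean(axis=0)
        bm = b - b.mean(axis=0)
        sa = np.sqrt((am * am).sum(axis=0))
        sb = np.sqrt((bm * bm).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rk = (am * bm).sum(axis=0) / (sa * sb)
        rk[(sa == 0) | (sb == 0)] = np.nan
        r_all[k] = rk
    r_all[:, ~valid] = np.nan

    defined = ~np.all(np.isnan(r_all), axis=0)
    lag_opt = np.full(X.shape[1], np.nan)
    r_max = np.full(X.shape[1], np.nan)
    with np.errstate(invalid="ignore"):
        lag_idx = np.nanargmax(np.where(np.isnan(r_all), -np.inf, r_all), axis=0)
    lag_opt[defined] = lag_idx[defined]
    r_max[defined] = r_all[lag_idx[defined], np.flatnonzero(defined)]
    n_eff = nt - lag_opt
    p = np.full(X.shape[1], np.nan)
    p[defined] = _pearson_p(r_max[defined], n_eff[defined])

    p_adj = fdr_adjust(p)
    significant = np.where(np.isnan(p_adj), False, p_adj < alpha)

    def grid(v, dtype=float):
        return (("lat", "lon"), np.asarray(v, dtype=dtype).reshape(ny, nx))

    coords = {"lat": npp_anom["lat"], "lon": npp_anom["lon"]}
    return xr.Dataset(
        {
            "r_max": grid(r_max),
            "lag_opt": grid(lag_opt),
            "p_value": grid(p),
            "p_adj": grid(p_adj),
            "significant": grid(significant, bool),
        },
        coords=coords,
        attrs={"max_lag": max_lag, "alpha": alpha},
    )


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    ok = np.isfinite(flat)
    if ok.any():
        adj = multipletests(flat[ok], method="fdr_bh")[1]
        out_flat = out.ravel()
        out_flat[ok] = adj
        out = out_flat.reshape(p.shape)
    return out


def ensemble_lag_map(results: list[xr.Dataset]) -> xr.Dataset:
    """Average r_max and lag_opt across models, per cell, where significant.

    A cell with no significant model is masked; ``n_contrib`` records how
    many models entered each cell's mean.
    """
    if not results:
        raise ValueError("no model results supplied")
    sig = np.stack([np.asarray(d["significant"].values, dtype=bool) for d in results])
    r = np.stack([np.asarray(d["r_max"].values, dtype=float) for d in results])
    lag = np.stack([np.asarray(d["lag_opt"].values, dtype=float) for d in results])
    n_contrib = sig.sum(axis=0)
    with np.errstate(invalid="ignore"):
        r_mean = np.where(n_contrib > 0, np.where(sig, r, 0.0).sum(axis=0) / np.maximum(n_contrib, 1), np.nan)
        lag_mean = np.where(n_contrib > 0, np.where(sig, lag, 0.0).sum(axis=0) / np.maximum(n_contrib, 1), np.nan)
    coords = {"lat": results[0]["lat"], "lon": results[0]["lon"]}
    return xr.Dataset(
        {
            "r_max_mean": (("lat", "lon"), r_mean),
            "lag_mean": (("lat", "lon"), lag_mean),
            "n_contrib": (("lat", "lon"), n_contrib),
        },
        coords=coords,
    )


def bin_lags(lag_map: xr.DataArray | np.ndarray) -> xr.DataArray:
    """Bin lag values (months) into {0, 1, 2, 3-6, 7-12, 13-24, >24}.

    Returns integer bin indices into :data:`LAG_BIN_LABELS`; NaN lags map
    to -1.
    """
    values = np.asarray(lag_map.values if isinstance(lag_map, xr.DataArray) else lag_map, dtype=float)
    idx = np.digitize(values, _LAG_BIN_EDGES)
    idx = np.where(np.isnan(values), -1, idx).astype(int)
    if isinstance(lag_map, xr.DataArray):
        out = lag_map.copy(data=idx)
        out.attrs["bin_labels"] = list(LAG_BIN_LABELS)
        return out
    return xr.DataArray(idx, attrs={"bin_labels": list(LAG_BIN_LABELS)})


def dominant_driver(
    npp_anom: xr.DataArray,
    precip_anom: xr.DataArray,
    temp_anom: xr.DataArray,
    max_lag: int = 60,
    alpha: float = 0.05,
    cell_mask: xr.DataArray | None = None,
) -> xr.Dataset:
    """Dominant climate driver (P or T) of NPP per cell.

    Both drivers get the same lag-optimized correlation treatment (0 to
    ``max_lag`` months, FDR per driver map); the dominant driver is the one
    with the larger |r_max| among the significant ones. Cells where neither
    driver is significant are masked (driver code -1).
    """
    res_p = lag_correlation_map(npp_anom, precip_anom, max_lag, alpha, cell_mask)
    res_t = lag_correlation_map(npp_anom, temp_anom, max_lag, alpha, cell_mask)
    rp = np.asarray(res_p["r_max"].values)
    rt = np.asarray(res_t["r_max"].values)
    sp = np.asarray(res_p["significant"].values, dtype=bool)
    st = np.asarray(res_t["significant"].values, dtype=bool)
    ap = np.where(sp, np.abs(rp), -np.inf)
    at = np.where(st, np.abs(rt), -np.inf)
    driver = np.full(rp.shape, -1, dtype=int)  # 0 = P, 1 = T, -1 = masked
    driver[(ap >= at) & sp] = 0
    driver[(at > ap) & st] = 1
    r_best = np.where(driver == 0, rp, np.where(driver == 1, rt, np.nan))
    return xr.Dataset(
        {
            "driver": (("lat", "lon"), driver),
            "r": (("lat", "lon"), r_best),
        },
        coords={"lat": npp_anom["lat"], "lon": npp_anom["lon"]},
        attrs={"driver_codes": "0=P, 1=T, -1=masked"},
    )
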
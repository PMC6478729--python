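"""Annual percentile metrics of intra-annual vegetation-index series.

The wet-season state of the vegetation is summarised by the 90th percentile
(p90) of the year's observations and the dry-season state by the 30th
percentile (p30; the 10th for low-frequency L-band VOD, whose weak
sensitivity to the herbaceous layer pushes p30 into the wet season). For
near-daily L-band VOD a pre-step aggregates to 10-day medians followed by a
locally weighted second-order polynomial smoother.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["annual_percentile", "annual_metrics", "site_average",
           "smooth_lvod", "local_quadratic_smooth", "AnnualPercentileMetrics"]

MIN_OBS_PER_YEAR = 8


@dataclass
class AnnualPercentileMetrics:
    site_or_pixel: str
    year: int
    p90: float
    p_dry: float
    dry_percentile_used: int
    n_obs: int


def annual_percentile(values, q: float, min_obs: int = MIN_OBS_PER_YEAR) -> float:
    """q-th percentile with linear interpolation between order statistics.

    Returns NaN (with a warning) when fewer than ``min_obs`` finite
    observations are available: percentiles of sparse years are unstable.
    """
    if not (0.0 < q <= 100.0):
        raise ValueError("q must lie in (0, 100]")
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_obs:
        warnings.warn(f"only {arr.size} observations (< {min_obs}); "
                      "metric set to missing", stacklevel=2)
        return float("nan")
    return float(np.percentile(arr, q))


def annual_metrics(series: pd.DataFrame, dry_percentile: int = 30,
                   min_obs: int = MIN_OBS_PER_YEAR) -> pd.DataFrame:
    """Per (site, year) p90 and dry-season percentile.

    ``series`` is a long table with columns site, year, value (one row per
    observation). ``dry_percentile`` is 30 for optical/high-frequency VOD
    and 10 for L-band VOD (explicit, never inferred from the data).
    """
    if dry_percentile not in (30, 10):
        raise ValueError("dry_percentile must be 30 or 10")
    rows = []
    for (site, year), grp in series.groupby(["site", "year"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p90 = annual_percentile(vals, 90, min_obs)
            p_dry = annual_percentile(vals, dry_percentile, min_obs)
        if np.isnan(p90):
            warnings.warn(f"{site}/{year}: too few observations", stacklevel=2)
        rows.append({"site": site, "year": int(year), "p90": p90,
                     "p_dry": p_dry, "n_obs": len(vals)})
    return pd.DataFrame(rows)


def site_average(metrics: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of the metrics across sites, per year.

    Sites with missing metrics are excluded year by year; the number of
    contributing sites is reported as ``n_sites``.
    """
    out = (metrics.groupby("year")
           .agg(p90=("p90", "mean"), p_dry=("p_dry", "mean"),
                n_sites=("p90", lambda s: int(s.notna().sum())))
           .reset_index())
    return out


# ---------------------------------------------------------------------------
# L-VOD smoothing pre-step
# ---------------------------------------------------------------------------

def local_quadratic_smooth(t: np.ndarray, y: np.ndarray, span: int = 5
                           ) -> np.ndarray:
    """Locally weighted 2nd-order polynomial smoother (tricube weights).

    For each point, a quadratic is fitted by weighted least squares to the
    ``span`` nearest points and evaluated there. Exact on quadratic input.
    NaNs are ignored in the fits and propagated where no local fit is
    possible.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    span = max(3, min(span, n))
    out = np.full(n, np.nan)
    finite = np.isfinite(y)
    for i in range(n):
        d = np.abs(t - t[i])
        order = np.argsort(d, kind="stable")
        sel = order[finite[order]][:span]
        if len(sel) < 3:
            continue
        dmax = np.max(np.abs(t[sel] - t[i]))
        if dmax == 0:
            out[i] = float(np.mean(y[sel]))
            continue
        u = np.abs(t[sel] - t[i]) / (dmax * 1.0001)
        w = (1 - u ** 3) ** 3
        X = np.vander(t[sel] - t[i], 3, increasing=True)  # [1, dt, dt^2]
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], y[sel] * W, rcond=None)
        out[i] = float(coef[0])
    return out


def smooth_lvod(series: pd.DataFrame, block_days: int = 10, span: int = 5
                ) -> pd.DataFrame:
    """Aggregate near-daily observations to 10-day medians, then apply the
    local weighted quadratic smoother.

    ``series`` is a long table with columns site, year, date, value at daily
    or near-daily cadence. Returns the same schema at ``block_days``
    cadence (timestamps at block centres). All-missing blocks stay missing.
    """
    frames = []
    for (site, year), grp in series.groupby(["site", "year"], sort=True):
        grp = grp.sort_values("date")
        dates = pd.to_datetime(grp["date"])
        doy0 = dates.dt.dayofyear.to_numpy() - 1
        block = doy0 // block_days
        med = (pd.DataFrame({"block": block, "value": grp["value"].to_numpy()})
               .groupby("block")["value"].median())
        centres = med.index.to_numpy() * block_days + (block_days - 1) / 2.0
        smoothed = local_quadratic_smooth(centres, med.to_numpy(), span=span)
        base = pd.Timestamp(year=int(year), month=1, day=1)
        out_dates = base + pd.to_timedelta(centres, unit="D")
        frames.append(pd.DataFrame({"site": site, "year": int(year),
                                    "date": out_dates, "value": smoothed}))
    return pd.concat(frames, ignore_index=True)
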
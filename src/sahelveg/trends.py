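"""Linear trends, z-scores, slope comparison, and dominant-harmonic fits.

Annual series (biomass, rainfall components, satellite metrics) are
characterised by: OLS trends against calendar year with a two-sided t test
on the slope; z-score standardisation for cross-variable comparison;
a pooled-regression test for equality of two slopes; and a single dominant
sinusoid ("1st harmonic") fitted to the linearly detrended series, whose
significance is assessed by permutation of years. The dominant harmonic is
the Fourier frequency with maximum periodogram power (not the record-length
fundamental): a ~5-year cycle in a 30-year record is the k = 6 component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TrendResult", "HarmonicFit", "ZScoreSeries", "SlopeComparison",
           "zscore", "ols_trend", "compare_slopes", "fit_first_harmonic",
           "pixelwise_harmonic_correlation"]


@dataclass(frozen=True)
class TrendResult:
    slope: float        # units per year
    intercept: float
    p_value: float      # two-sided t test on the slope
    se_slope: float
    n: int


@dataclass(frozen=True)
class ZScoreSeries:
    values: np.ndarray
    source_mean: float
    source_sd: float    # sample (n-1) standard deviation


@dataclass(frozen=True)
class SlopeComparison:
    slope_a: float
    slope_b: float
    diff: float         # slope_b - slope_a
    p_value: float


@dataclass(frozen=True)
class HarmonicFit:
    period: float       # years
    amplitude: float
    phase: float        # radians; fit is A*sin(2*pi*t/period + phase)
    mean_level: float
    p_value: float      # permutation significance of the dominant harmonic
    r_fit: float        # Pearson r between fitted sinusoid and detrended series


def zscore(values) -> ZScoreSeries:
    """Standardise to zero mean, unit sample standard deviation."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("need at least two values")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        raise ValueError("constant series has no z-score")
    mean = float(np.mean(arr))
    return ZScoreSeries(values=(np.asarray(values, dtype=float) - mean) / sd,
                        source_mean=mean, source_sd=sd)


def ols_trend(values, years) -> TrendResult:
    """OLS of an annual series on calendar year."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(years, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need at least three non-missing years")
    res = stats.linregress(x, y)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else (
        1.0 if res.slope == 0 else 0.0)
    return TrendResult(slope=float(res.slope), intercept=float(res.intercept),
                       p_value=p, se_slope=float(res.stderr), n=len(y))


def compare_slopes(series_a, series_b, years) -> SlopeComparison:
    """Test whether two annual series have equal linear slopes.

    Pooled regression with a group indicator and year-by-group interaction;
    the interaction coefficient is the slope difference (b minus a) and its
    two-sided t test gives the p value.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    x = np.asarray(years, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(x)
    a, b, x = a[ok], b[ok], x[ok]
    if len(x) < 3:
        raise ValueError("need at least three common years")
    import statsmodels.api as sm

    xc = x - x.mean()
    y = np.concatenate([a, b])
    g = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    t = np.concatenate([xc, xc])
    X = sm.add_constant(np.column_stack([t, g, t * g]))
    fit = sm.OLS(y, X).fit()
    diff = float(fit.params[3])
    p = float(fit.pvalues[3])
    scale = max(1.0, float(np.sum(y ** 2)))
    if not np.isfinite(p) or fit.ssr < 1e-12 * scale:
        # perfect fit: no residual variance to test against
        p = 1.0 if abs(diff) < 1e-9 * max(1.0, abs(y).max()) else 0.0
    slope_a = ols_trend(a, x).slope
    slope_b = ols_trend(b, x).slope
    return SlopeComparison(slope_a=slope_a, slope_b=slope_b, diff=diff,
                           p_value=p)


# ---------------------------------------------------------------------------
# dominant-harmonic ("1st sinusoidal term") analysis
# ---------------------------------------------------------------------------

def _detrend(y: np.ndarray) -> np.ndarray:
    t = np.arange(len(y), dtype=float)
    res = stats.linregress(t, y)
    return y - (res.slope * t + res.intercept)


def _max_power(detrended: np.ndarray) -> tuple[int, float]:
    """Dominant non-zero Fourier frequency index and its power."""
    spec = np.fft.rfft(detrended)
    power = np.abs(spec[1:]) ** 2          # drop the zero frequency
    k = int(np.argmax(power)) + 1
    return k, float(power[k - 1])


def fit_first_harmonic(values, n_permutations: int = 1000,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None
                       ) -> HarmonicFit:
    """Fit the dominant sinusoid of a linearly detrended annual series.

    The periodogram of the detrended series is evaluated at the Fourier
    frequencies k = 1 .. n/2; the maximum-power component sets the period
    (n/k years). Amplitude and phase come from a least-squares sin/cos fit
    at that frequency. Significance: the maximum periodogram power is
    compared with its distribution under random permutation of years
    (add-one permutation p value, seeded and reproducible).
    """
    y = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("series must be complete (no missing years)")
    n = len(y)
    if n < 10:
        raise ValueError("need at least ten years")
    if np.ptp(y) == 0:
        raise ValueError("constant series has no harmonic")
    detr = _detrend(y)
    k, obs_power = _max_power(detr)
    period = n / k
    t = np.arange(n, dtype=float)
    w = 2.0 * np.pi * t / period
    X = np.column_stack([np.sin(w), np.cos(w)])
    coef, *_ = np.linalg.lstsq(X, detr, rcond=None)
    bs, bc = float(coef[0]), float(coef[1])
    amplitude = float(np.hypot(bs, bc))
    phase = float(np.arctan2(bc, bs))      # A*sin(w + phase)
    fitted = X @ coef
    r_fit = (float(stats.pearsonr(fitted, detr).statistic)
             if np.ptp(fitted) > 0 else float("nan"))

    if n_permutations > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(detr, (n_permutations, 1)), axis=1)
        spec = np.fft.rfft(perms, axis=1)
        null_max = np.max(np.abs(spec[:, 1:]) ** 2, axis=1)
        p = (1.0 + np.count_nonzero(null_max >= obs_power)) / (n_permutations + 1.0)
    else:
        p = float("nan")
    return HarmonicFit(period=float(period), amplitude=amplitude, phase=phase,
                       mean_level=float(np.mean(y)), p_value=float(p),
                       r_fit=r_fit)


def pixelwise_harmonic_correlation(cube: np.ndarray) -> np.ndarray:
    """Per-pixel Pearson r between an annual series and its fitted dominant
    sinusoid.

    ``cube`` has shape (years, ny, nx); pixels with any missing year (or a
    constant series) propagate NaN. No significance is computed here.
    """
    cube = np.asarray(cube, dtype=float)
    ny, nx = cube.shape[1], cube.shape[2]
    out = np.full((ny, nx), np.nan)
    for i in range(ny):
        for j in range(nx):
            y = cube[:, i, j]
            if np.any(~np.isfinite(y)) or np.ptp(y) == 0:
                continue
            fit = fit_first_harmonic(y, n_permutations=0)
            out[i, j] = fit.r_fit
    return out
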
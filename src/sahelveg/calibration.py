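"""Calibration of satellite percentile metrics to field biomass and the
woody/herbaceous partition.

Two independent linear regressions are fitted on site-averaged annual
values: total green mass (AGH + WPF) on the wet-season metric (p90) and
woody foliage mass (WPF) on the dry-season metric (p30/p10). Applying the
two models to any metric pair and subtracting,

    total = p90 * slope_t + offset_t
    wpf   = p_dry * slope_w + offset_w
    agh   = total - wpf            (floored at zero)

partitions total green mass into its herbaceous and woody-foliage
components. The partition rests on contrasting phenology: woody plants keep
green foliage into the dry season, annual herbaceous plants do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CalibrationModel", "fit_calibration", "apply_calibration",
           "partition", "evaluate"]


@dataclass(frozen=True)
class CalibrationModel:
    """Linear field <-> satellite relation with fit diagnostics."""

    target: str          # "total_mass" or "wpf"
    slope: float         # kg/ha per index unit
    offset: float        # kg/ha
    r: float             # Pearson correlation of the calibration pairs
    rmse: float          # kg/ha, root mean squared residual
    n: int               # years used

    def predict(self, metric):
        return np.asarray(metric, dtype=float) * self.slope + self.offset


def fit_calibration(metric: pd.Series, field: pd.Series,
                    target: str = "total_mass") -> CalibrationModel:
    """OLS of annual field mass on the annual satellite metric.

    ``metric`` and ``field`` are year-indexed; pairing is on the index and
    requires at least three complete pairs.
    """
    if target not in ("total_mass", "wpf"):
        raise ValueError("target must be 'total_mass' or 'wpf'")
    df = pd.concat({"metric": metric, "field": field}, axis=1, join="inner")
    df = df.dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 paired years, got {len(df)}")
    x = df["metric"].to_numpy(dtype=float)
    y = df["field"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("metric has zero variance; cannot calibrate")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return CalibrationModel(target=target, slope=float(res.slope),
                            offset=float(res.intercept), r=float(res.rvalue),
                            rmse=float(np.sqrt(np.mean(resid ** 2))),
                            n=len(df))


def apply_calibration(model: CalibrationModel, metric) -> pd.Series:
    """Estimated mass (kg/ha) per year/pixel; negatives floored at zero."""
    pred = model.predict(np.asarray(metric, dtype=float))
    pred = np.maximum(pred, 0.0)
    if isinstance(metric, pd.Series):
        return pd.Series(pred, index=metric.index)
    return pd.Series(pred)


def partition(total_hat: pd.Series, wpf_hat: pd.Series) -> pd.DataFrame:
    """AGH = total - WPF, floored at zero with a ``clamped`` flag."""
    df = pd.concat({"total_hat": total_hat, "wpf_hat": wpf_hat},
                   axis=1, join="inner")
    agh = df["total_hat"] - df["wpf_hat"]
    clamped = agh < 0
    df["agh_hat"] = agh.clip(lower=0.0)
    df["clamped"] = clamped
    return df


def evaluate(estimate: pd.Series, field: pd.Series) -> dict:
    """Pearson r, RMSE and mean bias (estimate - field) over paired years."""
    df = pd.concat({"est": estimate, "obs": field}, axis=1, join="inner").dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 paired years, got {len(df)}")
    e = df["est"].to_numpy(dtype=float)
    o = df["obs"].to_numpy(dtype=float)
    r = float(stats.pearsonr(e, o).statistic) if np.ptp(e) and np.ptp(o) else float("nan")
    return {"r": r,
            "rmse": float(np.sqrt(np.mean((e - o) ** 2))),
            "bias": float(np.mean(e - o)),
            "n": len(df)}
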
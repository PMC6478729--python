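"""End-to-end pipeline on a synthetic scene (or pre-loaded tables):
rainfall decomposition -> percentile metrics -> calibration -> partition ->
trends, slope comparison and dominant-harmonic analysis.

The stages mirror the field-site analysis: nine-site averages of annual
satellite percentile metrics are calibrated against field biomass, the
calibrated estimates are partitioned into herbaceous (AGH) and
woody-foliage (WPF) components, and annual series of both components and
of the two rainfall components are reduced to trends and periodicity
statistics. A manifest (config hash, seed, library versions) makes runs
reproducible and comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import calibration as cal
from . import phenology, rainseason, trends
from .synthetic import SyntheticConfig, SyntheticScene, generate_scene

__all__ = ["PipelineResult", "run_pipeline", "decompose_scene",
            "field_site_statistics", "config_manifest"]


@dataclass
class PipelineResult:
    scene: SyntheticScene
    decompositions: pd.DataFrame       # per site-year rule-based decomposition
    rain_annual: pd.DataFrame          # per year site-mean rainfall components
    metrics: pd.DataFrame              # per site-year p90/p_dry
    metrics_avg: pd.DataFrame          # per year site-averaged metrics
    field_avg: pd.DataFrame            # per year site-averaged field masses
    model_total: cal.CalibrationModel
    model_wpf: cal.CalibrationModel
    estimates: pd.DataFrame            # per year total_hat/wpf_hat/agh_hat
    stats: dict                        # trend/harmonic/share statistics
    manifest: dict = field(default_factory=dict)


def decompose_scene(scene: SyntheticScene,
                    params: rainseason.RuleParams = rainseason.DEFAULT_PARAMS
                    ) -> pd.DataFrame:
    """Rule-based decomposition of every generated site-year."""
    decomps = [rainseason.decompose_season(series, params)
               for series in scene.daily_rainfall.values()]
    return rainseason.decomposition_table(decomps)


def field_site_statistics(field_avg: pd.DataFrame,
                          cycle_permutations: int = 1000,
                          seed: Optional[int] = None) -> dict:
    """Trend and periodicity statistics of site-averaged annual field data.

    ``field_avg`` needs columns year, agh_kg_ha, wpf_kg_ha (one row per
    year). Returns component trends, the slope-difference test, summary
    means/shares, the share trend, and the dominant harmonic of AGH.
    """
    years = field_avg["year"].to_numpy()
    agh = field_avg["agh_kg_ha"].to_numpy(dtype=float)
    wpf = field_avg["wpf_kg_ha"].to_numpy(dtype=float)
    total = agh + wpf
    share = 100.0 * agh / total
    tr_agh = trends.ols_trend(agh, years)
    tr_wpf = trends.ols_trend(wpf, years)
    tr_share = trends.ols_trend(share, years)
    comp = trends.compare_slopes(agh, wpf, years)
    harm = trends.fit_first_harmonic(agh, n_permutations=cycle_permutations,
                                     seed=seed)
    return {
        "mean_agh_kg_ha": float(np.mean(agh)),
        "mean_wpf_kg_ha": float(np.mean(wpf)),
        "mean_total_kg_ha": float(np.mean(total)),
        "mean_agh_share_pct": float(np.mean(share)),
        "agh_trend": tr_agh,
        "wpf_trend": tr_wpf,
        "share_trend": tr_share,
        "slope_comparison": comp,
        "agh_harmonic": harm,
    }


def run_pipeline(config: Optional[SyntheticConfig] = None,
                 noise: bool = True,
                 rule_params: rainseason.RuleParams = rainseason.DEFAULT_PARAMS,
                 cycle_permutations: int = 1000,
                 decompose: bool = True) -> PipelineResult:
    """Run the full analysis on a generated scene.

    ``decompose=False`` skips the (comparatively slow) rule-based rainfall
    decomposition and uses the generator's true split; closed-loop tests of
    the biomass stages use this.
    """
    config = config or SyntheticConfig()
    scene = generate_scene(config, noise=noise)

    if decompose:
        dec = decompose_scene(scene, rule_params)
        rain_annual = (dec.groupby("year")[["rainfall_C_mm", "rainfall_EL_mm",
                                            "annual_mm"]].mean().reset_index())
    else:
        dec = pd.DataFrame()
        t = scene.truth
        rain_annual = (t.assign(annual_mm=t["rainfall_C"] + t["rainfall_EL"])
                       .rename(columns={"rainfall_C": "rainfall_C_mm",
                                        "rainfall_EL": "rainfall_EL_mm"})
                       .groupby("year")[["rainfall_C_mm", "rainfall_EL_mm",
                                         "annual_mm"]].mean().reset_index())

    metrics = phenology.annual_metrics(scene.satellite, dry_percentile=30)
    metrics_avg = phenology.site_average(metrics)
    field_avg = (scene.field_obs.groupby("year")[["agh_kg_ha", "wpf_kg_ha"]]
                 .mean().reset_index())

    merged = metrics_avg.merge(field_avg, on="year")
    total_obs = merged["agh_kg_ha"] + merged["wpf_kg_ha"]
    model_total = cal.fit_calibration(
        pd.Series(merged["p90"].to_numpy(), index=merged["year"]),
        pd.Series(total_obs.to_numpy(), index=merged["year"]),
        target="total_mass")
    model_wpf = cal.fit_calibration(
        pd.Series(merged["p_dry"].to_numpy(), index=merged["year"]),
        pd.Series(merged["wpf_kg_ha"].to_numpy(), index=merged["year"]),
        target="wpf")

    total_hat = cal.apply_calibration(
        model_total, pd.Series(metrics_avg["p90"].to_numpy(),
                               index=metrics_avg["year"]))
    wpf_hat = cal.apply_calibration(
        model_wpf, pd.Series(metrics_avg["p_dry"].to_numpy(),
                             index=metrics_avg["year"]))
    estimates = cal.partition(total_hat, wpf_hat).reset_index(names="year")

    stats = field_site_statistics(field_avg,
                                  cycle_permutations=cycle_permutations,
                                  seed=config.seed)
    stats["rain_c_trend"] = trends.ols_trend(rain_annual["rainfall_C_mm"],
                                             rain_annual["year"])
    stats["rain_el_trend"] = trends.ols_trend(rain_annual["rainfall_EL_mm"],
                                              rain_annual["year"])
    stats["eval_total"] = cal.evaluate(
        pd.Series(estimates["total_hat"].to_numpy(), index=estimates["year"]),
        pd.Series(total_obs.to_numpy(), index=merged["year"]))
    stats["eval_wpf"] = cal.evaluate(
        pd.Series(estimates["wpf_hat"].to_numpy(), index=estimates["year"]),
        pd.Series(merged["wpf_kg_ha"].to_numpy(), index=merged["year"]))

    return PipelineResult(scene=scene, decompositions=dec,
                          rain_annual=rain_annual, metrics=metrics,
                          metrics_avg=metrics_avg, field_avg=field_avg,
                          model_total=model_total, model_wpf=model_wpf,
                          estimates=estimates, stats=stats,
                          manifest=config_manifest(config))


def config_manifest(config: SyntheticConfig) -> dict:
    """Reproducibility manifest: config hash, seed and library versions."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    import scipy
    return {
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                     "scipy": scipy.__version__},
    }
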
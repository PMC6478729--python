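"""Synthetic scenes: monsoonal rainfall, field biomass, satellite observations.

Every downstream stage of the pipeline is exercised against generated data
with known ground truth. The generator emulates the sandy-Ferlo study
conditions (nine pastoral sites in northern Senegal, 1987-2016):

* **Daily rainfall** — a single summer monsoon. A core wet window (default
  day-of-year 204-244) carries most of the rain as gamma-distributed wet-day
  events; a configurable fraction of the annual total falls as discrete
  events in the early (May - core start) and late (core end - October)
  shoulders, which gives the rule-based season detector realistic onset
  ambiguity and dry spells. Core and shoulder totals drift linearly at
  configurable rates. Defaults: 328 mm mean annual rain, 20% early/late
  share, trends +0.7 mm/yr (core) and +2.1 mm/yr (early/late).

* **Field biomass** — above-ground herbaceous mass (AGH) is proportional to
  the year's core-season rain with a superimposed multi-year sinusoid
  (default 5-yr period) and noise; woody plant foliage mass (WPF) follows
  early/late rain plus a slowly recovering woody-stand term (drought
  recovery) and noise. Defaults reproduce mean AGH ≈ 939 and WPF ≈ 362
  kg/ha with expected trends ≈ +2.5 and +17 kg/ha/yr.

* **Satellite series** — a vegetation-index curve per site-year whose
  wet-season plateau is ``obs_slope*(AGH+WPF)+obs_offset`` and whose
  dry-season plateau is ``obs_slope*WPF+obs_offset`` (woody foliage
  persists into the dry season, herbaceous mass does not), plus iid
  Gaussian noise at a configurable cadence.

Randomness is fully deterministic under ``(config, seed)``: one global seed
is split into independent substreams per stage, site and year, so any stage
can be regenerated alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date
from typing import Optional

import numpy as np
import pandas as pd

from .rainseason import DailyRainfallSeries

__all__ = ["SyntheticConfig", "SyntheticScene", "generate_daily_rainfall",
           "generate_field_obs", "generate_satellite_series", "generate_scene"]

# substream ids (never reorder: part of the reproducibility contract)
_STREAM_RAIN = 1
_STREAM_FIELD = 2
_STREAM_SAT = 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults are the Ferlo study conditions."""

    n_sites: int = 9
    year_start: int = 1987
    year_end: int = 2016
    # rainfall regime
    wet_season_center_doy: int = 224            # core window 204-244
    wet_season_width_days: int = 41
    mean_annual_rain_mm: float = 328.0
    early_late_fraction: float = 0.2
    trend_rain_c_mm_per_yr: float = 0.7
    trend_rain_el_mm_per_yr: float = 2.1
    wet_day_prob: float = 0.8                   # inside the core window
    core_event_shape: float = 0.8               # gamma shape, core events
    early_event_mean_mm: float = 7.0
    early_event_shape: float = 1.2     # skewed: occasional heavy pre-onset storm
    late_event_mean_mm: float = 3.5
    late_event_shape: float = 2.5      # late rains are small sporadic showers
    early_share_of_el: float = 0.6
    # field biomass model
    agh_rain_use_efficiency_kg_per_mm: float = 3.58
    wpf_rain_use_efficiency_kg_per_mm: float = 2.5
    wpf_persistence_kg: float = 198.0           # woody baseline at mid-period
    wpf_recovery_kg_per_yr: float = 11.75       # drought-recovery drift
    agh_cycle_period_yr: float = 5.0
    agh_cycle_amplitude_kg: float = 200.0
    # phase chosen orthogonal to a linear term over the default 30-yr
    # record (-3*pi/10), so the cycle does not alias into the AGH trend
    # and the injected trend is exactly what the trend stage should see
    agh_cycle_phase_rad: float = -0.3 * np.pi
    agh_noise_sd_kg: float = 90.0
    wpf_noise_sd_kg: float = 35.0
    # satellite observation model
    obs_slope: float = 2.0e-4                   # index units per kg/ha
    obs_offset: float = 0.15
    obs_noise_sd: float = 0.01
    obs_cadence_days: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.early_late_fraction <= 1.0):
            raise ValueError("early_late_fraction must lie in [0, 1]")
        if not (0.0 <= self.early_share_of_el <= 1.0):
            raise ValueError("early_share_of_el must lie in [0, 1]")
        for name in ("mean_annual_rain_mm", "agh_rain_use_efficiency_kg_per_mm",
                     "wpf_rain_use_efficiency_kg_per_mm", "wpf_persistence_kg",
                     "agh_cycle_amplitude_kg", "agh_noise_sd_kg",
                     "wpf_noise_sd_kg", "obs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if not (0.0 < self.wet_day_prob <= 1.0):
            raise ValueError("wet_day_prob must lie in (0, 1]")

    # -- derived quantities -------------------------------------------------
    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def _mid(self) -> float:
        return (self.year_start + self.year_end) / 2.0

    def core_window_doy(self) -> tuple[int, int]:
        w = self.wet_season_width_days
        start = self.wet_season_center_doy - (w - 1) // 2
        return start, start + w - 1

    def target_core_mm(self, year: int) -> float:
        base = (1.0 - self.early_late_fraction) * self.mean_annual_rain_mm
        return max(0.0, base + self.trend_rain_c_mm_per_yr * (year - self._mid))

    def target_el_mm(self, year: int) -> float:
        base = self.early_late_fraction * self.mean_annual_rain_mm
        return max(0.0, base + self.trend_rain_el_mm_per_yr * (year - self._mid))

    def expected_agh_kg(self) -> float:
        return (self.agh_rain_use_efficiency_kg_per_mm
                * (1.0 - self.early_late_fraction) * self.mean_annual_rain_mm)

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        """Load a configuration from a YAML key-value file; keys missing
        from the file keep their defaults, unknown keys are an error."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _rng(config: SyntheticConfig, stream: int, site: int = 0, year: int = 0
         ) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(stream, site, year))
    return np.random.default_rng(ss)


def _site_id(i: int) -> str:
    return f"site{i + 1:02d}"


@dataclass
class SyntheticScene:
    """All generated observations plus the per-site-year ground truth."""

    config: SyntheticConfig
    daily_rainfall: dict  # (site, year) -> DailyRainfallSeries
    truth: pd.DataFrame   # site, year, rainfall_C, rainfall_EL, agh_true, wpf_true
    field_obs: pd.DataFrame       # site, year, agh_kg_ha, wpf_kg_ha
    satellite: pd.DataFrame       # site, year, date, value


# ---------------------------------------------------------------------------
# rainfall
# ---------------------------------------------------------------------------

def generate_daily_rainfall(config: SyntheticConfig, site: str, year: int
                            ) -> DailyRainfallSeries:
    """One site-year of daily rainfall, 1 May - 31 October.

    Core-window rain: Bernoulli wet days with gamma event sizes whose mean
    is set so the expected core total hits the year's target. Shoulder
    rain: independent daily events at a rate set so the expected early/late
    totals hit their targets.
    """
    sites = [_site_id(i) for i in range(config.n_sites)]
    if site not in sites:
        raise ValueError(f"unknown site {site!r}")
    if not (config.year_start <= year <= config.year_end):
        raise ValueError(f"year {year} outside configured range")
    site_idx = sites.index(site)
    rng = _rng(config, _STREAM_RAIN, site_idx, year)

    index = pd.date_range(date(year, 5, 1), date(year, 10, 31), freq="D")
    doy = index.dayofyear.to_numpy()
    rain = np.zeros(len(index))

    core_start, core_end = config.core_window_doy()
    core_mask = (doy >= core_start) & (doy <= core_end)
    n_core = int(core_mask.sum())

    target_c = config.target_core_mm(year)
    if n_core > 0 and target_c > 0:
        mean_event = target_c / (config.wet_day_prob * n_core)
        wet = rng.random(n_core) < config.wet_day_prob
        k = config.core_event_shape
        amounts = rng.gamma(k, mean_event / k, size=n_core)
        rain[core_mask] = np.where(wet, amounts, 0.0)

    target_el = config.target_el_mm(year)
    for shoulder_mask, share, mean_event, k in (
        (doy < core_start, config.early_share_of_el,
         config.early_event_mean_mm, config.early_event_shape),
        (doy > core_end, 1.0 - config.early_share_of_el,
         config.late_event_mean_mm, config.late_event_shape),
    ):
        n_days = int(shoulder_mask.sum())
        target = target_el * share
        if n_days == 0 or target <= 0 or mean_event <= 0:
            continue
        p_event = min(1.0, target / (n_days * mean_event))
        hit = rng.random(n_days) < p_event
        amounts = rng.gamma(k, mean_event / k, size=n_days)
        rain[shoulder_mask] = np.where(hit, amounts, 0.0)

    return DailyRainfallSeries(site=site, year=year,
                               values=pd.Series(rain, index=index))


def _rainfall_truth(config: SyntheticConfig, series: DailyRainfallSeries
                    ) -> tuple[float, float]:
    """True (rainfall_C, rainfall_EL) of a generated year: the split at the
    generator's own core window. Conserves the May-Oct total exactly."""
    doy = series.values.index.dayofyear.to_numpy()
    core_start, core_end = config.core_window_doy()
    mask = (doy >= core_start) & (doy <= core_end)
    total = float(series.values.sum())
    rainfall_c = float(series.values.to_numpy()[mask].sum())
    return rainfall_c, total - rainfall_c


# ---------------------------------------------------------------------------
# field biomass
# ---------------------------------------------------------------------------

def generate_field_obs(config: SyntheticConfig, truth_rain: pd.DataFrame,
                       noise: bool = True) -> pd.DataFrame:
    """Annual AGH and WPF per site from true rainfall components.

    ``truth_rain`` needs columns site, year, rainfall_C, rainfall_EL.
    AGH = RUE_agh * rainfall_C * (1 + a*sin(2*pi*t/P)), WPF =
    RUE_wpf * rainfall_EL + persistence + recovery*(t - mid); Gaussian
    noise truncated at zero (masses are non-negative).
    """
    required = {"site", "year", "rainfall_C", "rainfall_EL"}
    if not required.issubset(truth_rain.columns):
        raise ValueError(f"truth_rain must have columns {sorted(required)}")
    sites = [_site_id(i) for i in range(config.n_sites)]
    expected_agh = config.expected_agh_kg()
    rel_amp = (config.agh_cycle_amplitude_kg / expected_agh
               if expected_agh > 0 else 0.0)
    rows = []
    for _, rec in truth_rain.iterrows():
        site, year = str(rec["site"]), int(rec["year"])
        site_idx = sites.index(site) if site in sites else 0
        rng = _rng(config, _STREAM_FIELD, site_idx, year)
        eps_a, eps_w = rng.normal(0.0, 1.0, size=2)
        t = year - config.year_start
        cycle = rel_amp * np.sin(2.0 * np.pi * t / config.agh_cycle_period_yr
                                 + config.agh_cycle_phase_rad)
        agh = (config.agh_rain_use_efficiency_kg_per_mm
               * float(rec["rainfall_C"]) * (1.0 + cycle))
        wpf = (config.wpf_rain_use_efficiency_kg_per_mm
               * float(rec["rainfall_EL"])
               + config.wpf_persistence_kg
               + config.wpf_recovery_kg_per_yr * (year - config._mid))
        if noise:
            agh += config.agh_noise_sd_kg * eps_a
            wpf += config.wpf_noise_sd_kg * eps_w
        rows.append({"site": site, "year": year,
                     "agh_kg_ha": max(0.0, agh), "wpf_kg_ha": max(0.0, wpf)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# satellite observations
# ---------------------------------------------------------------------------

def _green_fraction(doy: np.ndarray) -> np.ndarray:
    """Herbaceous greenness profile: ramp up 185-200, full 200-255,
    wilt 255-285, zero otherwise. Woody foliage persists year-round."""
    g = np.zeros_like(doy, dtype=float)
    up = (doy >= 185) & (doy < 200)
    g[up] = (doy[up] - 185) / 15.0
    g[(doy >= 200) & (doy <= 255)] = 1.0
    down = (doy > 255) & (doy <= 285)
    g[down] = (285 - doy[down]) / 30.0
    return g


def generate_satellite_series(config: SyntheticConfig, field_obs: pd.DataFrame,
                              noise: bool = True) -> pd.DataFrame:
    """Vegetation-index observations per site-year at the configured cadence.

    value(d) = obs_offset + obs_slope * (WPF + g(d) * AGH) + eps, where g is
    the herbaceous greenness profile. Long table: site, year, date, value.
    """
    sites = [_site_id(i) for i in range(config.n_sites)]
    cadence = config.obs_cadence_days
    frames = []
    for _, rec in field_obs.iterrows():
        site, year = str(rec["site"]), int(rec["year"])
        site_idx = sites.index(site) if site in sites else 0
        rng = _rng(config, _STREAM_SAT, site_idx, year)
        doy = np.arange(cadence // 2, 366 - cadence // 2 + 1, cadence)
        doy = doy[doy <= (366 if pd.Timestamp(year=year, month=12, day=31
                                              ).dayofyear == 366 else 365)]
        dates = pd.to_datetime([date(year, 1, 1)] * len(doy)) + pd.to_timedelta(
            doy - 1, unit="D")
        signal = config.obs_offset + config.obs_slope * (
            float(rec["wpf_kg_ha"])
            + _green_fraction(doy) * float(rec["agh_kg_ha"]))
        values = signal + (config.obs_noise_sd * rng.normal(size=len(doy))
                           if noise else 0.0)
        frames.append(pd.DataFrame({"site": site, "year": year,
                                    "date": dates, "value": values}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# full scene
# ---------------------------------------------------------------------------

def generate_scene(config: Optional[SyntheticConfig] = None,
                   noise: bool = True) -> SyntheticScene:
    """Generate rainfall, truth, field and satellite data for every
    (site, year). ``noise=False`` zeroes the field and satellite noise for
    closed-loop tests (rainfall remains stochastic: it *is* the weather)."""
    config = config or SyntheticConfig()
    rainfall = {}
    truth_rows = []
    for i in range(config.n_sites):
        site = _site_id(i)
        for year in config.years:
            series = generate_daily_rainfall(config, site, int(year))
            rainfall[(site, int(year))] = series
            c, el = _rainfall_truth(config, series)
            truth_rows.append({"site": site, "year": int(year),
                               "rainfall_C": c, "rainfall_EL": el})
    truth = pd.DataFrame(truth_rows)
    field_obs = generate_field_obs(config, truth, noise=noise)
    truth = truth.merge(
        field_obs.rename(columns={"agh_kg_ha": "agh_true",
                                  "wpf_kg_ha": "wpf_true"}),
        on=["site", "year"])
    satellite = generate_satellite_series(config, field_obs, noise=noise)
    return SyntheticScene(config=config, daily_rainfall=rainfall, truth=truth,
                          field_obs=field_obs, satellite=satellite)
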
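"""Decompose a year of daily Sahelian rainfall into core wet-season rain and
early/late rain.

The wet season of the Sahel is a single summer monsoon. Annual herbaceous
plants germinate with the first sustained rains and wilt at the end of the
season, so only rain falling inside an *uninterrupted* core wet season is
usable by them; rain falling before onset or after cessation (early/late
rain) mainly benefits perennial woody plants. This module implements a
rule system that locates that core window from daily rainfall alone, using
two running water stores as simple evapotranspiration surrogates:

* ``CR-5`` accumulates daily rainfall minus 5 mm per day, clamped at zero
  (used for season onset — germination needs a sustained surplus).
* ``CR-3`` accumulates daily rainfall minus 3 mm per day, clamped at zero
  (used for dry-spell detection).

Four dates bound the core season:

1. *Onset of first rain* — first day with >= 12 mm, or the first day of
   five consecutive days summing to more than 20 mm.
2. *Onset of the core wet season* — ten days after the first rain with
   CR-5 positive if no dry spell intervenes, otherwise the first day with
   CR-5 positive after the last dry spell; in any case before 15 August.
3. *End of the core wet season* — the last rain, unless a dry spell occurs
   between 15 August and the last rain, in which case the season ends when
   the spell begins.
4. *Last rain* — after 15 August, the last day with more than 12 mm or the
   last day of five consecutive days summing to more than 20 mm.

Dry spells fire when any of five sliding-window conditions on the CR-3
store holds: six consecutive zero days, or 12/18/24/30 consecutive days
whose summed store stays below 6/9/12/15 mm. Overlapping detections are
clustered and the longest prevailing window is reported per cluster.

Rain summed over [onset_core, end_core] is ``rainfall_C``; the remainder of
the 1 May - 31 October total is ``rainfall_EL``. November-April is excluded
throughout. A fixed-window variant (default day-of-year 204-244, the
regional mean window) is provided for large-area application.

All thresholds are parameters of :class:`RuleParams`; the defaults are the
published rule values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RuleParams",
    "DailyRainfallSeries",
    "CumulativeStore",
    "DrySpell",
    "SeasonDates",
    "RainfallDecomposition",
    "cumulative_store",
    "detect_onset_first_rain",
    "detect_last_rain",
    "detect_dry_spells",
    "detect_core_onset",
    "detect_core_end",
    "decompose_season",
    "decompose_fixed_window",
]


@dataclass(frozen=True)
class RuleParams:
    """Thresholds of the decomposition rule system (defaults as published).

    ``dry_spell_conditions`` is a tuple of ``(window_days, sum_below_mm)``;
    ``sum_below_mm == 0`` means "store exactly zero on every day".
    ``balance_mode`` selects what "summed CR-3 balance" means: the sum of
    the daily store values (``"store"``, default) or the sum of the daily
    net increments rain - drawdown (``"increment"``).
    ``end_convention`` controls the core-season end when a dry spell occurs
    after 15 August: ``"day_before_spell"`` (default) or ``"last_rain"``.
    """

    heavy_rain_onset_mm: float = 12.0   # inclusive (">= 12 mm")
    heavy_rain_last_mm: float = 12.0    # exclusive ("above 12 mm")
    run_days: int = 5
    run_sum_mm: float = 20.0            # exclusive ("> 20 mm")
    onset_drawdown_mm: float = 5.0      # CR-5
    dry_drawdown_mm: float = 3.0        # CR-3
    germination_days: int = 10
    season_start: tuple[int, int] = (5, 1)     # 1 May
    season_end: tuple[int, int] = (10, 31)     # 31 Oct
    mid_cutoff: tuple[int, int] = (8, 15)      # 15 Aug
    dry_spell_conditions: tuple[tuple[int, float], ...] = (
        (6, 0.0), (12, 6.0), (18, 9.0), (24, 12.0), (30, 15.0),
    )
    balance_mode: str = "store"
    end_convention: str = "day_before_spell"
    fixed_start_doy: int = 204
    fixed_end_doy: int = 244

    def __post_init__(self) -> None:
        if self.balance_mode not in ("store", "increment"):
            raise ValueError(f"unknown balance_mode {self.balance_mode!r}")
        if self.end_convention not in ("day_before_spell", "last_rain"):
            raise ValueError(f"unknown end_convention {self.end_convention!r}")


DEFAULT_PARAMS = RuleParams()


@dataclass
class DailyRainfallSeries:
    """One site-year of daily rainfall in mm, date-indexed.

    ``values`` must cover at least 1 May - 31 October of ``year`` at daily
    cadence with no gaps and no negative or non-finite entries.
    """

    site: str
    year: int
    values: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v.index, pd.DatetimeIndex):
            raise TypeError("values must be indexed by a DatetimeIndex")
        v = v.sort_index()
        arr = np.asarray(v.to_numpy(), dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("rainfall values must be finite (no gaps)")
        if np.any(arr < 0):
            raise ValueError("rainfall values must be non-negative")
        start = pd.Timestamp(date(self.year, 5, 1))
        end = pd.Timestamp(date(self.year, 10, 31))
        if v.index[0] > start or v.index[-1] < end:
            raise ValueError(
                f"series must cover 1 May-31 Oct {self.year}, "
                f"got {v.index[0].date()}..{v.index[-1].date()}"
            )
        window = v.loc[start:end]
        if len(window) != (end - start).days + 1:
            raise ValueError("daily cadence with no gaps required inside May-Oct")
        self.values = v

    def season_window(self, params: RuleParams = DEFAULT_PARAMS) -> pd.Series:
        """The 1 May - 31 Oct slice used by every rule."""
        start = pd.Timestamp(date(self.year, *params.season_start))
        end = pd.Timestamp(date(self.year, *params.season_end))
        return self.values.loc[start:end]


@dataclass
class CumulativeStore:
    """Daily water store: ``value_t = max(0, value_{t-1} + rain_t - drawdown)``."""

    drawdown: float
    values: pd.Series


@dataclass(frozen=True)
class DrySpell:
    start: pd.Timestamp
    end: pd.Timestamp
    rule_id: int        # 1..5, index into RuleParams.dry_spell_conditions
    length_days: int


@dataclass
class SeasonDates:
    onset_first_rain: Optional[pd.Timestamp] = None
    onset_core: Optional[pd.Timestamp] = None
    end_core: Optional[pd.Timestamp] = None
    last_rain: Optional[pd.Timestamp] = None

    @property
    def complete(self) -> bool:
        return None not in (
            self.onset_first_rain, self.onset_core, self.end_core, self.last_rain
        )


@dataclass
class RainfallDecomposition:
    site: str
    year: int
    season: SeasonDates
    rainfall_C: float
    rainfall_EL: float
    annual: float
    dry_spells: list[DrySpell] = field(default_factory=list)
    flag: str = ""   # "" if the full rule system resolved, else a reason


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _store_array(rain: np.ndarray, drawdown: float) -> np.ndarray:
    out = np.empty_like(rain)
    level = 0.0
    for i, r in enumerate(rain):
        level = level + r - drawdown
        if level < 0.0:
            level = 0.0
        out[i] = level
    return out


def cumulative_store(series: DailyRainfallSeries, drawdown: float,
                     params: RuleParams = DEFAULT_PARAMS) -> CumulativeStore:
    """Clamped running water balance over the May-Oct window.

    The store is initialised at zero on 1 May (the core dry season is
    excluded, so no carry-over between years).
    """
    if drawdown <= 0:
        raise ValueError("drawdown must be positive")
    window = series.season_window(params)
    values = _store_array(window.to_numpy(dtype=float), float(drawdown))
    return CumulativeStore(drawdown=float(drawdown),
                           values=pd.Series(values, index=window.index))


def _qualifying_run_starts(rain: np.ndarray, run_days: int, run_sum: float) -> np.ndarray:
    """Start indices of runs of ``run_days`` consecutive days summing > run_sum."""
    if len(rain) < run_days:
        return np.empty(0, dtype=int)
    sums = np.convolve(rain, np.ones(run_days), mode="valid")
    return np.nonzero(sums > run_sum)[0]


def _first_wet(rain: np.ndarray, start: int, length: int) -> Optional[int]:
    for i in range(start, start + length):
        if rain[i] > 0:
            return i
    return None


def _last_wet(rain: np.ndarray, start: int, length: int) -> Optional[int]:
    for i in range(start + length - 1, start - 1, -1):
        if rain[i] > 0:
            return i
    return None


def detect_onset_first_rain(series: DailyRainfallSeries,
                            params: RuleParams = DEFAULT_PARAMS
                            ) -> Optional[pd.Timestamp]:
    """Earliest day on/after 1 May with >= 12 mm, or the first rain day of
    five consecutive days summing to more than 20 mm. ``None`` if neither
    clause fires.

    For the 5-day clause the reported day is the first day *with rain*
    inside the qualifying window (a window may begin on rainless days).
    """
    window = series.season_window(params)
    rain = window.to_numpy(dtype=float)
    idx: list[int] = []
    heavy = np.nonzero(rain >= params.heavy_rain_onset_mm)[0]
    if heavy.size:
        idx.append(int(heavy[0]))
    runs = _qualifying_run_starts(rain, params.run_days, params.run_sum_mm)
    if runs.size:
        fw = _first_wet(rain, int(runs[0]), params.run_days)
        if fw is not None:
            idx.append(fw)
    if not idx:
        return None
    return window.index[min(idx)]


def detect_last_rain(series: DailyRainfallSeries,
                     params: RuleParams = DEFAULT_PARAMS
                     ) -> Optional[pd.Timestamp]:
    """Latest qualifying rain day in [15 Aug, 31 Oct].

    Qualifies: daily rain strictly above 12 mm, or the last rain day of
    five consecutive days summing to more than 20 mm (the window may begin
    before 15 August, its last rain day may not).
    """
    window = series.season_window(params)
    rain = window.to_numpy(dtype=float)
    cutoff = pd.Timestamp(date(series.year, *params.mid_cutoff))
    cut_i = int(window.index.get_loc(cutoff))
    idx: list[int] = []
    heavy = np.nonzero(rain > params.heavy_rain_last_mm)[0]
    heavy = heavy[heavy >= cut_i]
    if heavy.size:
        idx.append(int(heavy[-1]))
    for s in _qualifying_run_starts(rain, params.run_days, params.run_sum_mm):
        lw = _last_wet(rain, int(s), params.run_days)
        if lw is not None and lw >= cut_i:
            idx.append(lw)
    if not idx:
        return None
    return window.index[max(idx)]


def _envelopes_from_starts(starts: np.ndarray, win_len: int) -> list[tuple[int, int]]:
    """Merge consecutive/overlapping qualifying window starts of one rule
    into envelopes [first_start, last_start + win_len - 1]."""
    if starts.size == 0:
        return []
    envelopes = []
    s0 = prev = int(starts[0])
    for s in starts[1:]:
        s = int(s)
        if s <= prev + win_len:      # windows overlap or touch
            prev = s
        else:
            envelopes.append((s0, prev + win_len - 1))
            s0 = prev = s
    envelopes.append((s0, prev + win_len - 1))
    return envelopes


def detect_dry_spells(cr3: CumulativeStore,
                      params: RuleParams = DEFAULT_PARAMS,
                      rain: Optional[np.ndarray] = None) -> list[DrySpell]:
    """Evaluate the five dry-spell conditions over every sliding window.

    Per-rule qualifying windows that overlap are merged into envelopes;
    envelopes from different rules that overlap form a cluster, and the
    longest envelope prevails (ties: earlier start, then the condition
    with the longer base window). ``rain`` is only needed for
    ``balance_mode="increment"``.
    """
    store = cr3.values.to_numpy(dtype=float)
    index = cr3.values.index
    n = len(store)
    if params.balance_mode == "increment":
        if rain is None:
            raise ValueError("increment mode needs the rain array")
        balance = np.asarray(rain, dtype=float) - cr3.drawdown
    else:
        balance = store

    candidates: list[tuple[int, int, int, int]] = []  # (start, end, rule_id, base_len)
    for rule_id, (win_len, thresh) in enumerate(params.dry_spell_conditions, start=1):
        if win_len > n:
            continue
        if thresh == 0.0:
            # runs of exactly-zero store of at least win_len days
            zero = store <= 1e-12
            starts = []
            i = 0
            while i < n:
                if zero[i]:
                    j = i
                    while j + 1 < n and zero[j + 1]:
                        j += 1
                    if j - i + 1 >= win_len:
                        candidates.append((i, j, rule_id, win_len))
                    i = j + 1
                else:
                    i += 1
        else:
            sums = np.convolve(balance, np.ones(win_len), mode="valid")
            starts = np.nonzero(sums < thresh)[0]
            for s, e in _envelopes_from_starts(starts, win_len):
                candidates.append((s, e, rule_id, win_len))

    if not candidates:
        return []

    # cluster by date overlap
    candidates.sort(key=lambda c: (c[0], c[1]))
    clusters: list[list[tuple[int, int, int, int]]] = []
    cur = [candidates[0]]
    cur_end = candidates[0][1]
    for c in candidates[1:]:
        if c[0] <= cur_end:                 # overlaps the running cluster
            cur.append(c)
            cur_end = max(cur_end, c[1])
        else:
            clusters.append(cur)
            cur = [c]
            cur_end = c[1]
    clusters.append(cur)

    spells = []
    for cluster in clusters:
        best = max(cluster, key=lambda c: (c[1] - c[0], -c[0], c[3]))
        s, e, rule_id, _ = best
        spells.append(DrySpell(start=index[s], end=index[e], rule_id=rule_id,
                               length_days=e - s + 1))
    return spells


def detect_core_onset(series: DailyRainfallSeries,
                      cr5: CumulativeStore,
                      first_rain: Optional[pd.Timestamp],
                      dry_spells: Sequence[DrySpell],
                      params: RuleParams = DEFAULT_PARAMS
                      ) -> Optional[pd.Timestamp]:
    """Onset of the core wet season (strictly before 15 August).

    No dry spell between the first rain and 15 August: ten days after the
    first rain provided CR-5 is positive there, else the first later day
    with CR-5 positive. Otherwise: the first day with CR-5 positive after
    the end of the last such dry spell.
    """
    if first_rain is None:
        return None
    cutoff = pd.Timestamp(date(series.year, *params.mid_cutoff))
    store = cr5.values
    relevant = [sp for sp in dry_spells
                if sp.start > first_rain and sp.start < cutoff]
    if relevant:
        search_from = max(sp.end for sp in relevant) + timedelta(days=1)
    else:
        search_from = first_rain + timedelta(days=params.germination_days)
    tail = store.loc[search_from:]
    positive = tail[tail > 0]
    if positive.empty:
        return None
    onset = positive.index[0]
    return onset if onset < cutoff else None


def detect_core_end(series: DailyRainfallSeries,
                    dry_spells: Sequence[DrySpell],
                    last_rain: Optional[pd.Timestamp],
                    params: RuleParams = DEFAULT_PARAMS
                    ) -> Optional[pd.Timestamp]:
    """End of the core wet season (on/after 15 August).

    If a dry spell starts between 15 August and the last rain, the season
    ends the day before the earliest such spell (configurable); otherwise
    it ends at the last rain.
    """
    if last_rain is None:
        return None
    cutoff = pd.Timestamp(date(series.year, *params.mid_cutoff))
    if last_rain < cutoff:
        return None
    between = [sp for sp in dry_spells if cutoff <= sp.start <= last_rain]
    if between and params.end_convention == "day_before_spell":
        first_spell = min(between, key=lambda sp: sp.start)
        end = first_spell.start - timedelta(days=1)
        return max(end, cutoff)
    return last_rain


def decompose_season(series: DailyRainfallSeries,
                     params: RuleParams = DEFAULT_PARAMS
                     ) -> RainfallDecomposition:
    """Full rule-based decomposition of one site-year.

    When any required season date cannot be established the year is flagged
    and all May-Oct rain is attributed to ``rainfall_EL``.
    """
    window = series.season_window(params)
    annual = float(window.sum())
    cr5 = cumulative_store(series, params.onset_drawdown_mm, params)
    cr3 = cumulative_store(series, params.dry_drawdown_mm, params)
    spells = detect_dry_spells(cr3, params, rain=window.to_numpy(dtype=float))

    dates = SeasonDates()
    dates.onset_first_rain = detect_onset_first_rain(series, params)
    dates.last_rain = detect_last_rain(series, params)
    dates.onset_core = detect_core_onset(series, cr5, dates.onset_first_rain,
                                         spells, params)
    dates.end_core = detect_core_end(series, spells, dates.last_rain, params)

    if dates.complete and dates.onset_core <= dates.end_core:
        rainfall_c = float(window.loc[dates.onset_core:dates.end_core].sum())
        flag = ""
    else:
        rainfall_c = 0.0
        missing = [name for name, v in (
            ("onset_first_rain", dates.onset_first_rain),
            ("onset_core", dates.onset_core),
            ("end_core", dates.end_core),
            ("last_rain", dates.last_rain),
        ) if v is None]
        flag = "no_core_season:" + ",".join(missing) if missing else "inverted_core"
    return RainfallDecomposition(
        site=series.site, year=series.year, season=dates,
        rainfall_C=rainfall_c, rainfall_EL=annual - rainfall_c,
        annual=annual, dry_spells=list(spells), flag=flag,
    )


def decompose_fixed_window(series: DailyRainfallSeries,
                           start_doy: Optional[int] = None,
                           end_doy: Optional[int] = None,
                           params: RuleParams = DEFAULT_PARAMS
                           ) -> RainfallDecomposition:
    """Fixed day-of-year window variant (regional application).

    ``rainfall_C`` is the sum over [start_doy, end_doy] (default 204-244,
    the regional mean core season); ``rainfall_EL`` the remainder of the
    May-Oct total. Windows reaching outside May-Oct are clipped with a
    warning.
    """
    import warnings

    start_doy = params.fixed_start_doy if start_doy is None else int(start_doy)
    end_doy = params.fixed_end_doy if end_doy is None else int(end_doy)
    if not (1 <= start_doy <= end_doy <= 366):
        raise ValueError("need 1 <= start_doy <= end_doy <= 366")
    window = series.season_window(params)
    doy = window.index.dayofyear
    lo, hi = int(doy[0]), int(doy[-1])
    if start_doy < lo or end_doy > hi:
        warnings.warn("fixed window reaches outside 1 May-31 Oct; clipped",
                      stacklevel=2)
        start_doy, end_doy = max(start_doy, lo), min(end_doy, hi)
    mask = (doy >= start_doy) & (doy <= end_doy)
    annual = float(window.sum())
    rainfall_c = float(window.to_numpy()[mask].sum())
    start = window.index[mask][0] if mask.any() else None
    end = window.index[mask][-1] if mask.any() else None
    return RainfallDecomposition(
        site=series.site, year=series.year,
        season=SeasonDates(onset_core=start, end_core=end),
        rainfall_C=rainfall_c, rainfall_EL=annual - rainfall_c,
        annual=annual, dry_spells=[], flag="fixed_window",
    )


def decomposition_table(decomps: Sequence[RainfallDecomposition]) -> pd.DataFrame:
    """Flatten decompositions to the canonical output table."""
    def _d(ts):
        return ts.date().isoformat() if ts is not None else ""

    rows = []
    for d in decomps:
        rows.append({
            "site": d.site, "year": d.year,
            "onset_first_rain": _d(d.season.onset_first_rain),
            "onset_core": _d(d.season.onset_core),
            "end_core": _d(d.season.end_core),
            "last_rain": _d(d.season.last_rain),
            "rainfall_C_mm": d.rainfall_C,
            "rainfall_EL_mm": d.rainfall_EL,
            "annual_mm": d.annual,
            "n_dry_spells": len(d.dry_spells),
            "flag": d.flag,
        })
    return pd.DataFrame(rows)
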
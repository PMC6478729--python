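"""Rule-system tests: hand-traced recurrences, date detectors, dry spells,
full decomposition against an independent reference implementation."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sahelveg import rainseason as rs

from conftest import make_series, series_from_events
from oracle_rules import oracle_decompose


def ts(year, month, day):
    return pd.Timestamp(date(year, month, day))


# ---------------------------------------------------------------------------
# cumulative stores
# ---------------------------------------------------------------------------

class TestCumulativeStore:
    def test_all_zero_rain_gives_all_zero_store(self):
        store = rs.cumulative_store(make_series(), 5.0)
        assert (store.values == 0).all()

    @pytest.mark.parametrize("rain,drawdown,expected", [
        ([10, 0, 0], 5.0, [5, 0, 0]),
        ([20, 20, 20], 3.0, [17, 34, 51]),
    ])
    def test_hand_traced_recurrence(self, rain, drawdown, expected):
        full = np.zeros(184)
        full[:len(rain)] = rain
        store = rs.cumulative_store(make_series(rain=full), drawdown)
        np.testing.assert_allclose(store.values.iloc[:len(rain)], expected)

    def test_negative_drawdown_rejected(self):
        with pytest.raises(ValueError):
            rs.cumulative_store(make_series(), -1.0)

    @given(st.lists(st.floats(0, 60), min_size=184, max_size=184))
    @settings(max_examples=25, deadline=None)
    def test_recurrence_matches_naive_loop(self, rain):
        store = rs.cumulative_store(make_series(rain=rain), 3.0)
        level, expected = 0.0, []
        for r in rain:
            level = max(0.0, level + r - 3.0)
            expected.append(level)
        np.testing.assert_allclose(store.values.to_numpy(), expected)

    def test_negative_rain_rejected(self):
        with pytest.raises(ValueError):
            make_series(rain=np.full(184, -1.0))


# ---------------------------------------------------------------------------
# date detectors
# ---------------------------------------------------------------------------

class TestOnsetFirstRain:
    def test_exactly_12mm_day_qualifies(self):
        ser = series_from_events(events=[(6, 1, 12.0)])
        assert rs.detect_onset_first_rain(ser) == ts(2000, 6, 1)

    def test_five_day_sum_above_20_qualifies_at_first_day(self):
        ser = series_from_events(events=[((6, 10), (6, 14), 4.5)])
        assert rs.detect_onset_first_rain(ser) == ts(2000, 6, 10)

    def test_five_day_sum_exactly_20_does_not_qualify(self):
        ser = series_from_events(events=[((6, 10), (6, 14), 4.0)])
        assert rs.detect_onset_first_rain(ser) is None

    def test_constant_3mm_never_qualifies(self):
        ser = make_series(rain=np.full(184, 3.0))
        assert rs.detect_onset_first_rain(ser) is None

    def test_window_starting_on_dry_day_reports_first_wet_day(self):
        # 21 mm preceded by dry days: window [Jun 8..12] qualifies but the
        # onset is the rain day itself
        ser = series_from_events(events=[(6, 10, 11.0), (6, 11, 10.0)])
        assert rs.detect_onset_first_rain(ser) == ts(2000, 6, 10)


class TestLastRain:
    def test_single_heavy_event_after_cutoff(self):
        ser = series_from_events(events=[(6, 20, 15.0), (9, 30, 15.0)])
        assert rs.detect_last_rain(ser) == ts(2000, 9, 30)

    def test_exactly_12mm_does_not_qualify(self):
        ser = series_from_events(events=[(9, 30, 12.0)])
        assert rs.detect_last_rain(ser) is None

    def test_five_day_run_reports_last_wet_day(self):
        ser = series_from_events(events=[((10, 8), (10, 12), 4.5)])
        assert rs.detect_last_rain(ser) == ts(2000, 10, 12)

    def test_no_qualifying_rain_after_cutoff(self):
        ser = series_from_events(events=[(7, 1, 40.0)])
        assert rs.detect_last_rain(ser) is None

    def test_heavy_rain_before_cutoff_ignored_by_daily_clause(self):
        ser = series_from_events(events=[(8, 14, 30.0)])
        # 30 mm alone is also a >20 5-day window, but its last wet day is
        # 14 Aug < the cutoff
        assert rs.detect_last_rain(ser) is None


# ---------------------------------------------------------------------------
# dry spells
# ---------------------------------------------------------------------------

def spells_for(ser, params=rs.DEFAULT_PARAMS):
    cr3 = rs.cumulative_store(ser, params.dry_drawdown_mm, params)
    return rs.detect_dry_spells(cr3, params,
                                rain=ser.season_window(params).to_numpy())


class TestDrySpells:
    def test_constant_heavy_rain_no_spells(self):
        ser = make_series(rain=np.full(184, 10.0))
        assert spells_for(ser) == []

    def test_single_storm_then_dry_reports_longest_condition(self):
        # 20 mm on 1 May, dry after: CR-3 drains to zero on 7 May; the
        # 30-day condition's window envelope starts 5 May and runs to the
        # series end, prevailing over the zero-run
        ser = series_from_events(events=[(5, 1, 20.0)])
        spells = spells_for(ser)
        assert len(spells) == 1
        sp = spells[0]
        assert sp.start == ts(2000, 5, 5)
        assert sp.end == ts(2000, 10, 31)
        assert sp.rule_id == 5
        assert sp.length_days == 180

    def test_two_separated_zero_runs_give_two_spells(self):
        # two 10-day rainless gaps bracketed by 20 mm storms, then
        # sustained rain keeping the store positive
        ser = series_from_events(events=[
            (5, 1, 20.0), (5, 17, 20.0),
            ((6, 2), (10, 31), 10.0),
        ])
        spells = spells_for(ser)
        assert len(spells) == 2
        first, second = spells
        assert first.rule_id == 1 and second.rule_id == 1
        assert first.start == ts(2000, 5, 7) and first.end == ts(2000, 5, 16)
        assert second.start == ts(2000, 5, 23) and second.end == ts(2000, 6, 1)

    @pytest.mark.parametrize("n_zero,fires", [(5, False), (6, True)])
    def test_six_zero_store_days_fire_but_five_do_not(self, n_zero, fires):
        # crafted store: a short exact-zero run inside an otherwise full
        # store, so only the zero-run condition can possibly fire
        index = pd.date_range("2000-05-01", "2000-10-31", freq="D")
        vals = np.full(len(index), 100.0)
        vals[50:50 + n_zero] = 0.0
        store = rs.CumulativeStore(drawdown=3.0,
                                   values=pd.Series(vals, index=index))
        spells = rs.detect_dry_spells(store)
        assert bool(spells) is fires
        if fires:
            assert spells[0].rule_id == 1 and spells[0].length_days == 6

    def test_increment_balance_mode_differs_from_store_mode(self):
        ser = series_from_events(events=[(5, 1, 20.0)])
        params = rs.RuleParams(balance_mode="increment")
        inc = spells_for(ser, params)
        store = spells_for(ser)
        assert inc  # fires as well
        assert (inc[0].start, inc[0].end) != (store[0].start, store[0].end)


# ---------------------------------------------------------------------------
# core season onset / end
# ---------------------------------------------------------------------------

class TestCoreSeason:
    def test_sustained_rain_onset_ten_days_after_first_rain(self):
        ser = series_from_events(events=[((7, 1), (10, 31), 13.0)])
        dec = rs.decompose_season(ser)
        assert dec.season.onset_first_rain == ts(2000, 7, 1)
        assert dec.season.onset_core == ts(2000, 7, 11)

    def test_onset_follows_last_pre_august_dry_spell(self):
        # first rain in June, drought, heavy rain resumes 9 Aug
        ser = series_from_events(events=[
            (6, 20, 25.0), ((8, 9), (10, 31), 20.0)])
        dec = rs.decompose_season(ser)
        assert dec.season.onset_first_rain == ts(2000, 6, 20)
        assert dec.season.onset_core == ts(2000, 8, 9)

    def test_first_rain_after_cutoff_gives_no_core_season(self):
        ser = series_from_events(events=[(8, 20, 15.0), (9, 20, 15.0)])
        dec = rs.decompose_season(ser)
        assert dec.season.onset_core is None
        assert dec.flag.startswith("no_core_season")
        assert dec.rainfall_C == 0.0
        assert dec.rainfall_EL == pytest.approx(dec.annual)

    def test_end_is_last_rain_without_post_cutoff_spell(self):
        ser = series_from_events(events=[((7, 1), (9, 20), 13.0)])
        dec = rs.decompose_season(ser)
        assert dec.season.last_rain == ts(2000, 9, 20)
        assert dec.season.end_core == ts(2000, 9, 20)

    def test_end_is_day_before_post_cutoff_dry_spell(self):
        # moderate rain through 20 Aug (store drains by mid Sep), long
        # gap, then a late storm 10 Oct: the gap is a dry spell between
        # the cutoff and the last rain, so the season ends before it
        ser = series_from_events(events=[
            ((7, 20), (8, 20), 5.5), (10, 10, 25.0)])
        dec = rs.decompose_season(ser)
        assert dec.season.last_rain == ts(2000, 10, 10)
        spell_starts = [sp.start for sp in dec.dry_spells
                        if sp.start >= ts(2000, 8, 15)]
        assert spell_starts, "a post-cutoff dry spell must exist"
        assert dec.season.end_core == min(spell_starts) - pd.Timedelta(days=1)
        assert dec.season.end_core >= ts(2000, 8, 15)

    def test_last_rain_convention_for_core_end(self):
        ser = series_from_events(events=[
            ((7, 20), (8, 20), 5.5), (10, 10, 25.0)])
        params = rs.RuleParams(end_convention="last_rain")
        dec = rs.decompose_season(ser, params)
        assert dec.season.end_core == ts(2000, 10, 10)


# ---------------------------------------------------------------------------
# full decomposition
# ---------------------------------------------------------------------------

class TestDecomposeSeason:
    def test_all_zero_year(self):
        dec = rs.decompose_season(make_series())
        assert dec.rainfall_C == 0.0 and dec.rainfall_EL == 0.0
        assert dec.annual == 0.0
        assert not dec.season.complete

    def test_toy_year_hand_simulation(self):
        """12 mm on 15 Jun; 8 mm/day 1 Jul-20 Sep; 13 mm on 5 Oct —
        every date and component verified by hand against the rules."""
        ser = series_from_events(events=[
            (6, 15, 12.0), ((7, 1), (9, 20), 8.0), (10, 5, 13.0)])
        dec = rs.decompose_season(ser)
        assert dec.season.onset_first_rain == ts(2000, 6, 15)
        assert dec.season.onset_core == ts(2000, 7, 2)
        assert dec.season.last_rain == ts(2000, 10, 5)
        assert dec.season.end_core == ts(2000, 10, 5)
        assert dec.annual == pytest.approx(12 + 8 * 82 + 13)
        assert dec.rainfall_C == pytest.approx(8 * 81 + 13)
        assert dec.rainfall_EL == pytest.approx(20.0)
        # the two dry spells: May drought (30-day condition envelope
        # reaching the first-rain day) and the post-first-rain gap
        assert [sp.rule_id for sp in dec.dry_spells] == [5, 2]
        assert dec.dry_spells[1].start == ts(2000, 6, 17)
        assert dec.dry_spells[1].end == ts(2000, 7, 1)

    def test_monotonicity_extra_core_rain_goes_to_c(self):
        events = [(6, 15, 12.0), ((7, 1), (9, 20), 8.0), (10, 5, 13.0)]
        base = rs.decompose_season(series_from_events(events=events))
        more = rs.decompose_season(series_from_events(
            events=events + [(8, 1, 13.0)]))
        assert more.rainfall_C == pytest.approx(base.rainfall_C + 5.0)
        assert more.rainfall_EL == pytest.approx(base.rainfall_EL)

    def test_leap_year_cutoffs(self):
        ser = series_from_events(year=2004, events=[((7, 1), (9, 20), 13.0)])
        dec = rs.decompose_season(ser)
        assert dec.season.onset_core == ts(2004, 7, 11)
        assert dec.season.end_core == ts(2004, 9, 20)
        assert dec.rainfall_C + dec.rainfall_EL == pytest.approx(dec.annual)


# ---------------------------------------------------------------------------
# fixed-window variant
# ---------------------------------------------------------------------------

class TestFixedWindow:
    def test_uniform_rain_default_window(self):
        dec = rs.decompose_fixed_window(make_series(rain=np.ones(184)))
        assert dec.rainfall_C == pytest.approx(41.0)
        assert dec.rainfall_EL == pytest.approx(184.0 - 41.0)

    def test_all_rain_inside_window_gives_zero_el(self):
        ser = series_from_events(events=[((8, 1), (8, 20), 5.0)])
        dec = rs.decompose_fixed_window(ser)
        assert dec.rainfall_EL == pytest.approx(0.0)

    def test_toy_year_shoulder_arithmetic(self):
        # rule-based C covers 2 Jul-5 Oct; the fixed window only DOY
        # 204-244 (22 Jul-31 Aug in 2000, a leap year): difference is the
        # hand-computable shoulder sums
        ser = series_from_events(events=[
            (6, 15, 12.0), ((7, 1), (9, 20), 8.0), (10, 5, 13.0)])
        dec = rs.decompose_fixed_window(ser)
        assert dec.rainfall_C == pytest.approx(41 * 8.0)
        assert dec.rainfall_EL == pytest.approx(dec.annual - 41 * 8.0)

    def test_window_outside_season_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            dec = rs.decompose_fixed_window(make_series(rain=np.ones(184)),
                                            start_doy=100, end_doy=140)
        assert dec.rainfall_C == pytest.approx(19.0)  # 1 May = DOY 122 in 2000

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            rs.decompose_fixed_window(make_series(), start_doy=200, end_doy=100)


# ---------------------------------------------------------------------------
# oracle equivalence + conservation
# ---------------------------------------------------------------------------

def fixture_years():
    """>= 20 constructed years spanning no-onset, late-onset, boundary
    thresholds, multiple dry spells and dense monsoon shapes."""
    cases = [
        ("all_zero", []),
        ("single_12mm", [(6, 1, 12.0)]),
        ("single_11.9mm", [(6, 1, 11.9)]),
        ("five_day_20.0", [((6, 10), (6, 14), 4.0)]),
        ("five_day_22.5", [((6, 10), (6, 14), 4.5)]),
        ("sustained_jul", [((7, 1), (10, 31), 13.0)]),
        ("toy_year", [(6, 15, 12.0), ((7, 1), (9, 20), 8.0), (10, 5, 13.0)]),
        ("late_onset", [(8, 20, 15.0), (9, 20, 15.0)]),
        ("post_cutoff_spell", [((6, 25), (8, 31), 6.0), (10, 10, 25.0)]),
        ("two_gaps", [(5, 1, 20.0), (5, 17, 20.0), ((6, 2), (10, 31), 10.0)]),
        ("exact_12_last", [(7, 1, 30.0), (9, 30, 12.0)]),
        ("above_12_last", [(7, 1, 30.0), (9, 30, 12.1)]),
        ("storm_then_dry", [(5, 1, 20.0)]),
        ("short_core", [((7, 20), (8, 25), 9.0)]),
        ("double_peak", [((6, 10), (7, 5), 7.0), ((8, 1), (9, 10), 7.0)]),
        ("late_heavy_oct31", [((7, 1), (9, 1), 8.0), (10, 31, 14.0)]),
        ("constant_3mm", []),          # handled below with base
        ("constant_4mm", []),
        ("spotty", [(5, 20, 13.0), (6, 18, 14.0), (7, 14, 16.0),
                     (8, 2, 18.0), (8, 29, 13.0), (9, 25, 15.0)]),
        ("ramp", []),                  # handled below
    ]
    out = []
    for name, events in cases:
        if name == "constant_3mm":
            ser = make_series(rain=np.full(184, 3.0))
        elif name == "constant_4mm":
            ser = make_series(rain=np.full(184, 4.0))
        elif name == "ramp":
            ser = make_series(rain=np.linspace(0, 12, 184))
        else:
            ser = series_from_events(events=events)
        out.append((name, ser))
    # leap-year variants of two interesting shapes
    out.append(("toy_year_leap", series_from_events(
        year=2004, events=[(6, 15, 12.0), ((7, 1), (9, 20), 8.0),
                           (10, 5, 13.0)])))
    out.append(("sustained_leap", series_from_events(
        year=2004, events=[((7, 1), (10, 31), 13.0)])))
    return out


@pytest.mark.parametrize("name,ser", fixture_years(),
                         ids=[n for n, _ in fixture_years()])
def test_oracle_equivalence_constructed_years(name, ser):
    """The vectorised decomposition matches the straight-line reference,
    date for date and mm for mm."""
    dec = rs.decompose_season(ser)
    window = ser.season_window()
    ref = oracle_decompose(ser.year, list(window.to_numpy()))

    def as_idx(ts_):
        return None if ts_ is None else int(window.index.get_loc(ts_))

    assert as_idx(dec.season.onset_first_rain) == ref["first"]
    assert as_idx(dec.season.onset_core) == ref["onset"]
    assert as_idx(dec.season.end_core) == ref["end"]
    assert as_idx(dec.season.last_rain) == ref["last"]
    assert [(as_idx(sp.start), as_idx(sp.end), sp.rule_id)
            for sp in dec.dry_spells] == ref["spells"]
    assert dec.rainfall_C == pytest.approx(ref["rainfall_C"], abs=1e-9)
    assert dec.rainfall_EL == pytest.approx(ref["rainfall_EL"], abs=1e-9)


def test_oracle_equivalence_random_years():
    """Random monsoon-like years agree with the reference as well."""
    rng = np.random.default_rng(123)
    doy = pd.date_range("2001-05-01", "2001-10-31").dayofyear.to_numpy()
    bell = np.exp(-0.5 * ((doy - 224) / 30.0) ** 2)
    for _ in range(25):
        wet = rng.random(184) < 0.15 + 0.6 * bell
        rain = np.where(wet, rng.gamma(0.9, 9.0, 184), 0.0)
        ser = make_series(year=2001, rain=rain)
        dec = rs.decompose_season(ser)
        ref = oracle_decompose(2001, list(rain))
        assert dec.rainfall_C == pytest.approx(ref["rainfall_C"], abs=1e-9)
        window = ser.season_window()
        for got, want in (
            (dec.season.onset_core, ref["onset"]),
            (dec.season.end_core, ref["end"]),
        ):
            got_i = None if got is None else int(window.index.get_loc(got))
            assert got_i == want


@given(st.lists(st.floats(0, 80), min_size=184, max_size=184))
@settings(max_examples=40, deadline=None)
def test_conservation_property(rain):
    """rainfall_C + rainfall_EL always equals the May-Oct sum."""
    dec = rs.decompose_season(make_series(rain=rain))
    assert dec.rainfall_C + dec.rainfall_EL == pytest.approx(dec.annual,
                                                             abs=1e-6)
    assert dec.rainfall_C >= 0 and dec.rainfall_EL >= -1e-9
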
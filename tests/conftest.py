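from datetime import date

import numpy as np
import pandas as pd
import pytest

from sahelveg.rainseason import DailyRainfallSeries
from sahelveg.synthetic import SyntheticConfig


def make_series(year=2000, rain=None, site="t", **events):
    """Build a May-Oct DailyRainfallSeries.

    ``rain``: full 184/185-value array, or None for all-zero.
    ``events``: ignored; use ``add_events`` for date->mm placement.
    """
    index = pd.date_range(date(year, 5, 1), date(year, 10, 31), freq="D")
    if rain is None:
        rain = np.zeros(len(index))
    else:
        rain = np.asarray(rain, dtype=float)
        if len(rain) != len(index):
            raise ValueError(f"need {len(index)} daily values")
    return DailyRainfallSeries(site=site, year=year,
                               values=pd.Series(rain, index=index))


def series_from_events(year=2000, events=(), base=0.0, site="t"):
    """Series with ``base`` mm/day everywhere and (month, day, mm) or
    ((month, day), (month, day), mm) range events overriding it."""
    index = pd.date_range(date(year, 5, 1), date(year, 10, 31), freq="D")
    rain = np.full(len(index), float(base))
    for ev in events:
        if len(ev) == 3 and isinstance(ev[0], tuple):
            (m1, d1), (m2, d2), mm = ev
            sel = slice(pd.Timestamp(date(year, m1, d1)),
                        pd.Timestamp(date(year, m2, d2)))
            rain[index.get_loc(sel.start):index.get_loc(sel.stop) + 1] = mm
        else:
            m, d, mm = ev
            rain[index.get_loc(pd.Timestamp(date(year, m, d)))] = mm
    return DailyRainfallSeries(site=site, year=year,
                               values=pd.Series(rain, index=index))


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def small_config():
    """Cheaper scene for tests that only need structure, not power."""
    return SyntheticConfig(n_sites=3, year_start=1995, year_end=2010, seed=7)
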
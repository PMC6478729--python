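"""Independent straight-line reference implementation of the rainfall
decomposition rules, used only as a test oracle.

Deliberately naive: plain Python loops over ``datetime.date`` and lists,
O(n*window) sliding scans, day-coverage marking instead of envelope
merging. Shares no code with ``sahelveg.rainseason``.
"""

from datetime import date, timedelta

ZERO = 1e-12


def _days(year):
    d0 = date(year, 5, 1)
    n = (date(year, 10, 31) - d0).days + 1
    return [d0 + timedelta(days=i) for i in range(n)]


def _store(rain, drawdown):
    out = []
    level = 0.0
    for r in rain:
        level = level + r - drawdown
        if level < 0.0:
            level = 0.0
        out.append(level)
    return out


def _rule_envelopes(vals, length, thresh):
    """Maximal runs of days covered by any qualifying window of one rule.
    ``thresh is None`` means the all-zero condition."""
    n = len(vals)
    covered = [False] * n
    for s in range(n - length + 1):
        win = vals[s:s + length]
        if thresh is None:
            ok = all(v <= ZERO for v in win)
        else:
            ok = sum(win) < thresh
        if ok:
            for i in range(s, s + length):
                covered[i] = True
    envs = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j + 1 < n and covered[j + 1]:
                j += 1
            envs.append((i, j))
            i = j + 1
        else:
            i += 1
    return envs


def oracle_dry_spells(cr3):
    """(start_idx, end_idx, rule_id) per overlap cluster; the longest
    envelope prevails (ties: earlier start, then longer base window)."""
    rules = [(1, 6, None), (2, 12, 6.0), (3, 18, 9.0), (4, 24, 12.0),
             (5, 30, 15.0)]
    cands = []
    for rule_id, length, thresh in rules:
        for s, e in _rule_envelopes(cr3, length, thresh):
            cands.append((s, e, rule_id, length))
    cands.sort(key=lambda c: (c[0], c[1]))
    clusters = []
    for c in cands:
        if clusters and c[0] <= max(x[1] for x in clusters[-1]):
            clusters[-1].append(c)
        else:
            clusters.append([c])
    spells = []
    for cl in clusters:
        best = None
        for s, e, rid, base in cl:
            key = (e - s, -s, base)
            if best is None or key > best[0]:
                best = (key, (s, e, rid))
        spells.append(best[1])
    return spells


def oracle_decompose(year, rain):
    """Full decomposition of one May-Oct year. ``rain`` is a list of daily
    mm, first element 1 May. Returns a dict of indices (into the May-Oct
    day list; None when absent) and the rainfall components."""
    days = _days(year)
    n = len(days)
    assert len(rain) == n
    aug15 = days.index(date(year, 8, 15))
    cr5 = _store(rain, 5.0)
    cr3 = _store(rain, 3.0)

    # --- onset of first rain ---
    first = None
    for i in range(n):
        if rain[i] >= 12.0:
            first = i
            break
    for s in range(n - 4):
        if sum(rain[s:s + 5]) > 20.0:
            for i in range(s, s + 5):
                if rain[i] > 0:
                    if first is None or i < first:
                        first = i
                    break
            break
    # --- last rain ---
    last = None
    for i in range(aug15, n):
        if rain[i] > 12.0:
            last = i
    for s in range(n - 4):
        if sum(rain[s:s + 5]) > 20.0:
            lw = None
            for i in range(s, s + 5):
                if rain[i] > 0:
                    lw = i
            if lw is not None and lw >= aug15 and (last is None or lw > last):
                last = lw

    spells = oracle_dry_spells(cr3)

    # --- onset of core wet season (before 15 Aug) ---
    onset = None
    if first is not None:
        between = [sp for sp in spells if first < sp[0] < aug15]
        if between:
            search = max(sp[1] for sp in between) + 1
        else:
            search = first + 10
        for i in range(search, n):
            if cr5[i] > 0:
                if i < aug15:
                    onset = i
                break
    # --- end of core wet season (on/after 15 Aug) ---
    end = None
    if last is not None and last >= aug15:
        blocking = [sp for sp in spells if aug15 <= sp[0] <= last]
        if blocking:
            earliest = min(sp[0] for sp in blocking)
            end = max(earliest - 1, aug15)
        else:
            end = last

    annual = sum(rain)
    if None not in (first, onset, end, last) and onset <= end:
        rainfall_c = sum(rain[onset:end + 1])
    else:
        rainfall_c = 0.0
    return {
        "first": first, "onset": onset, "end": end, "last": last,
        "spells": spells, "rainfall_C": rainfall_c,
        "rainfall_EL": annual - rainfall_c, "annual": annual,
    }
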
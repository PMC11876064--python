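"""Independent brute-force oracles used across the test suite.

Everything here is written as plain per-second / per-cell Python loops with
no reuse of the package's vectorised implementations, so agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

DAY_S = 86400


def brute_cumulative(timestamps, levels, utc_offset_s=0):
    """Per-second loop computation of Ldn, Lden, Lnight, Leq24, hourly Leq, L95."""
    e_dn = e_den = e_tot = 0.0
    e_night = 0.0
    n = 0
    n_night = 0
    hour_e = [0.0] * 24
    hour_n = [0] * 24
    for ts, lv in zip(timestamps, levels):
        sod = (int(ts) + utc_offset_s) % DAY_S
        night = sod >= 22 * 3600 or sod < 7 * 3600
        evening = 19 * 3600 <= sod < 22 * 3600
        e = 10.0 ** (lv / 10.0)
        e_tot += e
        e_dn += 10.0 ** ((lv + (10.0 if night else 0.0)) / 10.0)
        pen = 10.0 if night else (5.0 if evening else 0.0)
        e_den += 10.0 ** ((lv + pen) / 10.0)
        if night:
            e_night += e
            n_night += 1
        h = sod // 3600
        hour_e[h] += e
        hour_n[h] += 1
        n += 1
    out = {
        "ldn": 10.0 * math.log10(e_dn / n),
        "lden": 10.0 * math.log10(e_den / n),
        "leq24": 10.0 * math.log10(e_tot / n),
        "lnight": (
            10.0 * math.log10(e_night / n_night) if n_night else None
        ),
        "hourly": [
            10.0 * math.log10(hour_e[h] / hour_n[h]) if hour_n[h] else None
            for h in range(24)
        ],
        "l95": brute_percentile(levels, 5.0),
    }
    return out


def brute_percentile(values, q):
    """Nearest-rank percentile by explicit sort."""
    arr = sorted(float(v) for v in values)
    k = max(1, math.ceil(q / 100.0 * len(arr)))
    return arr[k - 1]


def brute_dose(levels, criterion_level, criterion_duration_h, exchange_rate, cutoff):
    dose = 0.0
    for lv in levels:
        if lv >= cutoff:
            t_allowed = criterion_duration_h * 2.0 ** (
                (criterion_level - lv) / exchange_rate
            )
            dose += (1.0 / 3600.0) / t_allowed
    return dose * 100.0


def brute_exposed(pop_values, surf_values, surf_mask, threshold):
    """Per-cell loop population at/above a threshold level."""
    total = 0.0
    nrows, ncols = pop_values.shape
    for r in range(nrows):
        for c in range(ncols):
            if not surf_mask[r, c] and surf_values[r, c] >= threshold:
                total += pop_values[r, c]
    return total


def brute_outcome(pop_values, surf_values, surf_mask, response_fn):
    """Per-cell loop of response(level)/100 * population."""
    total = 0.0
    nrows, ncols = pop_values.shape
    for r in range(nrows):
        for c in range(ncols):
            if not surf_mask[r, c]:
                total += response_fn(surf_values[r, c]) / 100.0 * pop_values[r, c]
    return total


def random_gapped_series(rng, n_min=600, n_max=3000):
    """Random timestamps (with gaps) and levels for oracle comparisons."""
    n = int(rng.integers(n_min, n_max))
    start = int(rng.integers(0, 30 * DAY_S))
    ts = start + np.sort(
        rng.choice(np.arange(int(n * 1.2)), size=n, replace=False)
    ).astype(np.int64)
    levels = rng.uniform(20.0, 100.0, size=n)
    offset = int(rng.choice([-28800, -25200, 0, 3600]))
    return ts, levels, offset
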
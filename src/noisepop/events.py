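"""Aircraft overflight event detection from 1-Hz SPL series.

The detector follows standard sound-monitoring practice for aircraft noise:

1. a 10-s centred moving energy average smooths the 1-s signal;
2. an adaptive threshold is formed each second as the residual-sound estimate
   (L95 of the surrounding +/-30-min window) plus a 15 dB margin, floored at a
   50 dB baseline (35 dB ambient + 15 dB margin);
3. an event starts when the smoothed level exceeds the threshold and ends
   when it has remained below it for 5 consecutive seconds (data gaps always
   terminate an event);
4. detections whose raw 1-s maximum is not at least the margin above the
   residual level are discarded;
5. detections containing multiple peaks separated by a sufficiently deep dip
   (a prominence criterion) are subdivided at the minimum between peaks, so
   rapid flybys and simultaneous aircraft yield one event per peak.

Event metrics (LE/SEL, Lmax, optional LFmax and LCpeak, onset rate) are
always computed on the raw, unsmoothed series: smoothing attenuates true
maxima and is used for detection only.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .metrics import db_to_energy, energy_sum, energy_to_db
from .series import SplSeries


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the event detector.

    ``floor_db`` is by construction ``baseline_ambient_db + margin_db``;
    the constructor enforces this.
    """

    smoothing_window_s: int = 10
    termination_gap_s: int = 5
    margin_db: float = 15.0
    baseline_ambient_db: float = 35.0
    l95_window_min: int = 60
    subdivision_prominence_db: float = 6.0
    #: "l95_plus_margin" -> max(L95 + margin, floor);
    #: "l95_or_floor"    -> max(L95, floor)
    threshold_mode: str = "l95_plus_margin"
    #: "centered" or "trailing" moving-average alignment
    smoothing_alignment: str = "centered"

    @property
    def floor_db(self) -> float:
        return self.baseline_ambient_db + self.margin_db

    def __post_init__(self) -> None:
        if self.smoothing_window_s < 1:
            raise ValueError("smoothing_window_s must be >= 1")
        if self.threshold_mode not in ("l95_plus_margin", "l95_or_floor"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.smoothing_alignment not in ("centered", "trailing"):
            raise ValueError(f"unknown alignment {self.smoothing_alignment!r}")


@dataclass(frozen=True)
class AcousticEvent:
    """One detected overflight.

    ``start``/``end`` are the first and last epoch seconds at which the
    smoothed level exceeded the detection threshold (inclusive).
    """

    start: int
    end: int
    le: float
    lmax: float
    onset_rate: float
    lfmax: float | None = None
    lcpeak: float | None = None
    threshold_at_peak: float = math.nan
    verified: bool = False

    @property
    def duration_s(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------

def smooth(series: SplSeries, window_s: int, alignment: str = "centered") -> SplSeries:
    """Moving energy average over ``window_s`` seconds.

    Centred alignment places an even window as ``[t - w//2, t + w - 1 - w//2]``;
    trailing uses ``[t - w + 1, t]``.  Edges and gaps use whatever samples are
    present in the window, so output timestamps equal input timestamps.
    """
    if window_s < 1:
        raise ValueError("window_s must be >= 1")
    ts = series.timestamps
    if alignment == "centered":
        lo_off, hi_off = window_s // 2, window_s - 1 - window_s // 2
    else:
        lo_off, hi_off = window_s - 1, 0
    left = np.searchsorted(ts, ts - lo_off, side="left")
    right = np.searchsorted(ts, ts + hi_off, side="right")
    csum = np.concatenate([[0.0], np.cumsum(db_to_energy(series.levels))])
    mean_energy = (csum[right] - csum[left]) / (right - left)
    return replace(series, levels=np.asarray(energy_to_db(mean_energy)))


def rolling_l95(series: SplSeries, half_window_s: int = 1800) -> np.ndarray:
    """Per-second residual-sound estimate.

    Nearest-rank 5th percentile of the levels within ``+/- half_window_s``
    of each sample (the L95 of the surrounding hour by default), maintained
    exactly with a sorted sliding window.
    """
    ts = series.timestamps
    lv = series.levels
    n = len(ts)
    out = np.empty(n)
    window: list[float] = []
    lo = hi = 0
    for i in range(n):
        t = ts[i]
        while hi < n and ts[hi] <= t + half_window_s:
            insort(window, lv[hi])
            hi += 1
        while ts[lo] < t - half_window_s:
            del window[bisect_left(window, lv[lo])]
            lo += 1
        k = max(1, math.ceil(0.05 * len(window)))
        out[i] = window[k - 1]
    return out


def detection_threshold_series(
    series: SplSeries, config: DetectionConfig | None = None
) -> np.ndarray:
    """Adaptive detection threshold for every sample of the series."""
    config = config or DetectionConfig()
    l95 = rolling_l95(series, half_window_s=config.l95_window_min * 60 // 2)
    if config.threshold_mode == "l95_plus_margin":
        return np.maximum(l95 + config.margin_db, config.floor_db)
    return np.maximum(l95, config.floor_db)


def detection_threshold(
    series: SplSeries, t: int, config: DetectionConfig | None = None
) -> float:
    """Detection threshold at time ``t`` (floor with a warning off-support)."""
    config = config or DetectionConfig()
    half = config.l95_window_min * 60 // 2
    sub = series.slice(t - half, t + half + 1)
    if len(sub) == 0:
        import logging

        logging.getLogger(__name__).warning(
            "no samples within +/-%d s of t=%d; using floor %.1f dB",
            half, t, config.floor_db,
        )
        return config.floor_db
    l95 = float(np.sort(sub.levels)[max(1, math.ceil(0.05 * len(sub))) - 1])
    if config.threshold_mode == "l95_plus_margin":
        return max(l95 + config.margin_db, config.floor_db)
    return max(l95, config.floor_db)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def event_metrics(
    raw: SplSeries,
    window: tuple[int, int],
    fast: SplSeries | None = None,
    cpeak: SplSeries | None = None,
    threshold_at_peak: float = math.nan,
) -> AcousticEvent:
    """Compute per-event metrics over ``window = (start_ts, end_ts)`` inclusive.

    ``le`` is the sound exposure level (1-s reference): the energy sum of the
    in-event 1-s levels.  ``lmax`` is the maximum raw 1-s level.  The onset
    rate is ``(lmax - level at start) / (t_peak - t_start)`` in dB/s, zero for
    an event peaking at its first second.
    """
    start, end = window
    sub = raw.slice(start, end + 1)
    if len(sub) == 0:
        raise ValueError(f"event window [{start}, {end}] contains no samples")
    le = energy_sum(sub.levels)
    ipk = int(np.argmax(sub.levels))
    lmax = float(sub.levels[ipk])
    t_peak = int(sub.timestamps[ipk])
    t0 = int(sub.timestamps[0])
    onset_rate = (lmax - float(sub.levels[0])) / (t_peak - t0) if t_peak > t0 else 0.0

    def _channel_max(chan: SplSeries | None) -> float | None:
        if chan is None:
            return None
        csub = chan.slice(start, end + 1)
        return float(csub.levels.max()) if len(csub) else None

    return AcousticEvent(
        start=int(sub.timestamps[0]),
        end=int(sub.timestamps[-1]),
        le=le,
        lmax=lmax,
        onset_rate=onset_rate,
        lfmax=_channel_max(fast),
        lcpeak=_channel_max(cpeak),
        threshold_at_peak=threshold_at_peak,
    )


def _above_runs(series: SplSeries, above: np.ndarray, gap_s: int) -> list[tuple[int, int]]:
    """Index runs of above-threshold samples.

    Runs separated by fewer than ``gap_s`` below-threshold seconds merge; any
    missing second (data gap) terminates a run unconditionally.
    """
    ts = series.timestamps
    idx = np.nonzero(above)[0]
    runs: list[tuple[int, int]] = []
    for i in idx:
        if not runs:
            runs.append((i, i))
            continue
        s, e = runs[-1]
        contiguous = ts[i] - ts[e] == i - e  # no missing seconds between
        if contiguous and ts[i] - ts[e] - 1 < gap_s:
            runs[-1] = (s, i)
        else:
            runs.append((i, i))
    return runs


def _subdivide(sm_levels: np.ndarray, prominence_db: float) -> list[tuple[int, int]]:
    """Split a run's local index span at minima between prominent peaks."""
    n = len(sm_levels)
    peaks, _ = find_peaks(sm_levels, prominence=prominence_db)
    if len(peaks) < 2:
        return [(0, n - 1)]
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        m = a + int(np.argmin(sm_levels[a : b + 1]))
        bounds.append(m)
    bounds.append(n - 1)
    spans = []
    for j in range(len(bounds) - 1):
        lo = bounds[j] if j == 0 else bounds[j] + 1
        hi = bounds[j + 1] if j == len(bounds) - 2 else bounds[j + 1]
        if hi >= lo:
            spans.append((lo, hi))
    return spans


def detect_events(
    series: SplSeries,
    config: DetectionConfig | None = None,
    fast: SplSeries | None = None,
    cpeak: SplSeries | None = None,
) -> list[AcousticEvent]:
    """Detect overflight events in a 1-Hz series.

    Returns non-overlapping events ordered by start time.  Deterministic:
    identical input and config yield an identical event list.
    """
    config = config or DetectionConfig()
    if len(series) < max(60, config.smoothing_window_s):
        raise ValueError("series too short for event detection (need >= 60 s)")
    sm = smooth(series, config.smoothing_window_s, config.smoothing_alignment)
    l95 = rolling_l95(series, half_window_s=config.l95_window_min * 60 // 2)
    if config.threshold_mode == "l95_plus_margin":
        thr = np.maximum(l95 + config.margin_db, config.floor_db)
    else:
        thr = np.maximum(l95, config.floor_db)
    above = sm.levels > thr

    events: list[AcousticEvent] = []
    for i0, i1 in _above_runs(series, above, config.termination_gap_s):
        for lo, hi in _subdivide(
            sm.levels[i0 : i1 + 1], config.subdivision_prominence_db
        ):
            a, b = i0 + lo, i0 + hi
            window = (int(series.timestamps[a]), int(series.timestamps[b]))
            sub_lv = series.levels[a : b + 1]
            ipk = a + int(np.argmax(sub_lv))
            # ISO-style validity check: raw maximum must clear residual+margin
            if series.levels[ipk] < l95[ipk] + config.margin_db:
                continue
            events.append(
                event_metrics(
                    series,
                    window,
                    fast=fast,
                    cpeak=cpeak,
                    threshold_at_peak=float(thr[ipk]),
                )
            )
    return events
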
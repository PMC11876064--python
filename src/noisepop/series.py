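"""Sound-level time-series containers.

A :class:`SplSeries` holds a nominally 1-Hz sequence of sound pressure levels
(dB re 20 µPa) for one monitoring location.  Missing seconds are simply absent
from the timestamp vector — they are never zero-filled, because 0 dB is a
level, not the absence of one.  Hour-of-day classification (day / evening /
night penalties) uses the local civil time obtained by adding the stored
UTC offset to the epoch timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: seconds in a day
DAY_S = 86400

#: half-open local-time period boundaries, seconds after local midnight
NIGHT_START_S = 22 * 3600   # 22:00
NIGHT_END_S = 7 * 3600      # 07:00
EVENING_START_S = 19 * 3600  # 19:00

FREQ_WEIGHTINGS = ("A", "C", "Z")
TIME_WEIGHTINGS = ("eq_1s", "fast_max", "peak")


@dataclass(frozen=True)
class SplSeries:
    """A 1-Hz sound-level time series.

    Parameters
    ----------
    location_id : str
        Monitoring-location identifier.
    timestamps : ndarray of int64
        Seconds since the UNIX epoch; strictly increasing.  Gaps are allowed.
    levels : ndarray of float64
        Sound level in dB for each timestamp; must be finite.
    freq_weighting : {"A", "C", "Z"}
    time_weighting : {"eq_1s", "fast_max", "peak"}
    utc_offset_s : int
        Local civil time offset in seconds (e.g. -28800 for UTC-8).  Used for
        all hour-of-day classification.
    """

    location_id: str
    timestamps: np.ndarray
    levels: np.ndarray
    freq_weighting: str = "A"
    time_weighting: str = "eq_1s"
    utc_offset_s: int = 0

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=np.int64)
        lv = np.asarray(self.levels, dtype=np.float64)
        if ts.ndim != 1 or lv.ndim != 1 or ts.size != lv.size:
            raise ValueError("timestamps and levels must be 1-D and equal length")
        if ts.size and np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(lv)):
            raise ValueError("levels must be finite")
        if self.freq_weighting not in FREQ_WEIGHTINGS:
            raise ValueError(f"freq_weighting must be one of {FREQ_WEIGHTINGS}")
        if self.time_weighting not in TIME_WEIGHTINGS:
            raise ValueError(f"time_weighting must be one of {TIME_WEIGHTINGS}")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "levels", lv)

    def __len__(self) -> int:
        return int(self.timestamps.size)

    # -- local-time helpers -------------------------------------------------

    def local_second_of_day(self) -> np.ndarray:
        """Second-of-day in local civil time, in [0, 86400)."""
        return (self.timestamps + self.utc_offset_s) % DAY_S

    def local_hour(self) -> np.ndarray:
        """Local clock hour (0-23) of every sample."""
        return self.local_second_of_day() // 3600

    def is_night(self) -> np.ndarray:
        """True for samples in the 22:00-07:00 night period (half-open)."""
        sod = self.local_second_of_day()
        return (sod >= NIGHT_START_S) | (sod < NIGHT_END_S)

    def is_evening(self) -> np.ndarray:
        """True for samples in the 19:00-22:00 evening period (half-open)."""
        sod = self.local_second_of_day()
        return (sod >= EVENING_START_S) & (sod < NIGHT_START_S)

    # -- coverage / gaps ----------------------------------------------------

    def coverage_fraction(self, expected_s: int | None = None) -> float:
        """Fraction of expected seconds actually present.

        ``expected_s`` defaults to the spanned duration (last - first + 1).
        """
        if len(self) == 0:
            return 0.0
        span = int(self.timestamps[-1] - self.timestamps[0]) + 1
        expected = span if expected_s is None else int(expected_s)
        return len(self) / expected

    def gaps(self) -> list[tuple[int, int]]:
        """Missing intervals as (first_missing_ts, last_missing_ts) pairs."""
        d = np.diff(self.timestamps)
        idx = np.nonzero(d > 1)[0]
        return [
            (int(self.timestamps[i]) + 1, int(self.timestamps[i + 1]) - 1)
            for i in idx
        ]

    def slice(self, start: int, end: int) -> "SplSeries":
        """Samples with start <= timestamp < end (half-open)."""
        i0, i1 = np.searchsorted(self.timestamps, [start, end])
        return replace(
            self, timestamps=self.timestamps[i0:i1], levels=self.levels[i0:i1]
        )


@dataclass(frozen=True)
class SpectrumSeries:
    """One-third-octave-band Z-weighted level time series.

    ``levels`` is a (seconds x bands) matrix aligned with ``timestamps``.
    """

    location_id: str
    timestamps: np.ndarray
    band_centers: np.ndarray = field(default_factory=lambda: np.array([]))
    levels: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=np.int64)
        bc = np.asarray(self.band_centers, dtype=np.float64)
        lv = np.asarray(self.levels, dtype=np.float64)
        if bc.ndim != 1 or np.any(bc <= 0) or np.any(np.diff(bc) <= 0):
            raise ValueError("band_centers must be positive and increasing")
        if lv.shape != (ts.size, bc.size):
            raise ValueError("levels must be (n_timestamps, n_bands)")
        if ts.size and np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "band_centers", bc)
        object.__setattr__(self, "levels", lv)

    def __len__(self) -> int:
        return int(self.timestamps.size)
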
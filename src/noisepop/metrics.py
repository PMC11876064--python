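"""Single-event, cumulative and occupational-dose acoustic metrics.

All decibel arithmetic happens in the energy domain (``10**(L/10)``) in double
precision with no intermediate rounding, so every metric here agrees with a
naive per-second loop to floating-point accuracy.

Cumulative metrics follow the conventional community-noise definitions:

* ``Ldn`` — 24-h energy average with a +10 dB penalty on 22:00-07:00,
* ``Lden`` — as Ldn plus a +5 dB penalty on 19:00-22:00,
* ``Lnight`` — unpenalised energy average over 22:00-07:00 only,
* ``LeqH`` — energy average over an arbitrary interval,
* ``L95`` — the level exceeded 95 % of the time (nearest-rank percentile),
* ``Ldnmr`` — energy average of monthly Ldn values, with a pluggable
  onset-rate penalty hook that defaults to zero.

Metrics are computed over the seconds actually present; a coverage fraction
is carried alongside so sparse series are detectable rather than silently
renormalised.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .series import DAY_S, SplSeries, SpectrumSeries

logger = logging.getLogger(__name__)

#: default warning threshold for missing data
DEFAULT_MIN_COVERAGE = 0.9

#: configurable substitute for -inf when synthesizing / renormalising
DEFAULT_SILENCE_FLOOR_DB = 0.0


class CoverageWarning(UserWarning):
    """Raised (as a warning) when an interval has less data than required."""


# ---------------------------------------------------------------------------
# energy-domain primitives
# ---------------------------------------------------------------------------

def db_to_energy(levels) -> np.ndarray:
    return np.power(10.0, np.asarray(levels, dtype=np.float64) / 10.0)


def energy_to_db(energy) -> np.ndarray:
    return 10.0 * np.log10(energy)


def energy_average(levels: Sequence[float] | np.ndarray) -> float:
    """Energy (logarithmic) mean of dB values: ``10*log10(mean(10^(L/10)))``.

    Always >= the arithmetic mean of the inputs (Jensen).

    Raises
    ------
    ValueError
        If ``levels`` is empty.
    """
    arr = np.asarray(levels, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("energy_average of an empty sequence is undefined")
    if not np.all(np.isfinite(arr)):
        raise ValueError("levels must be finite")
    return float(energy_to_db(db_to_energy(arr).mean()))


def energy_sum(levels) -> float:
    """dB level of the summed energies: ``10*log10(sum(10^(L/10)))``."""
    arr = np.asarray(levels, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("energy_sum of an empty sequence is undefined")
    return float(energy_to_db(db_to_energy(arr).sum()))


# ---------------------------------------------------------------------------
# interval / exceedance metrics
# ---------------------------------------------------------------------------

def leq_interval(
    series: SplSeries,
    start: int,
    end: int,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> tuple[float, float]:
    """Equivalent continuous level over ``[start, end)``.

    Returns ``(leq_db, coverage_fraction)``.  Seconds absent from the series
    are excluded; if coverage falls below ``min_coverage`` a
    :class:`CoverageWarning` is emitted (and logged) but the value is still
    returned.

    Raises
    ------
    ValueError
        If ``end <= start`` or the interval contains no samples.
    """
    if end <= start:
        raise ValueError("end must be after start")
    sub = series.slice(start, end)
    if len(sub) == 0:
        raise ValueError(
            f"no samples in interval [{start}, {end}) for {series.location_id!r}"
        )
    coverage = len(sub) / (end - start)
    if coverage < min_coverage:
        msg = (
            f"interval [{start}, {end}) coverage {coverage:.3f} below "
            f"minimum {min_coverage:.3f} for {series.location_id!r}"
        )
        logger.warning(msg)
        warnings.warn(msg, CoverageWarning, stacklevel=2)
    return energy_average(sub.levels), coverage


def exceedance_level(series: SplSeries, percent: float) -> float:
    """Level exceeded ``percent`` % of the time (nearest-rank rule).

    ``exceedance_level(s, 95)`` is the conventional L95 residual-sound
    estimator: the (100 - 95) = 5th percentile of the level distribution.
    """
    if len(series) == 0:
        raise ValueError("exceedance level of an empty series is undefined")
    if not 0.0 < percent < 100.0:
        raise ValueError("percent must be in (0, 100)")
    return nearest_rank_percentile(series.levels, 100.0 - percent)


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank ``q``-th percentile: sorted[ceil(q/100 * n)] (1-based)."""
    arr = np.sort(np.asarray(values, dtype=np.float64))
    n = arr.size
    if n == 0:
        raise ValueError("percentile of empty array")
    k = max(1, math.ceil(q / 100.0 * n))
    return float(arr[k - 1])


# ---------------------------------------------------------------------------
# day/evening/night cumulative metrics
# ---------------------------------------------------------------------------

def _require_a_eq(series: SplSeries) -> None:
    if series.freq_weighting != "A" or series.time_weighting != "eq_1s":
        raise ValueError(
            "cumulative day/night metrics require an A-weighted eq_1s series; "
            f"got {series.freq_weighting}/{series.time_weighting}"
        )


def _penalized_average(series: SplSeries, evening_db: float, night_db: float) -> float:
    if len(series) == 0:
        raise ValueError("empty series")
    penalties = np.zeros(len(series))
    penalties[series.is_night()] = night_db
    if evening_db:
        penalties[series.is_evening()] = evening_db
    return energy_average(series.levels + penalties)


def ldn(series: SplSeries) -> float:
    """Day-night average sound level: +10 dB penalty on 22:00-07:00."""
    _require_a_eq(series)
    return _penalized_average(series, evening_db=0.0, night_db=10.0)


def lden(series: SplSeries) -> float:
    """Day-evening-night level: +5 dB on 19:00-22:00, +10 dB on 22:00-07:00."""
    _require_a_eq(series)
    return _penalized_average(series, evening_db=5.0, night_db=10.0)


def lnight(series: SplSeries) -> float:
    """Unpenalised energy average over the 22:00-07:00 night period only."""
    night = series.is_night()
    if not night.any():
        raise ValueError("series has no nighttime (22:00-07:00) samples")
    return energy_average(series.levels[night])


def leq24(series: SplSeries) -> float:
    """Energy average over all present seconds of the (24-h) series."""
    if len(series) == 0:
        raise ValueError("empty series")
    return energy_average(series.levels)


def hourly_leq(series: SplSeries) -> np.ndarray:
    """Per-clock-hour energy averages; hours with no samples are NaN."""
    if len(series) == 0:
        raise ValueError("empty series")
    hours = series.local_hour()
    energies = db_to_energy(series.levels)
    sums = np.bincount(hours, weights=energies, minlength=24)
    counts = np.bincount(hours, minlength=24)
    out = np.full(24, np.nan)
    present = counts > 0
    out[present] = energy_to_db(sums[present] / counts[present])
    return out


def ldnmr(
    monthly_ldn: Iterable[float],
    onset_rate_penalty: Callable[[np.ndarray], np.ndarray] | None = None,
) -> float:
    """Onset-rate adjusted monthly day-night average level.

    Energy average of monthly Ldn values.  ``onset_rate_penalty`` may supply a
    per-month dB adjustment (added before averaging); by default no adjustment
    is applied, which is logged once per call so reports can flag it.
    """
    arr = np.asarray(list(monthly_ldn), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("ldnmr requires at least one monthly Ldn value")
    if onset_rate_penalty is not None:
        arr = arr + np.asarray(onset_rate_penalty(arr), dtype=np.float64)
    else:
        logger.info("ldnmr: onset-rate penalty not supplied; using zero adjustment")
    return energy_average(arr)


@dataclass(frozen=True)
class CumulativeMetrics:
    """All cumulative metrics for one location-day."""

    location_id: str
    ldn: float
    lden: float
    lnight: float | None
    leq24: float
    hourly_leq: np.ndarray
    l95: float
    coverage_fraction: float
    ldnmr: float | None = None


def cumulative_metrics(
    series: SplSeries, min_coverage: float = DEFAULT_MIN_COVERAGE
) -> CumulativeMetrics:
    """Compute the full cumulative-metric suite for one series.

    ``lnight`` is ``None`` when the series has no nighttime samples.  Coverage
    is measured against a full 86400-second day.
    """
    _require_a_eq(series)
    coverage = len(series) / DAY_S
    if coverage < min_coverage:
        logger.warning(
            "series %s covers %.1f%% of a day", series.location_id, 100 * coverage
        )
    try:
        ln = lnight(series)
    except ValueError:
        ln = None
    return CumulativeMetrics(
        location_id=series.location_id,
        ldn=ldn(series),
        lden=lden(series),
        lnight=ln,
        leq24=leq24(series),
        hourly_leq=hourly_leq(series),
        l95=exceedance_level(series, 95.0),
        coverage_fraction=coverage,
    )


# ---------------------------------------------------------------------------
# occupational noise dose
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseStandard:
    name: str
    criterion_level_db: float
    criterion_duration_h: float
    exchange_rate_db: float
    threshold_cutoff_db: float


DOSE_STANDARDS = {
    # criterion level, criterion duration, exchange rate, integration cutoff
    "OSHA": DoseStandard("OSHA", 90.0, 8.0, 5.0, 90.0),
    "NIOSH": DoseStandard("NIOSH", 85.0, 8.0, 3.0, 80.0),
}


@dataclass(frozen=True)
class DoseResult:
    """Occupational noise dose for one series under one standard."""

    standard: str
    twa: float
    dose_percent: float
    reference_duration_h: float


def noise_dose(
    series: SplSeries,
    standard: str = "NIOSH",
    reference_duration_h: float = 24.0,
) -> DoseResult:
    """Daily noise dose and time-weighted average level.

    ``dose_percent = sum_t (dt / T_allowed(L_t)) * 100`` with
    ``T_allowed(L) = Tc * 2**((Lc - L) / ER)``; seconds below the standard's
    integration cutoff contribute nothing.  The TWA is back-computed from the
    dose over ``reference_duration_h`` (24 h by default, the residential
    exposure convention): ``TWA = Lc + ER * log2(dose/100 * Tc / Tref)``.
    """
    if series.freq_weighting != "A":
        raise ValueError("noise dose requires an A-weighted series")
    try:
        std = DOSE_STANDARDS[standard]
    except KeyError:
        raise ValueError(f"unknown dose standard {standard!r}") from None
    if reference_duration_h <= 0:
        raise ValueError("reference_duration_h must be positive")
    levels = series.levels
    active = levels >= std.threshold_cutoff_db
    dt_h = 1.0 / 3600.0
    t_allowed_h = std.criterion_duration_h * np.power(
        2.0, (std.criterion_level_db - levels[active]) / std.exchange_rate_db
    )
    dose = float(np.sum(dt_h / t_allowed_h) * 100.0)
    if dose > 0:
        twa = std.criterion_level_db + std.exchange_rate_db * math.log2(
            dose / 100.0 * std.criterion_duration_h / reference_duration_h
        )
    else:
        twa = -math.inf
    return DoseResult(
        standard=standard,
        twa=twa,
        dose_percent=dose,
        reference_duration_h=reference_duration_h,
    )


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def average_spectrum(
    spectra: SpectrumSeries, event_windows: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Representative per-band event spectrum.

    Each event window ``[start, end)`` is energy-averaged per band, then the
    per-event spectra are energy-averaged across events, preserving the band
    count.  Raises if no window overlaps the series.
    """
    per_event = []
    for start, end in event_windows:
        i0, i1 = np.searchsorted(spectra.timestamps, [start, end])
        if i1 > i0:
            per_event.append(db_to_energy(spectra.levels[i0:i1]).mean(axis=0))
    if not per_event:
        raise ValueError("no event window overlaps the spectrum series")
    return np.asarray(energy_to_db(np.mean(per_event, axis=0)))
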
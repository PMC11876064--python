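"""Acoustic-metric unit and property tests.

Expected values are closed forms computed in the energy domain or
brute-force per-second loop results (see _oracles.py).
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from conftest import make_series
from noisepop import metrics as m
from noisepop.series import SplSeries

HALF_5060 = 10 * math.log10((1e5 + 1e6) / 2)  # mixing equal parts 50 and 60 dB


class TestEnergyAverage:
    def test_constant_is_identity(self):
        assert m.energy_average([60, 60, 60]) == pytest.approx(60.0)

    def test_two_level_closed_form(self):
        assert m.energy_average([50, 60]) == pytest.approx(HALF_5060, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            m.energy_average([])

    @given(
        st.lists(st.floats(min_value=0, max_value=120), min_size=1, max_size=50)
    )
    @settings(max_examples=50, derandomize=True)
    def test_at_least_arithmetic_mean(self, levels):
        assert m.energy_average(levels) >= np.mean(levels) - 1e-9


class TestLeqInterval:
    def test_constant(self):
        s = make_series([55.0] * 120)
        leq, cov = m.leq_interval(s, 0, 120)
        assert leq == pytest.approx(55.0)
        assert cov == 1.0

    def test_half_and_half(self):
        s = make_series([60.0] * 60 + [50.0] * 60)
        leq, _ = m.leq_interval(s, 0, 120)
        assert leq == pytest.approx(HALF_5060, abs=1e-9)

    def test_interval_in_gap_raises(self):
        ts = np.concatenate([np.arange(100), np.arange(500, 600)])
        s = SplSeries("g", ts, np.full(200, 50.0))
        with pytest.raises(ValueError):
            m.leq_interval(s, 200, 300)

    def test_low_coverage_warns(self):
        s = make_series([50.0] * 30)
        with pytest.warns(m.CoverageWarning):
            leq, cov = m.leq_interval(s, 0, 120)
        assert cov == pytest.approx(0.25)
        assert leq == pytest.approx(50.0)


class TestExceedance:
    def test_constant(self):
        assert m.exceedance_level(make_series([40.0] * 100), 95) == 40.0

    def test_staircase_nearest_rank(self):
        s = make_series(np.arange(1.0, 101.0))
        assert m.exceedance_level(s, 95) == 5.0

    def test_two_valued(self):
        s = make_series([30.0] * 95 + [80.0] * 5)
        assert m.exceedance_level(s, 95) == 30.0

    def test_bad_percent(self):
        with pytest.raises(ValueError):
            m.exceedance_level(make_series([40.0]), 0)


class TestDayNightMetrics:
    def test_ldn_constant_day(self):
        s = make_series([60.0] * _oracles.DAY_S)
        expected = 10 * math.log10((15 * 1e6 + 9 * 1e7) / 24)
        assert m.ldn(s) == pytest.approx(expected, abs=1e-9)

    def test_lden_constant_day(self):
        s = make_series([60.0] * _oracles.DAY_S)
        expected = 10 * math.log10((12 * 1e6 + 3 * 10 ** 6.5 + 9 * 1e7) / 24)
        assert m.lden(s) == pytest.approx(expected, abs=1e-9)

    def test_clock_hour_determinism(self):
        """Same clock coverage on different days gives identical results."""
        a = make_series([60.0] * _oracles.DAY_S, start=0)
        b = make_series([60.0] * _oracles.DAY_S, start=5 * _oracles.DAY_S)
        assert m.ldn(a) == m.ldn(b)
        assert m.lden(a) == m.lden(b)

    def test_wrong_weighting_rejected(self):
        s = make_series([60.0] * _oracles.DAY_S, freq_weighting="C")
        with pytest.raises(ValueError):
            m.ldn(s)

    def test_daytime_energy_dominates(self):
        """Loud daytime + silence-floor night: Ldn approaches daytime level."""
        levels = np.full(_oracles.DAY_S, m.DEFAULT_SILENCE_FLOOR_DB)
        sod = np.arange(_oracles.DAY_S) % _oracles.DAY_S
        day = (sod >= 7 * 3600) & (sod < 19 * 3600)
        levels[day] = 80.0
        s = make_series(levels)
        day_leq_renorm = 80.0 + 10 * math.log10(12 / 24)
        assert m.ldn(s) == pytest.approx(day_leq_renorm, abs=1e-3)

    def test_lnight_constant(self):
        s = make_series([45.0] * _oracles.DAY_S)
        assert m.lnight(s) == pytest.approx(45.0)

    def test_lnight_mixture(self):
        levels = np.full(_oracles.DAY_S, 30.0)
        sod = np.arange(_oracles.DAY_S)
        night = (sod >= 22 * 3600) | (sod < 7 * 3600)
        night_idx = np.nonzero(night)[0]
        levels[night_idx[: len(night_idx) // 2]] = 40.0
        levels[night_idx[len(night_idx) // 2:]] = 50.0
        s = make_series(levels)
        assert m.lnight(s) == pytest.approx(
            10 * math.log10((1e4 + 1e5) / 2), abs=1e-9
        )

    def test_lnight_daytime_only_raises(self):
        ts = 8 * 3600 + np.arange(3600, dtype=np.int64)  # 08:00-09:00
        s = SplSeries("d", ts, np.full(3600, 50.0))
        with pytest.raises(ValueError):
            m.lnight(s)

    def test_penalty_ordering(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ts, levels, off = _oracles.random_gapped_series(rng)
            s = SplSeries("r", ts, levels, utc_offset_s=off)
            assert m.lden(s) >= m.ldn(s) - 1e-12
            assert m.ldn(s) >= m.leq24(s) - 1e-12


class TestHourlyLeq:
    def test_constant(self):
        out = m.hourly_leq(make_series([50.0] * _oracles.DAY_S))
        assert np.allclose(out, 50.0)

    def test_single_loud_hour(self):
        levels = np.full(_oracles.DAY_S, 35.0)
        levels[10 * 3600: 11 * 3600] = 70.0
        out = m.hourly_leq(make_series(levels))
        assert out[10] == pytest.approx(70.0)
        assert np.allclose(np.delete(out, 10), 35.0)

    def test_half_hour_mixture(self):
        levels = np.concatenate([np.full(1800, 60.0), np.full(1800, 50.0)])
        out = m.hourly_leq(make_series(levels))
        assert out[0] == pytest.approx(HALF_5060, abs=1e-9)
        assert np.isnan(out[1:]).all()


class TestLdnmr:
    def test_single_month(self):
        assert m.ldnmr([40.0]) == pytest.approx(40.0)

    def test_two_months(self):
        expected = 10 * math.log10((10 ** 3.4 + 10 ** 4.7) / 2)
        assert m.ldnmr([34.0, 47.0]) == pytest.approx(expected, abs=1e-9)

    def test_equal_months_identity(self):
        assert m.ldnmr([42.0] * 12) == pytest.approx(42.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            m.ldnmr([])

    def test_penalty_hook(self):
        base = m.ldnmr([40.0, 50.0])
        bumped = m.ldnmr([40.0, 50.0], onset_rate_penalty=lambda a: np.full_like(a, 5.0))
        assert bumped == pytest.approx(base + 5.0, abs=1e-9)


class TestNoiseDose:
    def _hours(self, level, hours):
        return make_series([level] * int(hours * 3600))

    def test_niosh_criterion_exposure(self):
        dose = m.noise_dose(self._hours(85.0, 8), "NIOSH")
        assert dose.dose_percent == pytest.approx(100.0, rel=1e-9)

    def test_niosh_exchange_rate(self):
        dose = m.noise_dose(self._hours(88.0, 8), "NIOSH")
        assert dose.dose_percent == pytest.approx(200.0, rel=1e-9)

    def test_osha_exchange_rate(self):
        dose = m.noise_dose(self._hours(95.0, 8), "OSHA")
        assert dose.dose_percent == pytest.approx(200.0, rel=1e-9)

    def test_below_cutoff_contributes_nothing(self):
        assert m.noise_dose(self._hours(79.0, 8), "NIOSH").dose_percent == 0.0
        assert m.noise_dose(self._hours(89.0, 8), "OSHA").dose_percent == 0.0

    def test_dose_reciprocity(self):
        for std in ("OSHA", "NIOSH"):
            full = m.noise_dose(self._hours(95.0, 4), std).dose_percent
            half = m.noise_dose(self._hours(95.0, 2), std).dose_percent
            assert half == pytest.approx(full / 2, rel=1e-9)

    def test_matches_brute_loop(self):
        rng = np.random.default_rng(3)
        levels = rng.uniform(60, 110, size=5000)
        s = make_series(levels)
        got = m.noise_dose(s, "NIOSH").dose_percent
        exp = _oracles.brute_dose(levels, 85.0, 8.0, 3.0, 80.0)
        assert got == pytest.approx(exp, rel=1e-12)

    def test_twa_at_criterion(self):
        """8 h at the criterion level spread over 24 h lowers the TWA."""
        dose = m.noise_dose(self._hours(85.0, 8), "NIOSH", reference_duration_h=24)
        assert dose.twa == pytest.approx(85.0 + 3.0 * math.log2(8 / 24), rel=1e-9)

    def test_non_a_weighting_rejected(self):
        s = make_series([90.0] * 100, freq_weighting="Z")
        with pytest.raises(ValueError):
            m.noise_dose(s, "NIOSH")


class TestAverageSpectrum:
    def _spectrum(self, levels_matrix):
        from noisepop.series import SpectrumSeries

        n = len(levels_matrix)
        return SpectrumSeries(
            "s",
            np.arange(n, dtype=np.int64),
            band_centers=np.array([50.0, 100.0, 200.0]),
            levels=np.asarray(levels_matrix, dtype=float),
        )

    def test_constant_identity(self):
        spec = self._spectrum(np.full((20, 3), 70.0))
        out = m.average_spectrum(spec, [(0, 20)])
        assert np.allclose(out, 70.0)

    def test_two_event_mixture(self):
        mat = np.vstack([np.full((10, 3), 50.0), np.full((10, 3), 60.0)])
        spec = self._spectrum(mat)
        out = m.average_spectrum(spec, [(0, 10), (10, 20)])
        assert np.allclose(out, HALF_5060)

    def test_no_overlap_raises(self):
        spec = self._spectrum(np.full((10, 3), 70.0))
        with pytest.raises(ValueError):
            m.average_spectrum(spec, [(100, 200)])


class TestOracleEquivalence:
    def test_cumulative_metrics_match_brute_loop(self):
        """Vectorised metrics equal the per-second loop to 1e-9 dB."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(50):
            ts, levels, off = _oracles.random_gapped_series(rng)
            s = SplSeries("r", ts, levels, utc_offset_s=off)
            ref = _oracles.brute_cumulative(ts, levels, off)
            worst = max(
                worst,
                abs(m.ldn(s) - ref["ldn"]),
                abs(m.lden(s) - ref["lden"]),
                abs(m.leq24(s) - ref["leq24"]),
                abs(m.exceedance_level(s, 95) - ref["l95"]),
            )
            if ref["lnight"] is not None:
                worst = max(worst, abs(m.lnight(s) - ref["lnight"]))
            hourly = m.hourly_leq(s)
            for h in range(24):
                if ref["hourly"][h] is None:
                    assert np.isnan(hourly[h])
                else:
                    worst = max(worst, abs(hourly[h] - ref["hourly"][h]))
        assert worst < 1e-9

    def test_monotone_in_energy(self):
        """Raising any single second never lowers a cumulative metric."""
        rng = np.random.default_rng(5)
        ts, levels, off = _oracles.random_gapped_series(rng, 600, 1200)
        s = SplSeries("r", ts, levels, utc_offset_s=off)
        base = (m.ldn(s), m.lden(s), m.leq24(s))
        for idx in rng.integers(0, len(levels), size=10):
            bumped = levels.copy()
            bumped[idx] += 6.0
            sb = SplSeries("r", ts, bumped, utc_offset_s=off)
            assert m.ldn(sb) >= base[0] - 1e-12
            assert m.lden(sb) >= base[1] - 1e-12
            assert m.leq24(sb) >= base[2] - 1e-12

    @given(st.floats(min_value=-30, max_value=30))
    @settings(max_examples=25, derandomize=True)
    def test_scale_equivariance(self, c):
        """Adding c dB to every sample adds exactly c to every metric."""
        rng = np.random.default_rng(9)
        ts, levels, off = _oracles.random_gapped_series(rng, 600, 1200)
        s = SplSeries("r", ts, levels, utc_offset_s=off)
        sc = SplSeries("r", ts, levels + c, utc_offset_s=off)
        for fn in (m.ldn, m.lden, m.leq24):
            assert fn(sc) == pytest.approx(fn(s) + c, abs=1e-9)
        assert m.exceedance_level(sc, 95) == pytest.approx(
            m.exceedance_level(s, 95) + c, abs=1e-9
        )
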
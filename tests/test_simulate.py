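"""Simulator unit and property tests: protocol arithmetic, gas breakpoint
construction, RR dynamics, ECG rendering round trip, cohort statistics."""

import dataclasses
import json

import numpy as np
import pytest

from ecgvt.gas import average_30s, detect_vt_vslope
from ecgvt.io import manifest_row
from ecgvt.simulate import (ECGMorphology, PhysiologyParams, RRSeries,
                            detect_r_peaks, simulate_cohort,
                            simulate_gas_exchange, simulate_protocol,
                            simulate_rr_intervals, synthesize_ecg)


class TestProtocol:
    @pytest.mark.parametrize("ramp, peak, expected", [
        (10.0, 100.0, 600.0),
        (15.0, 106.0, 424.0),
    ])
    def test_exercise_duration(self, ramp, peak, expected):
        assert simulate_protocol(ramp, peak).exercise_duration == pytest.approx(expected)

    def test_phase_sum(self):
        p = simulate_protocol(12.0, 106.0)
        assert p.total_duration == pytest.approx(120 + 120 + 530 + 180)
        assert p.phase_boundaries == (120.0, 240.0, 770.0, 950.0)

    @pytest.mark.parametrize("ramp, peak", [(0.0, 100.0), (-5.0, 100.0),
                                            (10.0, 0.0)])
    def test_rejects_nonpositive(self, ramp, peak):
        with pytest.raises(ValueError):
            simulate_protocol(ramp, peak)

    def test_work_rate_ramp(self):
        p = simulate_protocol(12.0, 106.0)
        assert p.work_rate(100.0) == 0.0                      # rest
        assert p.work_rate(240.0 + 60.0) == pytest.approx(12.0)
        assert p.work_rate(10_000.0) == pytest.approx(106.0)  # clamped at peak


class TestGasExchange:
    def test_warmup_vo2_is_resting(self, protocol, noiseless_phys):
        b = simulate_gas_exchange(protocol, noiseless_phys, 300.0, rng_seed=1)
        warm = (b.breath_times > protocol.rest_duration) & \
               (b.breath_times < protocol.exercise_start)
        assert np.allclose(b.vo2[warm], 3.9)

    def test_single_breakpoint_at_constructed_vo2(self, protocol, spec_slopes_phys):
        """Noiseless VCO2-vs-VO2 is piecewise linear with one slope change
        exactly at VO2(vt_time)."""
        phys = spec_slopes_phys
        # choose vt_time so that the breakpoint lands at 14.0 mL/kg/min
        vt_vo2 = 14.0
        vt_time = (vt_vo2 - phys.resting_vo2) / (phys.vo2_gain * protocol.ramp_rate / 60.0)
        b = simulate_gas_exchange(protocol, phys, vt_time, rng_seed=2)
        ramp = b.breath_times > protocol.exercise_start
        vo2, vco2 = b.vo2[ramp], b.vco2[ramp]
        below, above = vo2 < vt_vo2 - 1e-9, vo2 > vt_vo2 + 1e-9
        slope_below = np.polyfit(vo2[below], vco2[below], 1)[0]
        slope_above = np.polyfit(vo2[above], vco2[above], 1)[0]
        assert slope_below == pytest.approx(0.9, abs=1e-9)
        assert slope_above == pytest.approx(1.2, abs=1e-9)
        # the two branches intersect at the constructed breakpoint
        avg = average_30s(b, protocol.exercise_start)
        vt = detect_vt_vslope(avg, (0.0, protocol.exercise_duration))
        assert vt.vt_vo2 == pytest.approx(14.0, abs=1e-6)

    def test_same_seed_identical(self, protocol, noiseless_phys):
        a = simulate_gas_exchange(protocol, noiseless_phys, 300.0, rng_seed=7)
        b = simulate_gas_exchange(protocol, noiseless_phys, 300.0, rng_seed=7)
        assert np.array_equal(a.breath_times, b.breath_times)
        assert np.array_equal(a.vo2, b.vo2)

    def test_vt_outside_exercise_rejected(self, protocol, noiseless_phys):
        with pytest.raises(ValueError):
            simulate_gas_exchange(protocol, noiseless_phys, 1e5, rng_seed=1)


class TestRRIntervals:
    def test_first_rr_matches_resting_hr(self, protocol, noiseless_phys):
        rr = simulate_rr_intervals(protocol, noiseless_phys, 300.0, rng_seed=1)
        assert rr.rr_intervals[0] == pytest.approx(60.0 / 75.0, abs=1e-9)

    def test_hrv_amplitude_drops_at_vt(self, protocol, noiseless_phys):
        phys = dataclasses.replace(noiseless_phys, hrv_below=0.05,
                                   hrv_above=0.01)
        vt_session = protocol.exercise_start + 300.0
        rr = simulate_rr_intervals(protocol, phys, 300.0, rng_seed=3)

        def detrended_sd(t0, t1):
            m = (rr.beat_times >= t0) & (rr.beat_times < t1)
            seg = rr.rr_intervals[m]
            return np.std(seg - np.polyval(np.polyfit(np.arange(len(seg)), seg, 1),
                                           np.arange(len(seg))))
        assert detrended_sd(vt_session - 30, vt_session) > \
            detrended_sd(vt_session + 5, vt_session + 35)

    def test_mean_hr_rises_through_exercise(self, protocol, noiseless_phys):
        rr = simulate_rr_intervals(protocol, noiseless_phys, 300.0, rng_seed=4)
        ex = (rr.beat_times >= protocol.exercise_start) & \
             (rr.beat_times < protocol.exercise_end)
        hr = 60.0 / rr.rr_intervals[ex]
        thirds = np.array_split(hr, 3)
        assert thirds[0].mean() < thirds[1].mean() < thirds[2].mean()
        assert np.all(hr >= 30) and np.all(hr <= 220)

    def test_af_mode_has_no_lag1_structure(self, protocol):
        phys = PhysiologyParams(af_mode=True, rr_jitter_sd=0.0)
        rr = simulate_rr_intervals(protocol, phys, 300.0, rng_seed=5)
        # rest + warm-up: constant base HR, so any structure would be AF's
        rest = rr.rr_intervals[rr.beat_times < protocol.exercise_start][:200]
        x = rest - rest.mean()
        rho1 = np.dot(x[:-1], x[1:]) / np.dot(x, x)
        assert abs(rho1) < 2.5 / np.sqrt(len(rest))

    def test_degenerate_hr_bounds_rejected(self):
        with pytest.raises(ValueError):
            PhysiologyParams(hr_rest=140.0, hr_peak=120.0)


class TestECGSynthesis:
    def test_single_beat_r_peak(self):
        rr = RRSeries(beat_times=np.array([1.0]), rr_intervals=np.array([0.8]))
        tr = synthesize_ecg(rr, ECGMorphology(r_amp=1.0), sampling_rate=1000,
                            total_duration=2.0)
        i = int(np.argmax(tr.voltage))
        assert abs(i / 1000.0 - 1.0) <= 1.0 / 1000.0
        assert tr.voltage[i] == pytest.approx(1.0, abs=1e-3)

    def test_trace_length(self, protocol, noiseless_phys):
        rr = simulate_rr_intervals(protocol, noiseless_phys, 300.0, rng_seed=1)
        tr = synthesize_ecg(rr, sampling_rate=1000,
                            total_duration=protocol.total_duration)
        assert len(tr.voltage) == round(protocol.total_duration * 1000)
        # a 30-s cut of this trace is exactly 30,000 samples
        assert len(tr.voltage[:30 * 1000]) == 30_000

    def test_rr_round_trip_within_1ms(self, protocol, noiseless_phys):
        rr = simulate_rr_intervals(protocol, noiseless_phys, 300.0, rng_seed=6)
        tr = synthesize_ecg(rr, sampling_rate=1000,
                            total_duration=protocol.total_duration)
        rec = detect_r_peaks(tr)
        assert len(rec) == len(rr.beat_times)
        assert np.max(np.abs(rec - rr.beat_times)) <= 1.0e-3 + 1e-12

    def test_low_sampling_rate_rejected(self):
        rr = RRSeries(np.array([1.0]), np.array([0.8]))
        with pytest.raises(ValueError):
            synthesize_ecg(rr, sampling_rate=50)


class TestCohort:
    def test_vt_inside_exercise_and_count(self):
        sessions = simulate_cohort(12, seed=0, fs=125)
        assert len(sessions) == 12
        for s in sessions:
            assert 0 < s.true_vt_time < s.protocol.exercise_duration
            n = round(s.protocol.total_duration * 125)
            assert len(s.ecg.voltage) == n

    def test_reproducible_from_seed(self):
        a = simulate_cohort(4, seed=11, fs=125)
        b = simulate_cohort(4, seed=11, fs=125)
        assert json.dumps([manifest_row(s) for s in a]) == \
            json.dumps([manifest_row(s) for s in b])
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.ecg.voltage, sb.ecg.voltage)
            assert np.array_equal(sa.breaths.vo2, sb.breaths.vo2)

    def test_vt_vo2_mean_matches_configured_distribution(self):
        """CLT check: the cohort mean VT-VO2 is within 3 SE of the target."""
        sessions = simulate_cohort(200, seed=1, include_ecg=False)
        vts = np.array([s.true_vt_vo2 for s in sessions])
        assert abs(vts.mean() - 14.0) < 3.0 * 4.5 / np.sqrt(200)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(0)
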
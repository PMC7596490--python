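"""Gas-exchange analysis tests: 30-s averaging, the three VT detectors with
their oracles, the consensus rule, and the derived CPX metrics."""

import dataclasses

import numpy as np
import pytest

from ecgvt.gas import (AveragedSeries, BreathSeries, VTResult, average_30s,
                       consensus_vt, derive_metrics, detect_rcp,
                       detect_vt_excess_co2, detect_vt_ventilatory_equivalent,
                       detect_vt_vslope, peak_vo2, ve_vco2_slope, vo2_at_time)
from ecgvt.simulate import simulate_cohort, simulate_gas_exchange


def make_breaths(times, vo2=None, vco2=None, ve=None):
    times = np.asarray(times, dtype=float)
    z = np.ones_like(times)
    return BreathSeries(times, vo2 if vo2 is not None else z,
                        vco2 if vco2 is not None else z,
                        ve if ve is not None else z)


def linear_avg(a, b, n_windows, window_s=30.0):
    """Averaged series whose window means follow a + b * midtime exactly."""
    starts = np.arange(n_windows) * window_s
    mids = starts + window_s / 2.0
    vo2 = a + b * mids
    return AveragedSeries(starts, vo2, 0.85 * vo2, 30.0 * 0.85 * vo2 * 0.065)


class TestAverage30s:
    def test_constant_channel(self):
        t = np.arange(0.5, 120.0, 3.0)
        avg = average_30s(make_breaths(t, vo2=np.full(len(t), 5.0)))
        assert np.allclose(avg.vo2, 5.0)

    def test_window_count(self):
        t = np.arange(1.0, 601.0, 3.0)
        avg = average_30s(make_breaths(t))
        # last breath at 598 s -> floor(598/30) = 19 complete windows
        assert len(avg) == 19

    def test_linear_ramp_mean_is_mean_of_breath_times(self):
        t = np.arange(0.5, 180.0, 2.5)
        a, b = 2.0, 0.05
        avg = average_30s(make_breaths(t, vo2=a + b * t))
        idx = np.floor(t / 30.0).astype(int)
        for w in range(len(avg)):
            expected = a + b * t[idx == w].mean()
            assert avg.vo2[w] == pytest.approx(expected, abs=1e-12)

    def test_empty_window_is_an_error(self):
        t = np.concatenate([np.arange(0.5, 25.0, 3.0), [70.0, 75.0, 95.0]])
        with pytest.raises(ValueError, match="window 1"):
            average_30s(make_breaths(t))

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            average_30s(make_breaths([1.0, 5.0, 20.0]))


class TestVSlope:
    def test_noiseless_recovery_is_exact(self, protocol, spec_slopes_phys):
        vt_vo2 = 14.0
        phys = spec_slopes_phys
        vt_time = (vt_vo2 - phys.resting_vo2) / (phys.vo2_gain * protocol.ramp_rate / 60.0)
        b = simulate_gas_exchange(protocol, phys, vt_time, rng_seed=3)
        avg = average_30s(b, protocol.exercise_start)
        vt = detect_vt_vslope(avg, (0.0, protocol.exercise_duration))
        assert vt.ok
        assert vt.vt_vo2 == pytest.approx(14.0, abs=1e-6)
        # time is read back through window means of jittered breath times,
        # so it is exact only to the breath-sampling scale
        assert vt.vt_time == pytest.approx(vt_time, abs=3.0)

    def test_straight_line_has_no_vt(self):
        starts = np.arange(10) * 30.0
        vo2 = 5.0 + 0.5 * starts
        avg = AveragedSeries(starts, vo2, 0.9 * vo2, 27.0 * 0.9 * vo2 * 0.065)
        vt = detect_vt_vslope(avg, (0.0, 300.0))
        assert not vt.ok

    def test_too_few_windows_rejected(self):
        starts = np.arange(5) * 30.0
        avg = AveragedSeries(starts, starts, starts, starts)
        with pytest.raises(ValueError):
            detect_vt_vslope(avg, (0.0, 150.0))

    def test_noisy_recovery_within_half_unit(self, protocol, spec_slopes_phys):
        """Breakpoint at 15.7 mL/kg/min with breath noise SD 0.2: the
        estimate stays within +/-0.5 for the vast majority of replicates."""
        phys = dataclasses.replace(spec_slopes_phys, breath_noise_sd=0.2)
        vt_vo2 = 15.7
        vt_time = (vt_vo2 - phys.resting_vo2) / (phys.vo2_gain * protocol.ramp_rate / 60.0)
        errs = []
        for seed in range(100):
            b = simulate_gas_exchange(protocol, phys, vt_time, rng_seed=seed)
            avg = average_30s(b, protocol.exercise_start)
            vt = detect_vt_vslope(avg, (0.0, protocol.exercise_duration))
            assert vt.ok
            errs.append(vt.vt_vo2 - vt_vo2)
        errs = np.asarray(errs)
        assert abs(errs.mean()) < 0.15          # unbiased
        assert np.median(np.abs(errs)) <= 0.5
        assert np.mean(np.abs(errs) <= 0.5) >= 0.8


class TestVentilatoryEquivalent:
    def test_noiseless_within_one_window(self, protocol, noiseless_phys):
        vt = 300.0
        b = simulate_gas_exchange(protocol, noiseless_phys, vt, rng_seed=4)
        avg = average_30s(b, protocol.exercise_start)
        res = detect_vt_ventilatory_equivalent(avg, (0.0, protocol.exercise_duration))
        assert res.ok
        assert abs(res.vt_time - vt) <= 30.0

    def test_cross_method_agreement_noiseless(self, protocol, noiseless_phys):
        vt = 270.0
        b = simulate_gas_exchange(protocol, noiseless_phys, vt, rng_seed=5)
        avg = average_30s(b, protocol.exercise_start)
        bounds = (0.0, protocol.exercise_duration)
        t1 = detect_vt_vslope(avg, bounds).vt_time
        t2 = detect_vt_ventilatory_equivalent(avg, bounds).vt_time
        assert abs(t1 - t2) <= 30.0

    def test_monotone_falling_equivalent_has_no_vt(self):
        starts = np.arange(10) * 30.0
        vo2 = 5.0 + 0.05 * starts
        ve = 2.0 + 0.01 * starts  # VE/VO2 strictly falling
        avg = AveragedSeries(starts, vo2, 0.9 * vo2, ve)
        res = detect_vt_ventilatory_equivalent(avg, (0.0, 300.0))
        assert not res.ok


class TestExcessCO2:
    def test_constant_rq_has_no_breakpoint(self):
        """With VCO2 = q * VO2 throughout (q constant), excess CO2 is an
        exact line in time and the slope-increase constraint cannot hold."""
        starts = np.arange(12) * 30.0
        vo2 = 5.0 + 0.04 * (starts + 15.0)
        q = 0.9
        avg = AveragedSeries(starts, vo2, q * vo2, 27.0 * q * vo2 * 0.065)
        exco2 = (q * vo2) ** 2 / vo2 - q * vo2
        fit = np.polyfit(starts + 15.0, exco2, 1)
        assert np.allclose(np.polyval(fit, starts + 15.0), exco2, atol=1e-12)
        res = detect_vt_excess_co2(avg, (0.0, 360.0))
        assert not res.ok

    def test_noiseless_session_within_two_windows(self, protocol, noiseless_phys):
        vt = 300.0
        b = simulate_gas_exchange(protocol, noiseless_phys, vt, rng_seed=6)
        avg = average_30s(b, protocol.exercise_start)
        res = detect_vt_excess_co2(avg, (0.0, protocol.exercise_duration))
        assert res.ok
        assert abs(res.vt_time - vt) <= 30.0

    def test_zero_vco2_rejected(self):
        starts = np.arange(8) * 30.0
        avg = AveragedSeries(starts, np.full(8, 5.0), np.zeros(8), np.ones(8))
        with pytest.raises(ValueError):
            detect_vt_excess_co2(avg, (0.0, 240.0))


class TestConsensus:
    def test_identical_times(self):
        rs = [VTResult(m, vt_time=300.0, vt_vo2=12.0)
              for m in ("vslope", "vent_equiv", "excess_co2")]
        assert consensus_vt(rs).vt_time == 300.0

    def test_median_of_three(self):
        rs = [VTResult("vslope", vt_time=300.0),
              VTResult("vent_equiv", vt_time=310.0),
              VTResult("excess_co2", vt_time=400.0)]
        assert consensus_vt(rs).vt_time == 310.0

    def test_midpoint_for_two(self):
        rs = [VTResult("vslope", vt_time=300.0),
              VTResult.failed("vent_equiv", "x"),
              VTResult("excess_co2", vt_time=330.0)]
        assert consensus_vt(rs).vt_time == 315.0

    def test_all_failed_flags_session(self):
        rs = [VTResult.failed(m, "x") for m in ("vslope", "vent_equiv",
                                                "excess_co2")]
        res = consensus_vt(rs)
        assert not res.ok and "vslope" in res.reason


class TestDerivedMetrics:
    def test_peak_vo2_constant_last_window(self):
        avg = AveragedSeries(np.arange(10) * 30.0, np.full(10, 21.8),
                             np.full(10, 20.0), np.full(10, 40.0))
        assert peak_vo2(avg, (0.0, 300.0)) == pytest.approx(21.8)

    def test_peak_vo2_below_ramp_endpoint(self):
        avg = linear_avg(0.0, 0.05, 20)
        assert peak_vo2(avg, (0.0, 600.0)) < 0.05 * 600.0

    def test_peak_vo2_exact_linear_ramp(self):
        # VO2 ramps 0 -> 30 over 600 s: last-30-s mean is the midpoint value
        avg = linear_avg(0.0, 30.0 / 600.0, 20)
        assert peak_vo2(avg, (0.0, 600.0)) == pytest.approx(29.25)

    def test_ve_vco2_slope_exact(self):
        starts = np.arange(10) * 30.0
        vco2 = 0.5 + 0.01 * starts
        avg = AveragedSeries(starts, vco2 / 0.9, vco2, 30.0 * vco2)
        assert ve_vco2_slope(avg, 0.0, 300.0) == pytest.approx(30.0)

    def test_ve_vco2_slope_weight_conversion(self):
        starts = np.arange(10) * 30.0
        vco2 = 8.0 + 0.02 * starts              # mL/kg/min
        ve = 30.0 * vco2 * 64.7 / 1000.0        # L/min
        avg = AveragedSeries(starts, vco2 / 0.9, vco2, ve)
        assert ve_vco2_slope(avg, 0.0, 300.0, weight=64.7) == pytest.approx(30.0)

    def test_ve_vco2_slope_degenerate(self):
        starts = np.arange(10) * 30.0
        avg = AveragedSeries(starts, np.full(10, 9.0), np.full(10, 8.0),
                             np.full(10, 16.0))
        with pytest.raises(ValueError):
            ve_vco2_slope(avg, 0.0, 300.0)


class TestRCPAndBundle:
    def test_rcp_and_metrics_on_noiseless_session(self, protocol,
                                                  noiseless_phys):
        """The VE-on-VCO2 breakpoint lands near the constructed RCP, the
        VE-VCO2 slope recovers the configured gain, and the bundled metrics
        respect peak >= VT ordering."""
        vt = 240.0
        weight = 64.7
        b = simulate_gas_exchange(protocol, noiseless_phys, vt, rng_seed=8,
                                  weight=weight)
        avg = average_30s(b, protocol.exercise_start)
        bounds = (0.0, protocol.exercise_duration)
        rcp_true = vt + noiseless_phys.rcp_fraction * \
            (protocol.exercise_duration - vt)
        rcp = detect_rcp(avg, bounds)
        assert abs(rcp - rcp_true) <= 45.0
        slope = ve_vco2_slope(avg, 0.0, rcp, weight=weight)
        assert slope == pytest.approx(noiseless_phys.ve_vco2_gain, rel=0.02)
        res = detect_vt_vslope(avg, bounds)
        metrics = derive_metrics(avg, bounds, res, weight=weight)
        assert metrics.peak_vo2 >= res.vt_vo2
        assert metrics.rq_at_peak > metrics.rq_at_vt


class TestVO2AtTime:
    @pytest.fixture
    def avg(self):
        return linear_avg(3.9, 0.03, 10)

    def test_window_start(self, avg):
        assert vo2_at_time(avg, 60.0) == avg.vo2[2]

    def test_inside_window(self, avg):
        assert vo2_at_time(avg, 60.0 + 29.9) == avg.vo2[2]

    def test_boundary_belongs_to_later_window(self, avg):
        assert vo2_at_time(avg, 90.0) == avg.vo2[3]

    def test_out_of_range(self, avg):
        with pytest.raises(ValueError):
            vo2_at_time(avg, 301.0)
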
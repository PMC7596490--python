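"""Synthetic cardiopulmonary exercise test (CPX) sessions with a known VT.

A session follows the in-hospital ergometer protocol — 2-min rest, 2-min
0-W warm-up, a 10–15 W/min ramp to volitional exhaustion, 3-min recovery —
and carries three coupled signal layers:

* breath-by-breath gas exchange with a VCO2-vs-VO2 slope breakpoint at the
  ventilatory threshold (VT) and a further VE breakpoint at the respiratory
  compensation point (RCP);
* an RR-interval series whose dynamics change at VT: the oscillatory RR
  modulation amplitude drops (HRV withdrawal) and the mean-HR trajectory,
  anchored at a fixed fraction of HR reserve at VT, changes slope;
* a single-lead ECG rendered from the RR series with a sum-of-Gaussians
  PQRST template.

The RR-dynamics change is the declared, tunable ECG signature of VT that a
downstream classifier can learn; cohort statistics default to an
in-hospital cardiovascular population (age 59 ± 15 y, 73% male, rest/VT/peak
VO2 3.9/14.0/21.8 mL/kg/min, HR 75/103/136 bpm).

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .gas import BreathSeries

__all__ = [
    "ExerciseProtocol",
    "PhysiologyParams",
    "RRSeries",
    "ECGTrace",
    "ECGMorphology",
    "CPXSession",
    "simulate_protocol",
    "simulate_gas_exchange",
    "simulate_rr_intervals",
    "synthesize_ecg",
    "simulate_cohort",
    "detect_r_peaks",
    "zero_signal_params",
]


@dataclass(frozen=True)
class ExerciseProtocol:
    """Rest / warm-up / ramp / recovery timing of one ergometer session."""

    ramp_rate: float                  # W/min
    peak_work_rate: float             # W
    rest_duration: float = 120.0      # s
    warmup_duration: float = 120.0    # s
    recovery_duration: float = 180.0  # s

    def __post_init__(self) -> None:
        for name in ("ramp_rate", "peak_work_rate", "rest_duration",
                     "warmup_duration", "recovery_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def exercise_duration(self) -> float:
        """Ramp duration in seconds: peak work rate / ramp rate."""
        return self.peak_work_rate / self.ramp_rate * 60.0

    @property
    def exercise_start(self) -> float:
        return self.rest_duration + self.warmup_duration

    @property
    def exercise_end(self) -> float:
        return self.exercise_start + self.exercise_duration

    @property
    def total_duration(self) -> float:
        return self.exercise_end + self.recovery_duration

    @property
    def phase_boundaries(self) -> tuple[float, float, float, float]:
        """(rest end, exercise start, exercise end, session end) in seconds."""
        return (self.rest_duration, self.exercise_start,
                self.exercise_end, self.total_duration)

    def work_rate(self, t) -> np.ndarray:
        """Ergometer load (W) at session time ``t`` (s); 0 outside the ramp."""
        t = np.asarray(t, dtype=float)
        te = np.clip(t - self.exercise_start, 0.0, self.exercise_duration)
        return self.ramp_rate * te / 60.0


def simulate_protocol(ramp_rate: float, peak_work_rate: float,
                      **kwargs) -> ExerciseProtocol:
    """Build a standard RAMP protocol (2-min rest, 2-min warm-up, 3-min recovery)."""
    return ExerciseProtocol(ramp_rate=ramp_rate, peak_work_rate=peak_work_rate,
                            **kwargs)


@dataclass
class PhysiologyParams:
    """Tunable physiology of the simulator; defaults follow the cohort means.

    ``hr_vt_frac`` is the fraction of HR reserve reached at VT (103 bpm
    between 75 and 136 gives ~0.46); set it to ``None`` for a straight
    rest-to-peak HR trajectory carrying no VT information.  ``hrv_below`` /
    ``hrv_above`` are the RR oscillation amplitudes (s) on either side of
    VT; making them equal removes the second VT signature.
    """

    resting_vo2: float = 3.9        # mL/kg/min
    vo2_gain: float = 10.0 / 64.7   # mL/kg/min per W (10 mL/min/W at 64.7 kg)
    vt_vo2_mean: float = 14.0       # mL/kg/min
    vt_vo2_sd: float = 4.5
    peak_vo2_mean: float = 21.8     # mL/kg/min
    peak_vo2_sd: float = 7.4
    vslope_below: float = 0.85      # VCO2/VO2 slope below VT
    vslope_above: float = 1.25      # and above VT
    rq_rest: float = 0.95           # sets the VCO2-on-VO2 intercept (> slope_below)
    ve_vco2_gain: float = 30.2      # dimensionless VE/VCO2 slope below RCP
    rcp_ve_factor: float = 1.4      # VE slope multiplier above RCP
    rcp_fraction: float = 0.6       # position of RCP between VT and peak
    hr_rest: float = 75.0           # bpm
    hr_peak: float = 136.0          # bpm
    hr_vt_frac: float | None = 0.46
    hrv_below: float = 0.06         # s, RR oscillation amplitude before VT
    hrv_above: float = 0.012        # s, after VT
    hrv_freq: float = 0.25          # Hz, respiratory-sinus-like modulation
    rr_jitter_sd: float = 0.005     # s, white RR jitter
    af_mode: bool = False
    af_rr_cv: float = 0.15          # multiplicative RR spread in AF
    breath_noise_sd: float = 0.25   # mL/kg/min, per-channel gas noise

    def __post_init__(self) -> None:
        if not self.vslope_below < self.vslope_above:
            raise ValueError("vslope_below must be < vslope_above")
        if not self.af_mode and self.hrv_above > self.hrv_below:
            raise ValueError("hrv_above must not exceed hrv_below")
        if not 0.0 < self.rcp_fraction < 1.0:
            raise ValueError("rcp_fraction must be in (0, 1)")
        if self.hr_rest >= self.hr_peak:
            raise ValueError("hr_rest must be below hr_peak")
        if self.hr_vt_frac is not None and not 0.0 < self.hr_vt_frac < 1.0:
            raise ValueError("hr_vt_frac must be in (0, 1) or None")


def zero_signal_params(**overrides) -> PhysiologyParams:
    """Physiology whose ECG carries no VT information (negative control).

    The HR trajectory runs straight from rest to peak and the RR modulation
    amplitude is identical on both sides of VT; the gas-exchange breakpoint
    is untouched, so VT remains detectable from gas but not from ECG.
    """
    base = dict(hr_vt_frac=None, hrv_above=0.06, hrv_below=0.06)
    base.update(overrides)
    return PhysiologyParams(**base)


@dataclass
class RRSeries:
    """Beat times (s from session start) and the preceding RR intervals (s)."""

    beat_times: np.ndarray
    rr_intervals: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_intervals = np.asarray(self.rr_intervals, dtype=float)
        if len(self.beat_times) != len(self.rr_intervals):
            raise ValueError("beat_times and rr_intervals must align")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.rr_intervals <= 0):
            raise ValueError("rr_intervals must be positive")


@dataclass
class ECGTrace:
    """Single-lead voltage trace (mV) with the protocol's phase boundaries."""

    voltage: np.ndarray
    sampling_rate: float = 1000.0
    phase_boundaries: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=np.float32)
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage must be finite")

    @property
    def duration(self) -> float:
        return len(self.voltage) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.voltage)) / self.sampling_rate


@dataclass(frozen=True)
class ECGMorphology:
    """Sum-of-Gaussians PQRST beat template.

    Each wave is (center offset, amplitude mV, width s).  QRS offsets are
    fixed in seconds; P and T offsets — and the T width — scale with the
    local RR interval, giving the mild rate dependence of repolarization.
    """

    p_offset_frac: float = -0.20   # × RR
    p_amp: float = 0.10
    p_width: float = 0.022
    q_offset: float = -0.035       # s
    q_amp: float = -0.10
    q_width: float = 0.008
    r_amp: float = 1.0
    r_width: float = 0.009
    s_offset: float = 0.035        # s
    s_amp: float = -0.15
    s_width: float = 0.010
    t_offset_frac: float = 0.30    # × RR
    t_amp: float = 0.30
    t_width_frac: float = 0.045    # × RR

    def waves(self, rr: float):
        """Concrete (offset, amplitude, width) triples for a beat with this RR."""
        return (
            (self.p_offset_frac * rr, self.p_amp, self.p_width),
            (self.q_offset, self.q_amp, self.q_width),
            (0.0, self.r_amp, self.r_width),
            (self.s_offset, self.s_amp, self.s_width),
            (self.t_offset_frac * rr, self.t_amp, self.t_width_frac * rr),
        )


@dataclass
class CPXSession:
    """One subject's complete synthetic CPX record."""

    id: str
    age: float
    sex: str                       # "male" | "female"
    weight: float                  # kg
    protocol: ExerciseProtocol
    breaths: BreathSeries
    ecg: ECGTrace | None
    true_vt_time: float | None     # s from exercise onset (synthetic only)
    true_vt_vo2: float | None = None  # mL/kg/min at the constructed breakpoint
    af: bool = False
    beta_blocker: bool = False

    def __post_init__(self) -> None:
        if self.true_vt_time is not None:
            if not 0.0 < self.true_vt_time < self.protocol.exercise_duration:
                raise ValueError("true_vt_time must lie inside the exercise phase")


def _vo2_trajectory(t: np.ndarray, protocol: ExerciseProtocol,
                    phys: PhysiologyParams) -> np.ndarray:
    """Noiseless VO2 (mL/kg/min) on the session clock; recovery decays (tau 60 s)."""
    vo2 = phys.resting_vo2 + phys.vo2_gain * protocol.work_rate(t)
    peak = phys.resting_vo2 + phys.vo2_gain * protocol.peak_work_rate
    rec = t >= protocol.exercise_end
    vo2[rec] = phys.resting_vo2 + (peak - phys.resting_vo2) * \
        np.exp(-(t[rec] - protocol.exercise_end) / 60.0)
    return vo2


def simulate_gas_exchange(protocol: ExerciseProtocol, phys: PhysiologyParams,
                          vt_time: float, rng_seed: int,
                          weight: float = 64.7) -> BreathSeries:
    """Breath-by-breath gas series with an exact V-slope breakpoint at VT.

    ``vt_time`` is seconds from exercise onset.  VO2 follows the ramp
    (10 mL/min/W equivalent); VCO2 is piecewise-linear in VO2 with slope
    ``vslope_below`` before the VT breakpoint and ``vslope_above`` after;
    VE tracks VCO2 at ``ve_vco2_gain`` with a steeper slope above the RCP.
    With ``breath_noise_sd = 0`` the output is noiseless and the breakpoint
    sits exactly at VO2(vt_time).
    """
    if not 0.0 < vt_time < protocol.exercise_duration:
        raise ValueError("vt_time must lie inside the exercise phase")
    rng = np.random.default_rng(rng_seed)
    times = []
    t = 0.0
    while t < protocol.total_duration:
        t += rng.uniform(2.4, 3.6)  # breath interval ~3 s
        if t >= protocol.total_duration:
            break
        times.append(t)
    times = np.asarray(times)
    vo2 = _vo2_trajectory(times, protocol, phys)
    vt_vo2 = phys.resting_vo2 + phys.vo2_gain * protocol.work_rate(
        np.array([protocol.exercise_start + vt_time]))[0]
    intercept = phys.rq_rest * phys.resting_vo2 - phys.vslope_below * phys.resting_vo2
    vco2_at = lambda v: np.where(
        v <= vt_vo2,
        intercept + phys.vslope_below * v,
        intercept + phys.vslope_below * vt_vo2 + phys.vslope_above * (v - vt_vo2))
    vco2 = vco2_at(vo2)
    # VE breakpoint at the respiratory compensation point.
    rcp_time = vt_time + phys.rcp_fraction * (protocol.exercise_duration - vt_time)
    rcp_vo2 = phys.resting_vo2 + phys.vo2_gain * protocol.work_rate(
        np.array([protocol.exercise_start + rcp_time]))[0]
    rcp_vco2 = float(vco2_at(np.array([rcp_vo2]))[0])
    kg = weight / 1000.0  # mL/kg/min -> L/min
    ve = np.where(
        vco2 <= rcp_vco2,
        phys.ve_vco2_gain * vco2 * kg,
        phys.ve_vco2_gain * (rcp_vco2 + phys.rcp_ve_factor * (vco2 - rcp_vco2)) * kg)
    if phys.breath_noise_sd > 0:
        vo2 = vo2 + rng.normal(0.0, phys.breath_noise_sd, len(times))
        vco2 = vco2 + rng.normal(0.0, phys.breath_noise_sd, len(times))
        ve = ve + rng.normal(0.0, phys.breath_noise_sd * phys.ve_vco2_gain * kg,
                             len(times))
    return BreathSeries(times, np.maximum(vo2, 0.0), np.maximum(vco2, 0.0),
                        np.maximum(ve, 0.0))


def _hr_trajectory(t: np.ndarray, protocol: ExerciseProtocol,
                   phys: PhysiologyParams, vt_time: float) -> np.ndarray:
    """Mean HR (bpm) on the session clock.

    During the ramp HR climbs from rest to peak; with ``hr_vt_frac`` set it
    reaches that fraction of HR reserve exactly at VT and then climbs with
    a different (steeper, for typical VT positions) slope to peak.
    """
    t = np.asarray(t, dtype=float)
    hr = np.full_like(t, phys.hr_rest)
    reserve = phys.hr_peak - phys.hr_rest
    te = t - protocol.exercise_start
    dur = protocol.exercise_duration
    ex = (te >= 0) & (te < dur)
    if phys.hr_vt_frac is None:
        hr[ex] = phys.hr_rest + reserve * te[ex] / dur
    else:
        hr_vt = phys.hr_rest + phys.hr_vt_frac * reserve
        below = ex & (te < vt_time)
        above = ex & (te >= vt_time)
        hr[below] = phys.hr_rest + (hr_vt - phys.hr_rest) * te[below] / vt_time
        hr[above] = hr_vt + (phys.hr_peak - hr_vt) * (te[above] - vt_time) / \
            (dur - vt_time)
    rec = te >= dur
    hr[rec] = phys.hr_rest + 10.0 + (phys.hr_peak - phys.hr_rest - 10.0) * \
        np.exp(-(te[rec] - dur) / 60.0)
    return hr


def simulate_rr_intervals(protocol: ExerciseProtocol, phys: PhysiologyParams,
                          vt_time: float, rng_seed: int) -> RRSeries:
    """RR series whose oscillation amplitude drops at VT.

    Before VT the RR intervals carry a sinusoidal modulation of amplitude
    ``hrv_below`` (respiratory-sinus-like, ``hrv_freq`` Hz); from VT onward
    the amplitude is ``hrv_above``.  In AF mode the modulation is replaced
    by independent multiplicative RR draws with no beat-to-beat structure.
    Instantaneous HR is kept within [30, 220] bpm.
    """
    if not 0.0 < vt_time < protocol.exercise_duration:
        raise ValueError("vt_time must lie inside the exercise phase")
    rng = np.random.default_rng(rng_seed)
    vt_session = protocol.exercise_start + vt_time
    beat_times, rrs = [], []
    t = 0.0
    while True:
        hr = float(_hr_trajectory(np.array([t]), protocol, phys, vt_time)[0])
        base = 60.0 / hr
        if phys.af_mode:
            rr = base * float(np.exp(rng.normal(0.0, phys.af_rr_cv)))
        else:
            amp = phys.hrv_below if t < vt_session else phys.hrv_above
            rr = base + amp * np.sin(2.0 * np.pi * phys.hrv_freq * t)
            if phys.rr_jitter_sd > 0:
                rr += float(rng.normal(0.0, phys.rr_jitter_sd))
        rr = float(np.clip(rr, 60.0 / 220.0, 60.0 / 30.0))
        t += rr
        if t >= protocol.total_duration:
            break
        beat_times.append(t)
        rrs.append(rr)
    return RRSeries(np.asarray(beat_times), np.asarray(rrs))


def synthesize_ecg(rr: RRSeries, morphology: ECGMorphology | None = None,
                   sampling_rate: float = 1000.0,
                   total_duration: float | None = None,
                   phase_boundaries: tuple[float, float, float, float] | None = None,
                   ) -> ECGTrace:
    """Render an RR series as a single-lead voltage trace.

    Each beat is the sum of five Gaussian bumps (P, Q, R, S, T) positioned
    relative to the beat time and stretched with the local RR.  The R peak
    has the template's ``r_amp`` and coincides with the beat time to within
    one sample.
    """
    if sampling_rate < 100.0:
        raise ValueError("sampling_rate must be at least 100 Hz")
    morph = morphology or ECGMorphology()
    if total_duration is None:
        total_duration = float(rr.beat_times[-1] + rr.rr_intervals[-1])
    n = int(round(total_duration * sampling_rate))
    voltage = np.zeros(n, dtype=np.float64)
    min_support = morph.s_offset - morph.q_offset
    for t_beat, rr_local in zip(rr.beat_times, rr.rr_intervals):
        if rr_local < min_support:
            raise ValueError("RR interval shorter than the QRS template support")
        for offset, amp, width in morph.waves(rr_local):
            center = t_beat + offset
            lo = max(int(np.floor((center - 4 * width) * sampling_rate)), 0)
            hi = min(int(np.ceil((center + 4 * width) * sampling_rate)) + 1, n)
            if hi <= lo:
                continue
            ts = np.arange(lo, hi) / sampling_rate
            voltage[lo:hi] += amp * np.exp(-0.5 * ((ts - center) / width) ** 2)
    return ECGTrace(voltage=voltage, sampling_rate=sampling_rate,
                    phase_boundaries=phase_boundaries or (0, 0, 0, total_duration))


def detect_r_peaks(trace: ECGTrace, min_height: float = 0.4,
                   min_distance_s: float = 0.22) -> np.ndarray:
    """R-peak times (s) recovered from a trace; the simulator round-trip oracle."""
    peaks, _ = find_peaks(trace.voltage, height=min_height,
                          distance=max(int(min_distance_s * trace.sampling_rate), 1))
    return peaks / trace.sampling_rate


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, max_tries: int = 1000) -> float:
    for _ in range(max_tries):
        x = float(rng.normal(mean, sd))
        if lo < x < hi:
            return x
    raise RuntimeError(
        f"could not draw N({mean}, {sd}) inside ({lo}, {hi}) "
        f"after {max_tries} tries")


def simulate_cohort(n: int, phys: PhysiologyParams | None = None,
                    seed: int = 0, fs: float = 1000.0,
                    af_fraction: float = 0.096,
                    include_ecg: bool = True) -> list[CPXSession]:
    """Draw ``n`` independent synthetic subjects.

    Per-subject VT-VO2 ~ N(vt_vo2_mean, vt_vo2_sd) truncated between resting
    and peak VO2 (peak ~ N(peak_vo2_mean, peak_vo2_sd)); demographics follow
    the cohort statistics (age 58.9 ± 14.6 y, 73.1% male, weight
    64.7 ± 13.8 kg, 68.1% beta-blocker, AF fraction configurable); HR rest
    and peak are N(75, 13) and N(136, 27).  Infeasible draws are redrawn
    with a bounded retry count.  Fully reproducible from ``seed``.

    ``fs`` is the ECG sampling rate; 1000 Hz matches the recording hardware,
    lower rates (e.g. 250 Hz) give proportionally cheaper desk-scale runs.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    phys = phys or PhysiologyParams()
    root = np.random.default_rng(seed)
    subject_seeds = root.integers(0, 2**31 - 1, size=(n, 3))
    sessions = []
    for i in range(n):
        rng = np.random.default_rng(int(subject_seeds[i, 0]))
        age = _truncated_normal(rng, 58.9, 14.6, 20.0, 90.0)
        sex = "male" if rng.random() < 0.731 else "female"
        weight = _truncated_normal(rng, 64.7, 13.8, 35.0, 120.0)
        beta_blocker = bool(rng.random() < 0.681)
        af = bool(rng.random() < af_fraction)
        rest_vo2 = _truncated_normal(rng, phys.resting_vo2, 0.8, 2.0, 6.5)
        peak = _truncated_normal(rng, phys.peak_vo2_mean, phys.peak_vo2_sd,
                                 rest_vo2 + 6.0, 60.0)
        # VT sits at 25-80% of the VO2 reserve (it is rarely adjacent to
        # rest or peak), which also keeps enough 30-s windows on each side
        # of the breakpoint for the gas detectors.
        vt_vo2 = _truncated_normal(rng, phys.vt_vo2_mean, phys.vt_vo2_sd,
                                   rest_vo2 + 0.25 * (peak - rest_vo2),
                                   rest_vo2 + 0.80 * (peak - rest_vo2))
        hr_rest = _truncated_normal(rng, phys.hr_rest, 13.0, 45.0, 110.0)
        hr_peak = _truncated_normal(rng, phys.hr_peak, 27.0, hr_rest + 30.0, 210.0)
        subj = dataclasses.replace(
            phys, resting_vo2=rest_vo2, vo2_gain=10.0 / weight,
            hr_rest=hr_rest, hr_peak=hr_peak, af_mode=af or phys.af_mode,
            hr_vt_frac=(None if phys.hr_vt_frac is None else
                        float(np.clip(phys.hr_vt_frac + rng.normal(0.0, 0.03),
                                      0.2, 0.8))))
        ramp_rate = float(rng.uniform(10.0, 15.0))
        peak_wr = (peak - rest_vo2) / subj.vo2_gain
        protocol = simulate_protocol(ramp_rate, peak_wr)
        vt_time = protocol.exercise_duration * (vt_vo2 - rest_vo2) / (peak - rest_vo2)
        breaths = simulate_gas_exchange(protocol, subj, vt_time,
                                        int(subject_seeds[i, 1]), weight=weight)
        ecg = None
        if include_ecg:
            rr = simulate_rr_intervals(protocol, subj, vt_time,
                                       int(subject_seeds[i, 2]))
            morph = ECGMorphology(r_amp=float(rng.uniform(0.8, 1.4)))
            ecg = synthesize_ecg(rr, morph, sampling_rate=fs,
                                 total_duration=protocol.total_duration,
                                 phase_boundaries=protocol.phase_boundaries)
        sessions.append(CPXSession(
            id=f"S{i:04d}", age=age, sex=sex, weight=weight, protocol=protocol,
            breaths=breaths, ecg=ecg, true_vt_time=vt_time, true_vt_vo2=vt_vo2,
            af=af, beta_blocker=beta_blocker))
    return sessions
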
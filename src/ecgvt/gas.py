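"""Breath-by-breath gas-exchange analysis and ventilatory-threshold detection.

Implements the conventional trio of VT detectors (modified V-slope,
ventilatory equivalent, excess CO2) on 30-s averaged gas series, a median
consensus rule, and the derived CPX metrics (peak VO2, VE-VCO2 slope,
respiratory quotients).

Conventions
-----------
* All times handed to these functions are seconds from **exercise onset**
  (the start of the ramp), not from the start of the recording.
* 30-s averaging windows are half-open ``[start, start + 30)`` and tile the
  record from exercise onset; the trailing partial window is dropped.
* VO2 and VCO2 are in mL/kg/min; VE is in L/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BreathSeries",
    "AveragedSeries",
    "VTResult",
    "GasDerivedMetrics",
    "average_30s",
    "detect_vt_vslope",
    "detect_vt_ventilatory_equivalent",
    "detect_vt_excess_co2",
    "consensus_vt",
    "peak_vo2",
    "ve_vco2_slope",
    "vo2_at_time",
    "detect_rcp",
    "derive_metrics",
]


@dataclass
class BreathSeries:
    """Breath-by-breath gas exchange samples on the session clock."""

    breath_times: np.ndarray  # s from start of recording
    vo2: np.ndarray           # mL/kg/min
    vco2: np.ndarray          # mL/kg/min
    ve: np.ndarray            # L/min

    def __post_init__(self) -> None:
        self.breath_times = np.asarray(self.breath_times, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        self.ve = np.asarray(self.ve, dtype=float)
        n = len(self.breath_times)
        if not (len(self.vo2) == len(self.vco2) == len(self.ve) == n):
            raise ValueError("all breath channels must have equal length")
        if np.any(np.diff(self.breath_times) <= 0):
            raise ValueError("breath_times must be strictly increasing")
        if min(self.vo2.min(initial=0.0), self.vco2.min(initial=0.0),
               self.ve.min(initial=0.0)) < 0:
            raise ValueError("gas values must be non-negative")


@dataclass
class AveragedSeries:
    """30-s window means of each gas channel, aligned to exercise onset."""

    window_starts: np.ndarray  # s from exercise onset
    vo2: np.ndarray
    vco2: np.ndarray
    ve: np.ndarray
    window_s: float = 30.0

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        self.ve = np.asarray(self.ve, dtype=float)

    @property
    def mid_times(self) -> np.ndarray:
        return self.window_starts + self.window_s / 2.0

    def __len__(self) -> int:
        return len(self.window_starts)


@dataclass
class VTResult:
    """A ventilatory-threshold estimate from one detector (or the consensus)."""

    method: str                     # vslope | vent_equiv | excess_co2 | consensus
    vt_time: float = float("nan")   # s from exercise onset
    vt_vo2: float = float("nan")    # mL/kg/min
    ok: bool = True
    reason: str = ""

    @classmethod
    def failed(cls, method: str, reason: str) -> "VTResult":
        return cls(method=method, ok=False, reason=reason)


@dataclass
class GasDerivedMetrics:
    peak_vo2: float
    ve_vco2_slope: float
    rq_at_vt: float
    rq_at_peak: float
    rcp_time: float


def average_30s(breaths: BreathSeries, exercise_start: float = 0.0,
                window_s: float = 30.0) -> AveragedSeries:
    """Average each gas channel over non-overlapping 30-s windows.

    Windows tile the record from ``exercise_start`` (session clock) onward;
    the returned window start times are relative to exercise onset.  A
    breath at time ``t`` belongs to window ``floor((t - exercise_start)/30)``
    (half-open intervals).  The trailing partial window is dropped.
    """
    t = breaths.breath_times - exercise_start
    span = breaths.breath_times[-1] - exercise_start
    if span < window_s:
        raise ValueError("record shorter than one averaging window")
    n_win = int(np.floor(span / window_s))
    starts = np.arange(n_win) * window_s
    out = {ch: np.empty(n_win) for ch in ("vo2", "vco2", "ve")}
    idx = np.floor(t / window_s).astype(int)
    for w in range(n_win):
        mask = idx == w
        if not mask.any():
            raise ValueError(f"no breaths fall in averaging window {w} "
                             f"[{starts[w]:.0f}, {starts[w] + window_s:.0f}) s")
        for ch in out:
            out[ch][w] = getattr(breaths, ch)[mask].mean()
    return AveragedSeries(starts, out["vo2"], out["vco2"], out["ve"], window_s)


def _exercise_window_mask(avg: AveragedSeries,
                          exercise_bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = exercise_bounds
    return (avg.window_starts >= lo - 1e-9) & \
           (avg.window_starts + avg.window_s <= hi + 1e-9)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, rss)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        return float("nan"), ym, float(((y - ym) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    return slope, intercept, float((resid ** 2).sum())


def _hinge_rss(xs: np.ndarray, ys: np.ndarray, c: float):
    """LS fit of the continuous broken line y = a + m1 x + d (x-c)+."""
    A = np.column_stack([np.ones_like(xs), xs, np.maximum(xs - c, 0.0)])
    coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
    rss = float(((A @ coef - ys) ** 2).sum())
    return rss, coef


def _hinge_scan(xs: np.ndarray, ys: np.ndarray, lo: float, hi: float,
                n_grid: int = 120):
    """Minimize hinge-model RSS over the breakpoint: grid scan + refinement."""
    from scipy.optimize import minimize_scalar

    grid = np.linspace(lo, hi, n_grid)
    rss_grid = [_hinge_rss(xs, ys, c)[0] for c in grid]
    c0 = grid[int(np.argmin(rss_grid))]
    delta = grid[1] - grid[0]
    res = minimize_scalar(lambda c: _hinge_rss(xs, ys, c)[0],
                          bounds=(max(lo, c0 - delta), min(hi, c0 + delta)),
                          method="bounded",
                          options={"xatol": 1e-9 * max(hi - lo, 1.0)})
    c = float(res.x)
    rss, coef = _hinge_rss(xs, ys, c)
    return c, rss, coef


def two_segment_fit(x: np.ndarray, y: np.ndarray,
                    require_slope_increase: bool = True):
    """Continuous two-segment least squares with breakpoint search.

    Fits the segmented (hinge) model ``y = a + m1 x + d (x - c)+`` — two
    straight lines meeting at the breakpoint ``c`` — by exhaustive grid
    scan over ``c`` with local refinement.  After 30-s averaging the
    window straddling the kink lies on neither limb; when that single
    sample's residual dominates the fit (as it does on otherwise noiseless
    data) it is treated as the transition sample and the fit is repeated
    without it, which recovers a constructed breakpoint exactly.  The
    added slope ``d`` must be a genuine increase, not floating-point noise
    on collinear data.

    Returns ``(i, (m1, b1), (m2, b2), x_break)`` where ``i`` indexes the
    sample nearest the breakpoint, or ``None`` when the slope-ordering
    constraint cannot be met.
    """
    n = len(x)
    c, rss, coef = _hinge_scan(x, y, x[1], x[-2])
    i = int(np.argmin(np.abs(x - c)))
    if 1 <= i <= n - 2 and rss > 0:
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        c2, rss2, coef2 = _hinge_scan(x[mask], y[mask], x[i - 1], x[i + 1])
        # The breakpoint is identifiable without the transition sample only
        # when each limb keeps >= 2 clean points; otherwise the excluded
        # fit is underdetermined and the all-points fit is retained.
        identifiable = ((x[mask] < c2).sum() >= 2 and (x[mask] > c2).sum() >= 2)
        if identifiable and rss2 < 0.5 * rss:
            c, rss, coef = c2, rss2, coef2
    a, m1, d = (float(v) for v in coef)
    margin = 1e-8 + 0.01 * max(abs(m1), abs(m1 + d))
    if require_slope_increase and not (d > margin):
        return None
    i = int(np.argmin(np.abs(x - c)))
    return i, (m1, a), (m1 + d, a - d * c), c


def _time_at_vo2(avg: AveragedSeries, mask: np.ndarray, target_vo2: float) -> float:
    """Invert the (mid-time, VO2) relation by linear interpolation."""
    t = avg.mid_times[mask]
    v = avg.vo2[mask]
    above = np.nonzero(v >= target_vo2)[0]
    if len(above) == 0:
        return float(t[-1])
    j = above[0]
    if j == 0 or v[j] == v[j - 1]:
        return float(t[j])
    frac = (target_vo2 - v[j - 1]) / (v[j] - v[j - 1])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def detect_vt_vslope(avg: AveragedSeries,
                     exercise_bounds: tuple[float, float]) -> VTResult:
    """Modified V-slope: breakpoint of VCO2 plotted against VO2.

    Two straight segments are fit over every candidate breakpoint
    (exhaustive search, transition window excluded from both segments);
    the upper segment must be steeper than the lower.  On noiseless
    piecewise-linear input the intersection recovers the constructed
    breakpoint exactly.
    """
    mask = _exercise_window_mask(avg, exercise_bounds)
    if mask.sum() < 6:
        raise ValueError("need at least 6 averaged windows inside exercise")
    x = avg.vo2[mask]
    y = avg.vco2[mask]
    fit = two_segment_fit(x, y)
    if fit is None:
        return VTResult.failed("vslope", "no breakpoint with increasing slope")
    _, _, _, vt_vo2 = fit
    vt_time = _time_at_vo2(avg, mask, vt_vo2)
    return VTResult("vslope", vt_time=vt_time, vt_vo2=vt_vo2)


def detect_vt_ventilatory_equivalent(avg: AveragedSeries,
                                     exercise_bounds: tuple[float, float],
                                     ve_vco2_tol: float = 0.02) -> VTResult:
    """Ventilatory equivalent method.

    VT is the earliest window after the VE/VO2 nadir at which VE/VO2 has
    risen for two consecutive windows while VE/VCO2 stays within
    ``ve_vco2_tol`` (fractional) of its running minimum — i.e. a systematic
    VE/VO2 rise without a concomitant VE/VCO2 rise.
    """
    mask = _exercise_window_mask(avg, exercise_bounds)
    if mask.sum() < 6:
        raise ValueError("need at least 6 averaged windows inside exercise")
    starts = avg.window_starts[mask]
    eq_o2 = avg.ve[mask] / avg.vo2[mask]
    eq_co2 = avg.ve[mask] / avg.vco2[mask]
    n = len(eq_o2)
    nadir = int(np.argmin(eq_o2))
    run_min = np.minimum.accumulate(eq_co2)
    for w in range(nadir + 1, n - 1):
        rising = eq_o2[w] > eq_o2[w - 1] and eq_o2[w + 1] > eq_o2[w]
        co2_flat = eq_co2[w] <= run_min[w - 1] * (1.0 + ve_vco2_tol)
        if rising and co2_flat:
            return VTResult("vent_equiv", vt_time=float(starts[w]),
                            vt_vo2=float(avg.vo2[mask][w]))
    return VTResult.failed("vent_equiv",
                           "no sustained VE/VO2 rise without VE/VCO2 rise")


def detect_vt_excess_co2(avg: AveragedSeries,
                         exercise_bounds: tuple[float, float]) -> VTResult:
    """Excess CO2 method: breakpoint of VCO2^2/VO2 - VCO2 against time."""
    mask = _exercise_window_mask(avg, exercise_bounds)
    if mask.sum() < 6:
        raise ValueError("need at least 6 averaged windows inside exercise")
    vo2 = avg.vo2[mask]
    vco2 = avg.vco2[mask]
    if np.any(vo2 <= 0):
        raise ValueError("excess CO2 undefined: non-positive VO2 window")
    if np.all(vco2 == 0):
        raise ValueError("excess CO2 degenerate: VCO2 identically zero")
    exco2 = vco2 ** 2 / vo2 - vco2
    t = avg.mid_times[mask]
    fit = two_segment_fit(t, exco2)
    if fit is None:
        return VTResult.failed("excess_co2", "no upward excess-CO2 breakpoint")
    _, _, _, t_break = fit
    vt_time = float(t_break)
    lo, hi = exercise_bounds
    vt_time = float(np.clip(vt_time, lo, hi))
    idx = int(np.clip(np.searchsorted(avg.window_starts[mask], vt_time,
                                      side="right") - 1, 0, mask.sum() - 1))
    return VTResult("excess_co2", vt_time=vt_time, vt_vo2=float(vo2[idx]))


def consensus_vt(results: list[VTResult],
                 avg: AveragedSeries | None = None) -> VTResult:
    """Median of the successful detectors' threshold times.

    The median (midpoint for an even count) is robust to a single divergent
    method.  When an averaged series is supplied the consensus VO2 is
    re-read from the window containing the consensus time.
    """
    ok = [r for r in results if r.ok]
    if not ok:
        return VTResult.failed(
            "consensus", "all detectors failed: " +
            "; ".join(f"{r.method}: {r.reason}" for r in results))
    vt_time = float(np.median([r.vt_time for r in ok]))
    if avg is not None:
        vt_vo2 = vo2_at_time(avg, vt_time)
    else:
        vt_vo2 = float(np.median([r.vt_vo2 for r in ok]))
    return VTResult("consensus", vt_time=vt_time, vt_vo2=vt_vo2)


def peak_vo2(avg: AveragedSeries, exercise_bounds: tuple[float, float]) -> float:
    """Mean VO2 over the last fully-averaged 30 s of the exercise phase."""
    lo, hi = exercise_bounds
    if hi - lo < avg.window_s:
        raise ValueError("exercise phase shorter than 30 s")
    mask = _exercise_window_mask(avg, exercise_bounds)
    if not mask.any():
        raise ValueError("no complete averaging window inside exercise")
    return float(avg.vo2[mask][-1])


def ve_vco2_slope(avg: AveragedSeries, onset: float, rcp_time: float,
                  weight: float | None = None) -> float:
    """OLS slope of VE on VCO2 from exercise onset to the RCP.

    With ``weight`` (kg) given, VCO2 is converted from mL/kg/min to L/min so
    the slope is the conventional dimensionless ventilatory efficiency.
    """
    mask = (avg.window_starts >= onset - 1e-9) & \
           (avg.window_starts + avg.window_s <= rcp_time + 1e-9)
    if mask.sum() < 3:
        raise ValueError("need at least 3 windows between onset and RCP")
    x = avg.vco2[mask]
    if weight is not None:
        x = x * weight / 1000.0
    y = avg.ve[mask]
    if np.ptp(x) == 0:
        raise ValueError("VCO2 constant over fit range")
    slope, _, _ = _ols_line(x, y)
    return slope


def vo2_at_time(avg: AveragedSeries, t: float) -> float:
    """VO2 of the 30-s window containing time ``t`` (s from exercise onset).

    Half-open windows: a boundary time belongs to the later window.
    """
    if t < avg.window_starts[0] - 1e-9:
        raise ValueError(f"time {t:.1f} s precedes the averaged record")
    idx = int(np.floor((t - avg.window_starts[0]) / avg.window_s))
    if idx >= len(avg):
        raise ValueError(f"time {t:.1f} s beyond the averaged record")
    return float(avg.vo2[idx])


def detect_rcp(avg: AveragedSeries,
               exercise_bounds: tuple[float, float]) -> float:
    """Respiratory compensation point: breakpoint of VE against VCO2.

    Uses the same two-segment machinery as the V-slope detector; returns
    the time (s from exercise onset) at which the upper, steeper VE
    segment begins, or the end of exercise when no breakpoint exists.
    """
    mask = _exercise_window_mask(avg, exercise_bounds)
    if mask.sum() < 6:
        raise ValueError("need at least 6 averaged windows inside exercise")
    fit = two_segment_fit(avg.vco2[mask], avg.ve[mask])
    if fit is None:
        return float(exercise_bounds[1])
    i, _, _, _ = fit
    return float(avg.window_starts[mask][i])


def derive_metrics(avg: AveragedSeries, exercise_bounds: tuple[float, float],
                   vt: VTResult, weight: float | None = None) -> GasDerivedMetrics:
    """Bundle the conventional CPX summary metrics for one session."""
    rcp_time = detect_rcp(avg, exercise_bounds)
    pk = peak_vo2(avg, exercise_bounds)
    slope = ve_vco2_slope(avg, exercise_bounds[0], rcp_time, weight=weight)
    mask = _exercise_window_mask(avg, exercise_bounds)
    rq = avg.vco2[mask] / avg.vo2[mask]
    if vt.ok:
        idx = int(np.floor((vt.vt_time - avg.window_starts[0]) / avg.window_s))
        rq_vt = float(rq[min(idx, mask.sum() - 1)])
    else:
        rq_vt = float("nan")
    return GasDerivedMetrics(peak_vo2=pk, ve_vco2_slope=slope,
                             rq_at_vt=rq_vt, rq_at_peak=float(rq[-1]),
                             rcp_time=rcp_time)
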
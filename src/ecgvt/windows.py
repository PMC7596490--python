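"""Exercise-phase extraction, 30-s windowing, VT labeling, and cohort split.

The classifier consumes fixed-length 30-s voltage windows cut from the
exercise phase only, each labeled 0 (entirely before VT) or 1 (containing
or after VT), together with three covariates: age (scaled by 1/100), sex
(0 = female, 1 = male), and exercise time.  Windows are half-open
``[start, start + 30)`` intervals, 0-indexed from exercise onset; the
trailing remainder of the phase is dropped.

The cohort split is by session — every window of a subject lands in exactly
one of the derivation / validation / test cohorts — which prevents
near-duplicate windows from leaking across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CPXSession, ECGTrace, ExerciseProtocol

__all__ = [
    "LabeledWindow",
    "CohortSplit",
    "extract_exercise_phase",
    "window_ecg",
    "label_windows",
    "assemble_features",
    "make_labeled_windows",
    "stack_windows",
    "split_cohorts",
    "AGE_SCALE",
    "EXERCISE_TIME_SCALE",
]

AGE_SCALE = 1.0 / 100.0
# Exercise time enters in units of 600 s (a typical ramp lasts ~10 min),
# keeping the covariate O(1) like the others.
EXERCISE_TIME_SCALE = 1.0 / 600.0


@dataclass
class LabeledWindow:
    session_id: str
    window_index: int        # 0-based from exercise onset
    start_time: float        # s from exercise onset
    voltage: np.ndarray      # window_s * fs samples
    label: int               # 0 before VT, 1 containing or after VT
    age: float               # years (unscaled)
    sex: int                 # 0 female, 1 male
    exercise_time: float     # s (see assemble_features)


@dataclass(frozen=True)
class CohortSplit:
    derivation_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.derivation_ids), set(self.validation_ids),
                set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("cohorts must be pairwise disjoint")

    def cohort_of(self, session_id: str) -> str:
        for name in ("derivation", "validation", "test"):
            if session_id in getattr(self, f"{name}_ids"):
                return name
        raise KeyError(session_id)


def extract_exercise_phase(ecg: ECGTrace,
                           protocol: ExerciseProtocol) -> np.ndarray:
    """Samples in ``[exercise_start, exercise_end)``; other phases discarded."""
    fs = ecg.sampling_rate
    lo = int(round(protocol.exercise_start * fs))
    hi = int(round(protocol.exercise_end * fs))
    if hi <= lo:
        raise ValueError("exercise phase is empty")
    if hi > len(ecg.voltage):
        raise ValueError("trace ends before the exercise phase does")
    return ecg.voltage[lo:hi]


def window_ecg(trace: np.ndarray, fs: float, window_s: float = 30.0) -> np.ndarray:
    """Cut a voltage array into consecutive non-overlapping 30-s windows.

    Returns an array of shape ``(n_windows, window_s * fs)``; the trailing
    remainder shorter than one window is dropped.
    """
    w = int(round(window_s * fs))
    n = len(trace) // w
    if n < 1:
        raise ValueError("trace shorter than one window")
    return trace[: n * w].reshape(n, w)


def label_windows(n_windows: int, vt_time: float,
                  window_s: float = 30.0) -> np.ndarray:
    """0/1 labels for consecutive windows: 0 iff the window ends at or before VT.

    Window ``i`` spans ``[i*30, (i+1)*30)``; its label is 0 when
    ``(i+1)*30 <= vt_time`` and 1 otherwise (the window containing VT and
    every later one).  Labels are therefore non-decreasing.
    """
    if vt_time < 0:
        raise ValueError("vt_time must be non-negative")
    ends = (np.arange(n_windows) + 1) * window_s
    return (ends > vt_time).astype(np.int8)


def assemble_features(window: LabeledWindow,
                      exercise_time_mode: str = "window_start",
                      total_exercise_duration: float | None = None,
                      zero_voltage: bool = False) -> dict:
    """Model input record: native-scale voltage plus scaled covariates.

    The voltage is passed unnormalized (the amplitude dynamics are part of
    the learnable signal).  ``exercise_time_mode`` selects what the
    exercise-time covariate means: ``"window_start"`` (the window's elapsed
    time from exercise onset; default) or ``"total_duration"`` (the
    subject's whole ramp duration, constant across their windows).
    ``zero_voltage`` substitutes an all-zero signal (the dummy-ECG ablation)
    while leaving label and covariates intact.
    """
    if exercise_time_mode == "window_start":
        ex_time = window.start_time
    elif exercise_time_mode == "total_duration":
        if total_exercise_duration is None:
            raise ValueError("total_duration mode needs total_exercise_duration")
        ex_time = total_exercise_duration
    else:
        raise ValueError(f"unknown exercise_time_mode {exercise_time_mode!r}")
    voltage = np.zeros_like(window.voltage) if zero_voltage else window.voltage
    return {
        "voltage": voltage,
        "covariates": np.array([window.age * AGE_SCALE,
                                float(window.sex),
                                ex_time * EXERCISE_TIME_SCALE]),
        "label": window.label,
        "session_id": window.session_id,
        "window_index": window.window_index,
    }


def make_labeled_windows(session: CPXSession, vt_time: float,
                         window_s: float = 30.0) -> list[LabeledWindow]:
    """Window one session's exercise-phase ECG and label against ``vt_time``.

    ``vt_time`` is seconds from exercise onset — normally the gas-analyzer
    consensus VT (the ground-truth time for purely synthetic checks).
    """
    if session.ecg is None:
        raise ValueError(f"session {session.id} has no ECG trace")
    trace = extract_exercise_phase(session.ecg, session.protocol)
    wins = window_ecg(trace, session.ecg.sampling_rate, window_s)
    labels = label_windows(len(wins), vt_time, window_s)
    sex_code = 1 if session.sex == "male" else 0
    return [
        LabeledWindow(session_id=session.id, window_index=i,
                      start_time=i * window_s, voltage=wins[i],
                      label=int(labels[i]), age=session.age, sex=sex_code,
                      exercise_time=i * window_s)
        for i in range(len(wins))
    ]


def stack_windows(windows: list[LabeledWindow],
                  exercise_time_mode: str = "window_start",
                  durations: dict[str, float] | None = None,
                  zero_voltage: bool = False):
    """Stack labeled windows into (X, C, y) model arrays plus window ids.

    Returns ``(X, C, y, ids)`` where ``X`` is float32 of shape
    ``(n, samples)``, ``C`` the scaled covariates ``(n, 3)``, ``y`` the 0/1
    labels and ``ids`` the list of (session_id, window_index).
    """
    records = [
        assemble_features(
            w, exercise_time_mode=exercise_time_mode,
            total_exercise_duration=(durations or {}).get(w.session_id),
            zero_voltage=zero_voltage)
        for w in windows
    ]
    X = np.stack([r["voltage"] for r in records]).astype(np.float32)
    C = np.stack([r["covariates"] for r in records]).astype(np.float32)
    y = np.array([r["label"] for r in records], dtype=np.float32)
    ids = [(r["session_id"], r["window_index"]) for r in records]
    return X, C, y, ids


def split_cohorts(session_ids: list[str],
                  fractions: tuple[float, float, float] = (0.373, 0.277, 0.350),
                  seed: int = 0) -> CohortSplit:
    """Randomly assign sessions to derivation/validation/test cohorts.

    Counts follow largest-remainder rounding of ``fractions`` (260 sessions
    with the default fractions give 97/72/91); assignment is a seeded
    permutation, by session.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(session_ids)
    if n < 3:
        raise ValueError("need at least as many sessions as cohorts")
    exact = np.array(fractions) * n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for idx in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[idx] += 1
    perm = np.random.default_rng(seed).permutation(n)
    ids = [session_ids[i] for i in perm]
    d, v = counts[0], counts[0] + counts[1]
    return CohortSplit(tuple(ids[:d]), tuple(ids[d:v]), tuple(ids[v:]))
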
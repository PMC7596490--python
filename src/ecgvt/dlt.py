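"""Deep-learning threshold (DLT): from per-window probabilities to a time.

The DLT is the start of the first 30-s window the classifier calls
at-or-after VT — operationally, the earliest window whose probability
reaches the decision threshold (default 0.5), with an optional smoothing
mode that demands ``k`` consecutive supra-threshold windows before firing.
Sessions in which no window reaches the threshold yield an explicit
"no DLT" result and are excluded (and counted) rather than silently
assigned a window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gas import AveragedSeries, vo2_at_time

__all__ = ["DLTResult", "estimate_dlt", "dlt_vo2"]


@dataclass
class DLTResult:
    dlt_window_index: int = -1
    dlt_time: float = float("nan")     # s from exercise onset (window start)
    dlt_vo2: float = float("nan")      # mL/kg/min, filled by ``dlt_vo2``
    decision_threshold: float = 0.5
    ok: bool = True
    reason: str = ""


def estimate_dlt(window_probs: np.ndarray, threshold: float = 0.5,
                 k: int = 1, window_s: float = 30.0) -> DLTResult:
    """Earliest window whose probability reaches ``threshold``.

    With ``k > 1`` the DLT is the first window of the earliest run of
    ``k`` consecutive supra-threshold windows.  Raising the threshold can
    only move the DLT later (or drop it), never earlier.
    """
    probs = np.asarray(window_probs, dtype=float)
    if probs.ndim != 1 or len(probs) < 1:
        raise ValueError("window_probs must be a non-empty 1-D sequence")
    if k < 1:
        raise ValueError("k must be >= 1")
    hot = probs >= threshold
    for i in range(len(probs) - k + 1):
        if hot[i: i + k].all():
            return DLTResult(dlt_window_index=i, dlt_time=i * window_s,
                             decision_threshold=threshold)
    return DLTResult(decision_threshold=threshold, ok=False,
                     reason=f"no run of {k} windows reached {threshold}")


def dlt_vo2(dlt: DLTResult, avg: AveragedSeries) -> float:
    """VO2 at the DLT: the 30-s window mean containing the DLT time."""
    if not dlt.ok:
        raise ValueError("cannot read VO2 for a failed DLT")
    value = vo2_at_time(avg, dlt.dlt_time)
    dlt.dlt_vo2 = value
    return value
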
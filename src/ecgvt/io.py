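"""Plain-text serialization of sessions, gas tables, and reports.

ECG traces are two-column CSV (time_s, voltage_mV); gas series are CSV
(time_s, vo2, vco2, ve); a cohort manifest is JSON-lines with one row per
subject (id, demographics, phase boundaries, true VT time).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gas import BreathSeries
from .simulate import CPXSession, ECGTrace, ExerciseProtocol

__all__ = ["write_ecg_csv", "read_ecg_csv", "write_gas_csv", "read_gas_csv",
           "write_protocol_json", "read_protocol_json", "write_cohort",
           "manifest_row"]


def write_ecg_csv(ecg: ECGTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": ecg.times, "voltage_mV": ecg.voltage}).to_csv(
        path, index=False, float_format="%.4f")


def read_ecg_csv(path: str | Path, sampling_rate: float | None = None) -> ECGTrace:
    df = pd.read_csv(path)
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy())))
    return ECGTrace(voltage=df["voltage_mV"].to_numpy(),
                    sampling_rate=round(sampling_rate, 6))


def write_gas_csv(breaths: BreathSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": breaths.breath_times, "vo2": breaths.vo2,
                  "vco2": breaths.vco2, "ve": breaths.ve}).to_csv(
        path, index=False, float_format="%.4f")


def read_gas_csv(path: str | Path) -> BreathSeries:
    df = pd.read_csv(path)
    return BreathSeries(df["time_s"].to_numpy(), df["vo2"].to_numpy(),
                        df["vco2"].to_numpy(), df["ve"].to_numpy())


def write_protocol_json(protocol: ExerciseProtocol, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(protocol), indent=2))


def read_protocol_json(path: str | Path) -> ExerciseProtocol:
    return ExerciseProtocol(**json.loads(Path(path).read_text()))


def manifest_row(session: CPXSession) -> dict:
    return {
        "id": session.id,
        "age": round(session.age, 2),
        "sex": session.sex,
        "weight": round(session.weight, 2),
        "af": session.af,
        "beta_blocker": session.beta_blocker,
        "phase_boundaries": [round(b, 3) for b in session.protocol.phase_boundaries],
        "ramp_rate": round(session.protocol.ramp_rate, 3),
        "peak_work_rate": round(session.protocol.peak_work_rate, 3),
        "true_vt_time": (None if session.true_vt_time is None
                         else round(session.true_vt_time, 3)),
    }


def write_cohort(sessions: list[CPXSession], out_dir: str | Path,
                 write_ecg: bool = True) -> None:
    """One gas CSV (and optionally one ECG CSV) per subject plus a
    JSON-lines manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.jsonl", "w") as fh:
        for s in sessions:
            fh.write(json.dumps(manifest_row(s)) + "\n")
            write_gas_csv(s.breaths, out / f"{s.id}_gas.csv")
            if write_ecg and s.ecg is not None:
                write_ecg_csv(s.ecg, out / f"{s.id}_ecg.csv")
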
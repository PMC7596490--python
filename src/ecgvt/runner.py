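"""End-to-end experiment orchestration.

``run_experiment`` drives the whole pipeline from one config: simulate a
cohort with known thresholds, determine each session's VT from gas
exchange (three-detector consensus), window and label the exercise-phase
ECG, split by session into derivation/validation/test cohorts, train the
full and the dummy-ECG (zero-voltage) classifiers, extract each session's
DLT, and evaluate VT-VO2 vs DLT-VO2 agreement per cohort, the
full-vs-dummy correlation comparison, and subgroup correlations.

Every stage is seeded from the experiment seed; a rerun of the same config
produces an identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ecgvt_io
from .dlt import DLTResult, dlt_vo2, estimate_dlt
from .gas import (AveragedSeries, VTResult, average_30s, consensus_vt,
                  detect_vt_excess_co2, detect_vt_ventilatory_equivalent,
                  detect_vt_vslope)
from .network import NetworkConfig, TrainedModel, VTNet, save_checkpoint, train
from .simulate import CPXSession, PhysiologyParams, simulate_cohort
from .stats import (AgreementReport, SubgroupReport, agreement,
                    compare_correlations, plot_agreement, subgroup_analysis)
from .windows import CohortSplit, make_labeled_windows, split_cohorts, stack_windows

logger = logging.getLogger("ecgvt")

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "evaluate_all_cohorts", "process_gas", "SessionData"]


@dataclass
class ExperimentConfig:
    n_sessions: int = 200
    seed: int = 0
    fs: float = 250.0
    af_fraction: float = 0.096
    phys: PhysiologyParams = field(default_factory=PhysiologyParams)
    split_fractions: tuple[float, float, float] = (0.373, 0.277, 0.350)
    network: NetworkConfig | None = None
    dlt_threshold: float = 0.5
    dlt_k: int = 1
    exercise_time_mode: str = "window_start"
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.network is None:
            self.network = NetworkConfig.desk_scale(fs=self.fs, seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if doc.get("phys") is not None:
            doc["phys"] = PhysiologyParams(**doc["phys"])
        if doc.get("network") is not None:
            net = doc["network"]
            net["conv_blocks"] = tuple(tuple(b) for b in net["conv_blocks"])
            doc["network"] = NetworkConfig(**net)
        if doc.get("split_fractions") is not None:
            doc["split_fractions"] = tuple(doc["split_fractions"])
        return cls(**doc)


@dataclass
class SessionData:
    """Everything the evaluation needs about one processed session."""

    session: CPXSession
    avg: AveragedSeries
    vt: VTResult                 # consensus
    windows: list                # LabeledWindow


def process_gas(session: CPXSession) -> tuple[AveragedSeries, VTResult]:
    """30-s averaging and three-detector consensus VT for one session."""
    avg = average_30s(session.breaths, session.protocol.exercise_start)
    bounds = (0.0, session.protocol.exercise_duration)
    results = []
    for detector in (detect_vt_vslope, detect_vt_ventilatory_equivalent,
                     detect_vt_excess_co2):
        try:
            results.append(detector(avg, bounds))
        except ValueError as err:
            results.append(VTResult.failed(detector.__name__, str(err)))
    return avg, consensus_vt(results, avg)


def _cohort_arrays(data: dict[str, SessionData], ids, mode: str,
                   zero_voltage: bool = False):
    windows = [w for sid in ids for w in data[sid].windows]
    durations = {sid: data[sid].session.protocol.exercise_duration
                 for sid in ids}
    return stack_windows(windows, exercise_time_mode=mode,
                         durations=durations, zero_voltage=zero_voltage)


def _session_dlts(trained: TrainedModel, data: dict[str, SessionData], ids,
                  config: ExperimentConfig, zero_voltage: bool = False,
                  rows: list | None = None):
    """Per-session DLT results; returns (vt_vo2s, dlt_vo2s, kept_ids, n_no_dlt).

    When ``rows`` is given, one record per session (fired or not) is
    appended to it for the per-session DLT report.
    """
    vt_vals, dlt_vals, kept = [], [], []
    n_no_dlt = 0
    for sid in ids:
        sd = data[sid]
        X, C, y, _ = _cohort_arrays(data, [sid], config.exercise_time_mode,
                                    zero_voltage=zero_voltage)
        probs = trained.predict(X, C)
        res = estimate_dlt(probs, threshold=config.dlt_threshold, k=config.dlt_k)
        if rows is not None:
            rows.append({
                "session_id": sid, "n_windows": len(probs),
                "decision_threshold": config.dlt_threshold,
                "vt_time": round(sd.vt.vt_time, 3),
                "vt_vo2": round(sd.vt.vt_vo2, 3),
                "dlt_time": (round(res.dlt_time, 3) if res.ok else None),
                "dlt_vo2": (round(dlt_vo2(res, sd.avg), 3) if res.ok else None),
            })
        if not res.ok:
            n_no_dlt += 1
            continue
        vt_vals.append(sd.vt.vt_vo2)
        dlt_vals.append(dlt_vo2(res, sd.avg))
        kept.append(sid)
    return np.array(vt_vals), np.array(dlt_vals), kept, n_no_dlt


def _safe_agreement(a: np.ndarray, b: np.ndarray) -> AgreementReport:
    """Agreement report that degrades to NaNs when too few sessions have a
    DLT (n < 3) instead of failing the whole experiment; the no-DLT counts
    in the report flag the situation."""
    nan = float("nan")
    if len(a) < 3:
        return AgreementReport(n=len(a), mean_diff=nan, sd_diff=nan,
                               loa_lower=nan, loa_upper=nan, mean_diff_p=nan,
                               means=np.asarray(a), diffs=np.asarray(a) - b)
    try:
        return agreement(a, b)
    except ValueError:  # constant vector: correlation undefined
        from .stats import bland_altman
        return bland_altman(a, b)


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    n_simulated: int
    n_gas_excluded: int
    split_counts: tuple[int, int, int]
    full: dict                      # cohort -> AgreementReport
    dummy_test: AgreementReport
    ablation_z: float
    ablation_p: float
    subgroups: list[SubgroupReport]
    no_dlt: dict                    # cohort -> excluded-session count
    full_model: TrainedModel
    dummy_model: TrainedModel
    dlt_table: pd.DataFrame = None  # per-session DLT report (full model)

    def to_dict(self) -> dict:
        def rep(r: AgreementReport) -> dict:
            return {"n": r.n, "pearson_r": r.pearson_r, "pearson_p": r.pearson_p,
                    "mean_diff": r.mean_diff, "sd_diff": r.sd_diff,
                    "loa_lower": r.loa_lower, "loa_upper": r.loa_upper,
                    "mean_diff_p": r.mean_diff_p}
        return {
            "n_simulated": self.n_simulated,
            "n_gas_excluded": self.n_gas_excluded,
            "split_counts": list(self.split_counts),
            "full": {k: rep(v) for k, v in self.full.items()},
            "dummy_test": rep(self.dummy_test),
            "ablation": {"z": self.ablation_z, "p": self.ablation_p},
            "subgroups": [
                {"stratification": s.stratification,
                 "strata": {str(k): v for k, v in s.strata.items()},
                 "interaction_p": s.interaction_p}
                for s in self.subgroups],
            "no_dlt": self.no_dlt,
            "best_epoch": {"full": self.full_model.best_epoch,
                           "dummy": self.dummy_model.best_epoch},
        }

    def summary(self) -> str:
        lines = ["# VT estimation experiment", ""]
        for cohort, r in self.full.items():
            lines.append(f"- full model, {cohort}: r = {r.pearson_r:.3f} "
                         f"(p = {r.pearson_p:.2g}), bias = {r.mean_diff:+.2f} "
                         f"[{r.loa_lower:.2f}, {r.loa_upper:.2f}] mL/kg/min, "
                         f"n = {r.n}")
        d = self.dummy_test
        lines.append(f"- dummy-ECG model, test: r = {d.pearson_r:.3f}, "
                     f"bias = {d.mean_diff:+.2f}, n = {d.n}")
        lines.append(f"- full vs dummy correlation difference: "
                     f"z = {self.ablation_z:.2f}, p = {self.ablation_p:.3g}")
        for s in self.subgroups:
            per = ", ".join(f"{k}: r = {v['r']:.3f} (n = {v['n']})"
                            for k, v in s.strata.items())
            lines.append(f"- subgroup {s.stratification}: {per}; "
                         f"interaction p = {s.interaction_p:.3g}")
        return "\n".join(lines) + "\n"


def evaluate_all_cohorts(full_model: TrainedModel, dummy_model: TrainedModel,
                         split: CohortSplit, data: dict[str, SessionData],
                         config: ExperimentConfig):
    """Agreement reports for all cohorts (full model), the test-cohort dummy
    report, the correlation-difference test, and test-only subgroups."""
    cohorts = {"derivation": split.derivation_ids,
               "validation": split.validation_ids,
               "test": split.test_ids}
    full_reports, no_dlt = {}, {}
    kept_test_ids = []
    dlt_rows: list[dict] = []
    for name, ids in cohorts.items():
        if len(ids) == 0:
            raise ValueError(f"cohort {name} is empty")
        vt_v, dlt_v, kept, n_miss = _session_dlts(full_model, data, ids, config,
                                                  rows=dlt_rows)
        for row in dlt_rows[len(dlt_rows) - len(ids):]:
            row["cohort"] = name
        full_reports[name] = _safe_agreement(vt_v, dlt_v)
        no_dlt[name] = n_miss
        if name == "test":
            kept_test_ids = kept
    vt_d, dlt_d, _, n_miss_d = _session_dlts(dummy_model, data,
                                             cohorts["test"], config,
                                             zero_voltage=True)
    dummy_test = _safe_agreement(vt_d, dlt_d)
    no_dlt["dummy_test"] = n_miss_d
    r_full, r_dummy = full_reports["test"].pearson_r, dummy_test.pearson_r
    if (np.isfinite(r_full) and np.isfinite(r_dummy)
            and full_reports["test"].n >= 4 and dummy_test.n >= 4):
        z, p = compare_correlations(r_full, r_dummy,
                                    full_reports["test"].n, dummy_test.n)
    else:
        z = p = float("nan")
    subgroups = []
    strat_fields = {"sex": lambda s: s.sex,
                    "af": lambda s: "AF" if s.af else "sinus",
                    "beta_blocker": lambda s: ("beta-blocker" if s.beta_blocker
                                               else "none")}
    vt_v, dlt_v, kept, _ = _session_dlts(full_model, data, kept_test_ids, config)
    for name, getter in strat_fields.items():
        labels = np.array([getter(data[sid].session) for sid in kept])
        if len(np.unique(labels)) < 2:
            continue
        subgroups.append(subgroup_analysis(vt_v, dlt_v, labels,
                                           stratification=name))
    dlt_table = pd.DataFrame(dlt_rows)
    return full_reports, dummy_test, (z, p), subgroups, no_dlt, dlt_table


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    t0 = time.time()
    logger.info("simulating %d sessions (seed %d, fs %g Hz)",
                config.n_sessions, config.seed, config.fs)
    sessions = simulate_cohort(config.n_sessions, config.phys,
                               seed=config.seed, fs=config.fs,
                               af_fraction=config.af_fraction)
    data: dict[str, SessionData] = {}
    n_excluded = 0
    for s in sessions:
        avg, vt = process_gas(s)
        if not vt.ok:
            n_excluded += 1
            logger.warning("session %s excluded: %s", s.id, vt.reason)
            continue
        wins = make_labeled_windows(s, vt.vt_time)
        data[s.id] = SessionData(session=s, avg=avg, vt=vt, windows=wins)
    logger.info("gas-exchange VT determined for %d/%d sessions (%.1f s)",
                len(data), len(sessions), time.time() - t0)
    split = split_cohorts(sorted(data.keys()), config.split_fractions,
                          seed=config.seed + 1)
    mode = config.exercise_time_mode
    deriv = _cohort_arrays(data, split.derivation_ids, mode)[:3]
    val = _cohort_arrays(data, split.validation_ids, mode)[:3]
    deriv_d = _cohort_arrays(data, split.derivation_ids, mode, zero_voltage=True)[:3]
    val_d = _cohort_arrays(data, split.validation_ids, mode, zero_voltage=True)[:3]

    logger.info("training full model (%d derivation windows)", len(deriv[0]))
    full_model = train(VTNet(config.network), deriv, val, config.network)
    logger.info("training dummy-ECG model")
    dummy_model = train(VTNet(config.network), deriv_d, val_d, config.network)
    logger.info("training done (%.1f s)", time.time() - t0)

    full, dummy_test, (z, p), subgroups, no_dlt, dlt_table = \
        evaluate_all_cohorts(full_model, dummy_model, split, data, config)
    report = ExperimentReport(
        config=config, n_simulated=len(sessions), n_gas_excluded=n_excluded,
        split_counts=(len(split.derivation_ids), len(split.validation_ids),
                      len(split.test_ids)),
        full=full, dummy_test=dummy_test, ablation_z=z, ablation_p=p,
        subgroups=subgroups, no_dlt=no_dlt,
        full_model=full_model, dummy_model=dummy_model, dlt_table=dlt_table)
    logger.info("experiment finished in %.1f s; test r = %.3f",
                time.time() - t0, full["test"].pearson_r)
    if config.out_dir:
        _persist(report, split, data)
    return report


def _persist(report: ExperimentReport, split: CohortSplit,
             data: dict[str, SessionData]) -> None:
    out = Path(report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(report.config)
    cfg.to_yaml(out / "config.yaml")
    with open(out / "manifest.jsonl", "w") as fh:
        for sid in sorted(data):
            row = ecgvt_io.manifest_row(data[sid].session)
            row["cohort"] = split.cohort_of(sid)
            row["consensus_vt_time"] = round(data[sid].vt.vt_time, 3)
            row["consensus_vt_vo2"] = round(data[sid].vt.vt_vo2, 3)
            fh.write(json.dumps(row) + "\n")
    rows = [
        {"session_id": sid, "window_index": w.window_index,
         "start_time": w.start_time, "label": w.label}
        for sid in sorted(data) for w in data[sid].windows
    ]
    pd.DataFrame(rows).to_csv(out / "window_manifest.csv", index=False)
    if report.dlt_table is not None:
        report.dlt_table.to_csv(out / "dlt_report.csv", index=False)
    sub_rows = [
        {"stratification": sg.stratification, "stratum": str(label),
         "n": v["n"], "r": round(v["r"], 4), "p": v["p"],
         "interaction_p": sg.interaction_p}
        for sg in report.subgroups for label, v in sg.strata.items()
    ]
    pd.DataFrame(sub_rows).to_csv(out / "subgroup_table.csv", index=False)
    save_checkpoint(report.full_model, out / "model_full")
    save_checkpoint(report.dummy_model, out / "model_dummy")
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out / "report.md").write_text(report.summary())
    plot_agreement(report.full["test"], out / "agreement_test.png",
                   title="full model, test cohort")
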
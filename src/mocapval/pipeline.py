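"""End-to-end validation runs: simulate -> preprocess -> align -> extract
-> report.

A run produces the long parameter table (subject x task x repetition x
system), per-landmark signal-accuracy summaries, and the agreement report
(accuracy on the first repetition per subject, repeatability over all
repetitions).  Recordings that fail any stage are excluded with a logged,
machine-readable reason; the run continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, parameters, preprocess, simulate
from .alignment import apply_transform, register_recordings
from .preprocess import PreprocessConfig, sample_at
from .skeleton import COMMON_LANDMARKS, DataError, System, Task, TaskRecording

__all__ = [
    "SimulationBlock",
    "RunConfig",
    "ValidationResult",
    "run_validation",
    "process_pair",
    "simulate_pair",
]

logger = logging.getLogger("mocapval")

DEFAULT_REPETITIONS = {Task.POCO: 3, Task.SAS: 3, Task.SIP: 3, Task.SCSW: 3}


@dataclass(frozen=True)
class SimulationBlock:
    """Synthetic-study design: how many subjects, repetitions and how much
    sensor degradation."""

    n_subjects: int = 10
    repetitions: dict = field(default_factory=lambda: dict(DEFAULT_REPETITIONS))
    tasks: tuple[Task, ...] = (Task.POCO, Task.SAS, Task.SIP, Task.SCSW)
    noise_scale: float = 1.0
    rep_truth_cv: float = 0.03  # within-subject between-repetition variability


@dataclass
class RunConfig:
    """Either a simulation block (synthetic study) or a manifest path
    (pre-recorded landmark tables) defines the inputs."""

    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    manifest: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    refine_offset: bool = False
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.get("simulation", {})
        reps = {
            Task(k): int(v)
            for k, v in sim_raw.get("repetitions", {}).items()
        } or dict(DEFAULT_REPETITIONS)
        sim = SimulationBlock(
            n_subjects=int(sim_raw.get("n_subjects", 10)),
            repetitions=reps,
            tasks=tuple(Task(t) for t in sim_raw.get("tasks", [t.value for t in DEFAULT_REPETITIONS])),
            noise_scale=float(sim_raw.get("noise_scale", 1.0)),
            rep_truth_cv=float(sim_raw.get("rep_truth_cv", 0.03)),
        )
        pp = PreprocessConfig(**raw.get("preprocess", {}))
        return cls(
            simulation=sim,
            manifest=raw.get("manifest"),
            preprocess=pp,
            refine_offset=bool(raw.get("refine_offset", False)),
            output_dir=raw.get("output_dir"),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def to_dict(self) -> dict:
        sim = dataclasses.asdict(self.simulation)
        sim["repetitions"] = {
            (k.value if isinstance(k, Task) else k): v
            for k, v in self.simulation.repetitions.items()
        }
        sim["tasks"] = [t.value for t in self.simulation.tasks]
        return {
            "simulation": sim,
            "manifest": self.manifest,
            "preprocess": dataclasses.asdict(self.preprocess),
            "refine_offset": self.refine_offset,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
        }


@dataclass
class ValidationResult:
    param_table: pd.DataFrame
    signal_table: pd.DataFrame
    report: agreement.AgreementReport
    exclusions: list[dict]
    config: RunConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.param_table.to_csv(out / "parameters.csv", index=False)
        self.signal_table.to_csv(out / "signal_accuracy.csv", index=False)
        self.report.accuracy.to_csv(out / "accuracy_report.csv", index=False)
        self.report.repeatability.to_csv(out / "repeatability_report.csv", index=False)
        (out / "bland_altman.json").write_text(
            json.dumps(
                {f"{t}/{p}": ba for (t, p), ba in self.report.bland_altman.items()},
                indent=2,
            )
        )
        (out / "exclusions.json").write_text(json.dumps(self.exclusions, indent=2))
        (out / "config.json").write_text(json.dumps(self.config.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# per-recording processing
# ---------------------------------------------------------------------------

def _perturb_truth(truth, rng: np.random.Generator, cv: float):
    """Within-subject repetition-to-repetition variability: scale the
    scalar motion magnitudes/timings by ~N(1, cv)."""
    if cv <= 0:
        return truth
    fields = {
        simulate.PostureTruth: ("pitch_amp_deg", "roll_amp_deg", "freq_hz"),
        simulate.SasTruth: (
            "rise_time_up_s",
            "rise_time_down_s",
            "ap_excursion_m",
            "hand_ap_range_m",
        ),
        simulate.SipTruth: ("period_s", "lift_duration_s", "lift_m"),
        simulate.GaitTruth: (
            "speed_mps",
            "step_period_s",
            "arm_amp_l_deg",
            "arm_amp_r_deg",
        ),
    }[type(truth)]
    updates = {}
    for name in fields:
        factor = float(np.clip(rng.normal(1.0, cv), 0.8, 1.2))
        updates[name] = getattr(truth, name) * factor
    if isinstance(truth, simulate.SipTruth):
        # keep the lift strictly inside the period after jitter
        updates["lift_duration_s"] = min(
            updates["lift_duration_s"], updates["period_s"] - 0.09
        )
    return dataclasses.replace(truth, **updates)


def simulate_pair(
    task: Task,
    subject_id: str,
    repetition: int,
    truth,
    sensor_model: simulate.SensorModel,
    degrade_seed: int,
) -> tuple[TaskRecording, TaskRecording]:
    """One reference recording plus its degraded sensor twin."""
    ref = simulate.simulate_task(
        task, truth=truth, subject_id=subject_id, repetition=repetition
    )
    sensor, _ = simulate.degrade(ref, sensor_model, seed=degrade_seed)
    return ref, sensor


def process_pair(
    ref: TaskRecording,
    sensor: TaskRecording,
    cfg: PreprocessConfig = PreprocessConfig(),
    refine_offset: bool = False,
) -> dict:
    """Preprocess, align and extract one reference/sensor recording pair.

    Returns a dict with the aligned recordings, the recovered transform,
    per-landmark signal accuracies and both parameter sets.
    """
    ref_rec = preprocess.lowpass(
        preprocess.interpolate_short_gaps(ref.recording, cfg), cfg
    )
    sen_rec = preprocess.lowpass(
        preprocess.interpolate_short_gaps(sensor.recording, cfg), cfg
    )
    declared = float(sen_rec.timestamps[0] - ref_rec.timestamps[0])
    if refine_offset and ref.task is not Task.POCO:
        from .alignment import temporal_offset_from_timestamps

        est = temporal_offset_from_timestamps(
            ref_rec, sen_rec, declared, refine=True
        )
        declared = est.offset_s
    tf = register_recordings(ref_rec, sen_rec, time_offset_s=declared)
    sen_aligned = apply_transform(sen_rec, tf)
    # pair frames on the sensor grid inside the reference span
    inside = (sen_aligned.timestamps >= ref_rec.timestamps[0]) & (
        sen_aligned.timestamps <= ref_rec.timestamps[-1]
    )
    sen_trim = sen_aligned.copy()
    sen_trim.timestamps = sen_aligned.timestamps[inside]
    sen_trim.positions = sen_aligned.positions[inside]
    sen_trim.missing = sen_aligned.missing[inside]
    ref_at = sample_at(ref_rec, sen_trim.timestamps)
    signal = agreement.signal_accuracy(ref_at, sen_trim)
    ref_30 = preprocess.resample_to(ref_rec, cfg)
    params_ref = parameters.extract_parameters(ref_30, ref.task)
    params_sen = parameters.extract_parameters(sen_trim, sensor.task)
    return {
        "transform": tf,
        "reference_aligned": ref_30,
        "sensor_aligned": sen_trim,
        "signal_accuracy": signal,
        "parameters": {System.REFERENCE: params_ref, System.SENSOR: params_sen},
    }


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _manifest_pairs(config: RunConfig):
    """Yield (key, reference TaskRecording, sensor TaskRecording) loaded
    from the manifest's landmark tables."""
    from . import io as io_mod

    base = Path(config.manifest).parent
    groups: dict[tuple, dict] = {}
    for e in io_mod.read_manifest(config.manifest):
        groups.setdefault((e.subject, e.task, int(e.repetition)), {})[e.system] = e
    for (subj, task, rep), by_system in sorted(groups.items()):
        key = f"{subj}:{task}:{rep}"
        missing = {s.value for s in System} - set(by_system)
        if missing:
            raise DataError(f"{key}: manifest lacks systems {sorted(missing)}")
        ref = io_mod.load_task_recording(by_system[System.REFERENCE.value], base)
        sen = io_mod.load_task_recording(by_system[System.SENSOR.value], base)
        yield key, ref, sen


def run_validation(config: RunConfig) -> ValidationResult:
    """Run the complete validation study defined by ``config`` — either a
    synthetic simulation block or a manifest of recorded landmark tables."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    sim = config.simulation
    base_model = simulate.SensorModel.default().scaled(sim.noise_scale)
    param_rows: list[dict] = []
    signal_acc: dict[str, list[agreement.SignalAccuracy]] = {}
    exclusions: list[dict] = []
    n_ok = 0

    def accumulate(result: dict, subject: str, task: Task, rep: int) -> None:
        for system, ps in result["parameters"].items():
            for name, value in ps.values.items():
                param_rows.append(
                    {
                        "subject": subject,
                        "task": task.value,
                        "repetition": rep,
                        "system": system.value,
                        "parameter": name,
                        "value": value,
                    }
                )
        for acc in result["signal_accuracy"]:
            signal_acc.setdefault(acc.landmark, []).append(acc)

    if config.manifest is not None:
        for key, ref, sensor in _manifest_pairs(config):
            try:
                result = process_pair(
                    ref, sensor, config.preprocess, config.refine_offset
                )
            except (DataError, ValueError) as exc:
                logger.warning("excluding %s: %s", key, exc)
                exclusions.append({"recording": key, "reason": str(exc)})
                continue
            n_ok += 1
            accumulate(result, ref.subject_id, ref.task, ref.repetition_index)
        if n_ok == 0:
            raise DataError("zero usable recordings")
        param_table = pd.DataFrame(param_rows)
        report = agreement.build_reports(param_table)
        result = ValidationResult(
            param_table, _aggregate_signal(signal_acc), report, exclusions, config
        )
        if config.output_dir:
            result.write(config.output_dir)
        return result

    root_ss = np.random.SeedSequence(config.seed)
    subject_seeds = root_ss.spawn(sim.n_subjects)
    for s_idx in range(sim.n_subjects):
        subject_id = f"S{s_idx + 1:03d}"
        subj_ss = subject_seeds[s_idx]
        truth_rng = np.random.default_rng(subj_ss)
        truths = simulate.sample_subject_truths(truth_rng)
        for task in sim.tasks:
            reps = int(sim.repetitions.get(task, 3))
            for rep in range(1, reps + 1):
                # degrade seed depends on subject/task/rep only, so noise
                # sweeps at different scales share their random draws
                rec_key = f"{config.seed}:{subject_id}:{task.value}:{rep}"
                degrade_seed = int(
                    np.random.SeedSequence(
                        [config.seed, s_idx, list(Task).index(task), rep]
                    ).generate_state(1)[0]
                    % (2**31)
                )
                rep_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [config.seed, s_idx, list(Task).index(task), rep, 7]
                    )
                )
                truth = _perturb_truth(truths[task], rep_rng, sim.rep_truth_cv)
                try:
                    ref, sensor = simulate_pair(
                        task, subject_id, rep, truth, base_model, degrade_seed
                    )
                    result = process_pair(
                        ref, sensor, config.preprocess, config.refine_offset
                    )
                except (DataError, ValueError) as exc:
                    logger.warning("excluding %s: %s", rec_key, exc)
                    exclusions.append({"recording": rec_key, "reason": str(exc)})
                    continue
                n_ok += 1
                accumulate(result, subject_id, task, rep)
    if n_ok == 0:
        raise DataError("zero usable recordings")
    param_table = pd.DataFrame(param_rows)
    signal_table = _aggregate_signal(signal_acc)
    report = agreement.build_reports(param_table)
    result = ValidationResult(param_table, signal_table, report, exclusions, config)
    if config.output_dir:
        result.write(config.output_dir)
    return result


def _aggregate_signal(
    signal_acc: dict[str, list[agreement.SignalAccuracy]]
) -> pd.DataFrame:
    rows = []
    for lm, accs in signal_acc.items():
        row: dict = {"landmark": lm, "n_recordings": len(accs)}
        row["rmse_mm"] = float(np.mean([a.rmse_mm for a in accs]))
        for ax in ("ml", "v", "ap"):
            rs = [a.pearson_r[ax] for a in accs if np.isfinite(a.pearson_r[ax])]
            ss = [a.snr_db[ax] for a in accs if np.isfinite(a.snr_db[ax])]
            row[f"r_{ax}"] = float(np.mean(rs)) if rs else np.nan
            row[f"snr_{ax}_db"] = float(np.mean(ss)) if ss else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        order = {lm: i for i, lm in enumerate(COMMON_LANDMARKS)}
        df = df.sort_values("landmark", key=lambda s: s.map(order)).reset_index(drop=True)
    return df
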
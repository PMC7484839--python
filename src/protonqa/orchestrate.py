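"""End-to-end pipeline orchestration: a resumable, polling state machine.

A verification run walks a fixed state sequence

    RECEIVED -> INTEGRITY_CHECKED -> PREPROCESSED -> SIMULATING
             -> COMBINING -> EXPORTED

with FAILED reachable from any state.  Every transition is appended to a
machine-parsable log and the :class:`JobRecord` is persisted as JSON in
the run directory after each change, so re-invoking :func:`run_pipeline`
on the same directory resumes from the last completed state (preprocessed
CT and batch files are reloaded from disk rather than recomputed).

Batch execution goes through the :class:`BatchRunner` abstraction: the
built-in mock runner completes jobs synchronously, while an external
runner can report jobs as pending, in which case the orchestrator polls
their status at a configurable interval (default 600 s, i.e. every
10 min) until all batches complete.  Notification is an abstract hook;
the default implementation writes a structured log line.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from . import dicom_io
from .combine import CalibrationTable, CombinedResult, combine_batches
from .core import CTVolume, DoseGrid, PipelineError, SpotPlan, StructureSet
from .engine import (
    BatchResult,
    EngineInterface,
    JobSpec,
    MockEngine,
    plan_to_jobs,
    read_batch,
    write_batch,
)
from .fixtures import FIXTURE_HISTORIES, FIXTURE_N_BATCHES
from .gamma import GammaCriteria, MeasurementPlane, gamma_map
from .let_report import mask_infield, overlap_high_dose_high_let
from .preprocess import CouchModel, DensityCurve, HUOverride, preprocess_ct

log = logging.getLogger(__name__)

STATES = ("RECEIVED", "INTEGRITY_CHECKED", "PREPROCESSED", "SIMULATING",
          "COMBINING", "EXPORTED")
TERMINAL_STATES = ("EXPORTED", "FAILED")


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from a JSON config file."""

    ct_dir: str
    structures_path: str
    plan_path: str
    calibration_path: str
    run_dir: str
    user_id: str = "local"
    engine: str = "mock"  # mock | mock_noiseless
    n_batches: int = FIXTURE_N_BATCHES
    total_histories: int = FIXTURE_N_BATCHES * FIXTURE_HISTORIES
    base_seed: int = 0
    poll_interval_s: float = 600.0
    apply_couch: bool = True
    overrides: list = field(default_factory=list)  # [[target, hu], ...]
    gamma_planes: list = field(default_factory=list)  # CSV paths
    gamma_dd_percent: float = 3.0
    gamma_dta_mm: float = 3.0
    gamma_cutoff_fraction: float = 0.10

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


@dataclass
class JobRecord:
    """Persistent record of one pipeline run."""

    run_id: str
    user_id: str
    state: str = "RECEIVED"
    batch_status: dict = field(default_factory=dict)  # job id -> status
    transitions: list = field(default_factory=list)  # [state, iso time]
    failure_cause: str = ""
    log_path: str = ""
    outputs: dict = field(default_factory=dict)

    def record_path(self, run_dir: Path) -> Path:
        return Path(run_dir) / "record.json"

    def save(self, run_dir: Path) -> None:
        self.record_path(run_dir).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, run_dir: Path) -> "JobRecord":
        data = json.loads((Path(run_dir) / "record.json").read_text())
        return cls(**data)

    def reached(self, state: str) -> bool:
        """True if the run has completed ``state`` (or is past it)."""
        done = [t[0] for t in self.transitions]
        return state in done


class PipelineLogger:
    """Append-only machine-parsable run log: `ISO8601|LEVEL|STATE|message`."""

    def __init__(self, path: Path):
        self.path = Path(path)

    def write(self, state: str, message: str, level: str = "INFO") -> None:
        stamp = _dt.datetime.now(_dt.timezone.utc).isoformat()
        with open(self.path, "a") as fh:
            fh.write(f"{stamp}|{level}|{state}|{message}\n")
        log.log(getattr(logging, level, logging.INFO), "[%s] %s", state, message)


def _transition(record: JobRecord, run_dir: Path, logger: PipelineLogger,
                state: str, message: str = "") -> None:
    if state != "FAILED":
        order = list(STATES)
        if record.state in order and state in order:
            if order.index(state) != order.index(record.state) + 1 and \
                    record.state != state:
                raise PipelineError(
                    f"illegal transition {record.state} -> {state}")
    record.state = state
    record.transitions.append([state, _dt.datetime.now(
        _dt.timezone.utc).isoformat()])
    logger.write(state, message or f"entered {state}")
    record.save(run_dir)


def notify(record: JobRecord, hook: Callable[[dict], None] | None,
           logger: PipelineLogger | None = None, **extra) -> None:
    """Invoke the notification hook; hook failures are logged, never fatal."""
    payload = {"run_id": record.run_id, "user_id": record.user_id,
               "state": record.state, **extra}
    if record.failure_cause:
        payload["failure_cause"] = record.failure_cause
    if hook is None:
        if logger is not None:
            logger.write(record.state, f"NOTIFY {json.dumps(payload)}")
        return
    try:
        hook(payload)
    except Exception as exc:  # noqa: BLE001 - hook errors must not kill a run
        if logger is not None:
            logger.write(record.state, f"notification hook failed: {exc}",
                         level="WARNING")


# ---------------------------------------------------------------------------
# Batch runners


class BatchRunner:
    """Opaque job execution: submit, poll status, fetch results."""

    def submit(self, job: JobSpec) -> str:
        raise NotImplementedError

    def status(self, job_id: str) -> str:  # PENDING | DONE | FAILED
        raise NotImplementedError

    def result(self, job_id: str) -> BatchResult:
        raise NotImplementedError


class MockRunner(BatchRunner):
    """Runs jobs synchronously through an in-process engine."""

    def __init__(self, engine: EngineInterface, ct: CTVolume,
                 curve: DensityCurve | None = None):
        self.engine = engine
        self.ct = ct
        self.curve = curve or DensityCurve()
        self._results: dict[str, BatchResult] = {}

    @staticmethod
    def job_id(job: JobSpec) -> str:
        return f"f{job.field_index}_b{job.batch_index}"

    def submit(self, job: JobSpec) -> str:
        jid = self.job_id(job)
        self._results[jid] = self.engine.run(job, self.ct, self.curve)
        return jid

    def status(self, job_id: str) -> str:
        return "DONE" if job_id in self._results else "FAILED"

    def result(self, job_id: str) -> BatchResult:
        return self._results[job_id]


def poll_jobs(record: JobRecord, runner: BatchRunner, run_dir: Path,
              logger: PipelineLogger) -> JobRecord:
    """One polling pass over all submitted batch jobs.

    Updates per-batch statuses, appends one status line to the log, and
    transitions to COMBINING only when every job is complete.  A failed
    batch sends the run to FAILED, naming the batch.
    """
    if record.state != "SIMULATING":
        raise PipelineError(f"poll_jobs called in state {record.state}")
    for jid, prev in record.batch_status.items():
        if prev != "DONE":  # jobs restored from disk stay done
            record.batch_status[jid] = runner.status(jid)
    counts = {s: sum(1 for v in record.batch_status.values() if v == s)
              for s in ("PENDING", "DONE", "FAILED")}
    logger.write("SIMULATING", f"poll: {json.dumps(counts)}")
    record.save(run_dir)
    failed = [j for j, s in record.batch_status.items() if s == "FAILED"]
    if failed:
        record.failure_cause = f"batch job failed: {failed[0]}"
        _transition(record, run_dir, logger, "FAILED", record.failure_cause)
        return record
    if all(s == "DONE" for s in record.batch_status.values()):
        _transition(record, run_dir, logger, "COMBINING",
                    "all batch jobs complete")
    return record


# ---------------------------------------------------------------------------
# Pipeline stages


def _load_inputs(config: PipelineConfig):
    ct = dicom_io.read_ct_series(config.ct_dir)
    structures = dicom_io.read_structures(config.structures_path, ct)
    plan = dicom_io.read_plan(config.plan_path)
    calib = CalibrationTable.from_csv(config.calibration_path)
    return ct, structures, plan, calib


def _combine_fields(per_field: dict[int, CombinedResult]) -> CombinedResult:
    fields = sorted(per_field)
    total = sum(per_field[f].dose.values for f in fields)
    geo = per_field[fields[0]].dose.geometry
    frame = per_field[fields[0]].dose.frame_of_reference_uid
    let_num = sum(per_field[f].let.values * per_field[f].dose.values
                  for f in fields)
    let = np.divide(let_num, total, out=np.zeros_like(let_num),
                    where=total > 0)
    var_num = sum((per_field[f].rel_uncertainty * per_field[f].dose.values) ** 2
                  for f in fields)
    unc = np.divide(np.sqrt(var_num), total, out=np.zeros_like(total),
                    where=total > 0)
    return CombinedResult(
        dose=DoseGrid(total, "Gy", geo, frame),
        let=DoseGrid(let, "keV_per_um", geo, frame),
        rel_uncertainty=unc,
        n_batches=sum(per_field[f].n_batches for f in fields),
    )


def run_pipeline(
    config: PipelineConfig,
    notification_hook: Callable[[dict], None] | None = None,
    stop_after: str | None = None,
    poll_sleep_s: float | None = None,
) -> JobRecord:
    """Drive a full verification run; resumes if the run directory has one.

    ``stop_after`` aborts the process after the named state completes
    (crash simulation for resumability tests).  Returns the final
    JobRecord (state EXPORTED, FAILED, or the stop point).
    """
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logger = PipelineLogger(run_dir / "pipeline.log")
    if (run_dir / "record.json").exists():
        record = JobRecord.load(run_dir)
        logger.write(record.state, "resuming from persisted record")
        if record.state in TERMINAL_STATES and record.state != "FAILED":
            return record
        if record.state == "FAILED":
            # a failed run restarts from scratch
            record = JobRecord(run_id=run_dir.name, user_id=config.user_id,
                               log_path=str(logger.path))
            _transition(record, run_dir, logger, "RECEIVED", "restart")
    else:
        record = JobRecord(run_id=run_dir.name, user_id=config.user_id,
                           log_path=str(logger.path))
        _transition(record, run_dir, logger, "RECEIVED", "run created")

    try:
        ct, structures, plan, calib = _load_inputs(config)
    except Exception as exc:
        record.failure_cause = f"input loading failed: {exc}"
        _transition(record, run_dir, logger, "FAILED", record.failure_cause)
        notify(record, notification_hook, logger)
        return record

    def stop_requested(state: str) -> bool:
        return stop_after is not None and state == stop_after

    # -- integrity ----------------------------------------------------------
    if not record.reached("INTEGRITY_CHECKED"):
        report = dicom_io.check_integrity(
            ct, structures, plan, calibration_energies=calib.energies())
        notify(record, notification_hook, logger,
               integrity_ok=report.ok, missing_items=report.missing_items)
        if not report.ok:
            record.failure_cause = f"integrity check failed: {report.summary()}"
            _transition(record, run_dir, logger, "FAILED", record.failure_cause)
            return record
        _transition(record, run_dir, logger, "INTEGRITY_CHECKED",
                    "integrity check passed")
    if stop_requested("INTEGRITY_CHECKED"):
        return record

    # -- preprocess ---------------------------------------------------------
    pre_dir = run_dir / "preprocessed"
    try:
        if not record.reached("PREPROCESSED"):
            couch = CouchModel() if config.apply_couch else None
            overrides = [HUOverride(t, int(h)) for t, h in config.overrides]
            result = preprocess_ct(ct, structures, couch=couch,
                                   overrides=overrides)
            dicom_io.write_ct_series(result.ct, pre_dir)
            (run_dir / "preprocess_provenance.json").write_text(
                json.dumps(result.provenance_dicts(), indent=2))
            pre_ct = result.ct
            _transition(record, run_dir, logger, "PREPROCESSED",
                        f"{len(result.provenance)} preprocessing rules applied")
        else:
            pre_ct = dicom_io.read_ct_series(pre_dir)
            pre_ct.frame_of_reference_uid = ct.frame_of_reference_uid
        if stop_requested("PREPROCESSED"):
            return record

        # -- simulate -------------------------------------------------------
        jobs = plan_to_jobs(plan, config.n_batches, config.total_histories,
                            config.base_seed)
        batch_dir = run_dir / "batches"
        batch_dir.mkdir(exist_ok=True)
        engine = MockEngine(noiseless=(config.engine == "mock_noiseless"))
        if config.engine not in ("mock", "mock_noiseless"):
            raise PipelineError(f"unknown engine {config.engine!r}")
        runner = MockRunner(engine, pre_ct)
        if not record.reached("COMBINING"):
            if not record.reached("SIMULATING"):
                _transition(record, run_dir, logger, "SIMULATING",
                            f"{len(jobs)} batch jobs prepared")
            pending: dict[str, Path] = {}
            for job in jobs:
                jid = MockRunner.job_id(job)
                path = batch_dir / f"{jid}.pvb"
                if path.exists():
                    record.batch_status[jid] = "DONE"
                    continue
                runner.submit(job)
                record.batch_status[jid] = "PENDING"
                pending[jid] = path
            record.save(run_dir)
            while record.state == "SIMULATING":
                # persist any finished batch before acknowledging it
                for jid in [j for j, p in pending.items()
                            if runner.status(j) == "DONE"]:
                    write_batch(runner.result(jid), pending.pop(jid))
                if stop_requested("SIMULATING") and not pending:
                    return record  # simulated crash before combination
                poll_jobs(record, runner, run_dir, logger)
                if record.state == "SIMULATING":
                    time.sleep(poll_sleep_s if poll_sleep_s is not None
                               else config.poll_interval_s)
            if record.state == "FAILED":
                notify(record, notification_hook, logger)
                return record
        if stop_requested("SIMULATING"):
            return record

        # -- combine --------------------------------------------------------
        per_field: dict[int, CombinedResult] = {}
        for fi, f in enumerate(plan.fields):
            batches = [read_batch(batch_dir / f"f{fi}_b{b}.pvb")
                       for b in range(config.n_batches)]
            per_field[fi] = combine_batches(batches, f, calib)
        combined = _combine_fields(per_field)
        if not record.reached("COMBINING"):
            _transition(record, run_dir, logger, "COMBINING",
                        f"combined {config.n_batches} batches per field")
        if stop_requested("COMBINING"):
            return record

        # -- export ---------------------------------------------------------
        out_dir = run_dir / "output"
        out_dir.mkdir(exist_ok=True)
        dose_path = dicom_io.write_dose(combined.dose, out_dir / "dose.dcm")
        masked_let = mask_infield(combined.let, combined.dose,
                                  plan.prescription_dose_gy)
        let_path = dicom_io.write_dose(masked_let, out_dir / "let.dcm")
        np.save(out_dir / "rel_uncertainty.npy", combined.rel_uncertainty)
        overlap = overlap_high_dose_high_let(
            combined.dose, combined.let, plan.prescription_dose_gy,
            structures=structures)
        report: dict = {
            "plan_id": plan.plan_id,
            "prescription_dose_gy": plan.prescription_dose_gy,
            "n_fields": len(plan.fields),
            "n_batches": config.n_batches,
            "total_histories": config.total_histories,
            "max_dose_gy": float(combined.dose.values.max()),
            "rel_uncertainty_at_max": float(
                combined.rel_uncertainty.flat[
                    int(np.argmax(combined.dose.values))]),
            "let_overlap": overlap.as_dict(),
        }
        gamma_results = []
        criteria = GammaCriteria(
            dose_tolerance_percent=config.gamma_dd_percent,
            distance_tolerance_mm=config.gamma_dta_mm,
            low_dose_cutoff_fraction=config.gamma_cutoff_fraction)
        for plane_path in config.gamma_planes:
            plane = MeasurementPlane.from_csv(plane_path)
            g = gamma_map(plane, combined.dose, criteria)
            gamma_results.append({"plane": str(plane_path), **g.as_dict()})
        if gamma_results:
            report["gamma"] = gamma_results
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        record.outputs = {"dose": str(dose_path), "let": str(let_path),
                          "uncertainty": str(out_dir / "rel_uncertainty.npy"),
                          "report": str(out_dir / "report.json")}
        _transition(record, run_dir, logger, "EXPORTED",
                    "outputs written: dose, LET, uncertainty, report")
        extra = {}
        if gamma_results:
            extra["pass_rate"] = gamma_results[0]["pass_rate"]
        notify(record, notification_hook, logger, **extra)
        return record
    except Exception as exc:  # noqa: BLE001 - any stage error fails the run
        record.failure_cause = f"{type(exc).__name__}: {exc}"
        _transition(record, run_dir, logger, "FAILED", record.failure_cause)
        notify(record, notification_hook, logger)
        return record
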
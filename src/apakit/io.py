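"""Delimited-text readers and writers, config parsing, logging.

Signals travel as plain CSV (one row per sample, header naming the
channels) with a JSON sidecar ``<name>.meta.json`` carrying the sampling
rate, time origin, quiet-standing window, task, stepping side and — for
force-plate files — the body weight.  Events are small JSON documents.

On load, left-stepping trials have their ML channels mirrored so that the
internal convention (ML positive toward the stepping side) always holds;
the writer applies the same mirror, so a write/read round trip is exact.
"""

from __future__ import annotations

import json
import logging
import os
import sys
import tempfile
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .model import (
    EventSource,
    ForcePlateRecording,
    GaitEvents,
    ImuRecording,
    IntegrityError,
    SchemaError,
    Side,
    Task,
    Thresholds,
    TimeSeries,
    events_from_mapping,
)

__all__ = [
    "FORCE_PLATE_CHANNELS",
    "IMU_CHANNELS",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "RunConfig",
    "FilterSettings",
    "TaskThresholds",
    "GridRanges",
    "load_config",
    "configure_logging",
    "atomic_write_text",
]

log = logging.getLogger("apakit")

FORCE_PLATE_CHANNELS = ("cop1_ml", "cop1_ap", "fz1", "fz2")
IMU_CHANNELS = ("trunk_acc_v", "trunk_acc_ml", "trunk_acc_ap", "shank_gyro_ml")

_FP_UNITS = {"cop1_ml": "cm", "cop1_ap": "cm", "fz1": "N", "fz2": "N"}
_IMU_UNITS = {
    "trunk_acc_v": "m/s^2",
    "trunk_acc_ml": "m/s^2",
    "trunk_acc_ap": "m/s^2",
    "shank_gyro_ml": "deg/s",
}

#: numeric precision of signal CSVs; fixed so regenerated files are
#: byte-identical across platforms
CSV_FLOAT_FORMAT = "%.9g"


def configure_logging(verbose: bool = False) -> None:
    """Route package logs to stderr (idempotent)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers.clear()
    log.addHandler(handler)
    log.setLevel(logging.DEBUG if verbose else logging.INFO)


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" else path.with_name(path.stem + ".meta.json")


def _load_sidecar(path: Path) -> dict:
    side = _sidecar_path(path)
    if not side.exists():
        raise SchemaError(f"metadata sidecar absent: {side}")
    try:
        return json.loads(side.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"unreadable metadata sidecar {side}: {exc}") from exc


def _require_meta(meta: dict, key: str, path: Path):
    if key not in meta:
        raise SchemaError(f"metadata field '{key}' absent in sidecar of {path}")
    return meta[key]


def read_recording(
    path: str | os.PathLike, schema: Literal["force_plate", "imu"]
) -> ForcePlateRecording | ImuRecording:
    """Read a signal CSV plus its JSON sidecar into a validated recording.

    Raises :class:`SchemaError` naming the offending field when a channel
    is missing, a cell is non-numeric, or metadata is invalid.
    """
    path = Path(path)
    if schema not in ("force_plate", "imu"):
        raise SchemaError(f"unknown schema '{schema}'")
    channels = FORCE_PLATE_CHANNELS if schema == "force_plate" else IMU_CHANNELS
    units = _FP_UNITS if schema == "force_plate" else _IMU_UNITS

    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise SchemaError(f"unreadable CSV {path}: {exc}") from exc
    for ch in channels:
        if ch not in frame.columns:
            raise SchemaError(f"{ch} absent in {path}")
    meta = _load_sidecar(path)
    fs = float(_require_meta(meta, "fs", path))
    if fs <= 0:
        raise SchemaError(f"fs must be positive, got {fs} in sidecar of {path}")
    t0 = float(meta.get("t0", 0.0))
    quiet = tuple(_require_meta(meta, "quiet_window", path))
    task = Task(_require_meta(meta, "task", path))
    side = Side(_require_meta(meta, "stepping_side", path))
    mirror = -1.0 if side is Side.LEFT else 1.0

    series: dict[str, TimeSeries] = {}
    for ch in channels:
        col = pd.to_numeric(frame[ch], errors="coerce").to_numpy(dtype=float)
        if np.isnan(col).any():
            row = int(np.flatnonzero(np.isnan(col))[0])
            raise SchemaError(f"non-numeric cell in column {ch}, row {row} of {path}")
        if ch.endswith("_ml"):
            col = mirror * col
        series[ch] = TimeSeries(t0, fs, col, units[ch])

    if schema == "force_plate":
        return ForcePlateRecording(
            cop1_ml=series["cop1_ml"],
            cop1_ap=series["cop1_ap"],
            fz1=series["fz1"],
            fz2=series["fz2"],
            body_weight=float(_require_meta(meta, "body_weight", path)),
            quiet_window=quiet,
            task=task,
            stepping_side=side,
        )
    return ImuRecording(
        trunk_acc_v=series["trunk_acc_v"],
        trunk_acc_ml=series["trunk_acc_ml"],
        trunk_acc_ap=series["trunk_acc_ap"],
        shank_gyro_ml=series["shank_gyro_ml"],
        quiet_window=quiet,
        task=task,
        stepping_side=side,
    )


def write_recording(
    rec: ForcePlateRecording | ImuRecording, path: str | os.PathLike
) -> None:
    """Write a recording as CSV plus JSON sidecar (inverse of read)."""
    path = Path(path)
    if isinstance(rec, ForcePlateRecording):
        names = FORCE_PLATE_CHANNELS
        series = {ch: getattr(rec, ch) for ch in names}
        meta: dict = {"body_weight": rec.body_weight}
    elif isinstance(rec, ImuRecording):
        names = IMU_CHANNELS
        series = {ch: getattr(rec, ch) for ch in names}
        meta = {}
    else:  # pragma: no cover - defensive
        raise SchemaError(f"cannot write object of type {type(rec).__name__}")
    mirror = -1.0 if rec.stepping_side is Side.LEFT else 1.0
    cols = {
        ch: (mirror * s.values if ch.endswith("_ml") else s.values)
        for ch, s in series.items()
    }
    meta.update(
        fs=rec.fs,
        t0=series[names[0]].t0,
        quiet_window=list(rec.quiet_window),
        task=rec.task.value,
        stepping_side=rec.stepping_side.value,
        units={ch: series[ch].units for ch in names},
    )
    frame = pd.DataFrame(cols, columns=list(names))
    atomic_write_text(path, frame.to_csv(index=False, float_format=CSV_FLOAT_FORMAT))
    atomic_write_text(_sidecar_path(path), json.dumps(meta, indent=1) + "\n")


def write_events(events: GaitEvents, path: str | os.PathLike) -> None:
    """Write events as a small JSON document (seconds as decimal numbers)."""
    atomic_write_text(path, json.dumps(events.as_dict(), indent=1) + "\n")


def read_events(path: str | os.PathLike) -> GaitEvents:
    """Exact inverse of :func:`write_events`.

    Raises :class:`IntegrityError` if the stored times violate the event
    ordering invariant, :class:`SchemaError` on malformed documents.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"unreadable event file {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise SchemaError(f"event file {path} must hold a JSON object")
    return events_from_mapping(payload)


# ---------------------------------------------------------------------------
# Run configuration


class FilterSettings(BaseModel):
    """Low-pass cutoffs (Hz) of the zero-phase Butterworth stages."""

    cop_cutoff_hz: float = 10.0
    imu_cutoff_hz: float = 3.5
    order: int = 4

    @field_validator("cop_cutoff_hz", "imu_cutoff_hz")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("cutoff must be positive")
        return v


class TaskThresholds(BaseModel):
    A: float = 2.0
    H: float = 0.07
    T: float = 0.25
    fc_grf_fraction: float = 0.065

    def to_thresholds(self) -> Thresholds:
        return Thresholds(self.A, self.H, self.T, self.fc_grf_fraction)


class GridRanges(BaseModel):
    """Calibration grid: A in 1..5 step 1, H in 0..1 step 0.01, T in 0..1
    step 0.05."""

    a_values: list[float] = Field(default_factory=lambda: [1, 2, 3, 4, 5])
    h_step: float = 0.01
    t_step: float = 0.05

    def h_values(self) -> np.ndarray:
        return np.round(np.arange(0, 1 + self.h_step / 2, self.h_step), 10)

    def t_values(self) -> np.ndarray:
        return np.round(np.arange(0, 1 + self.t_step / 2, self.t_step), 10)


class RunConfig(BaseModel):
    """Structured configuration shared by the CLI subcommands."""

    filters: FilterSettings = Field(default_factory=FilterSettings)
    thresholds: dict[str, TaskThresholds] = Field(
        default_factory=lambda: {
            "gait_initiation": TaskThresholds(A=2, H=0.07, T=0.25),
            "step_climbing": TaskThresholds(A=2, H=0.08, T=1.0),
        }
    )
    grid: GridRanges = Field(default_factory=GridRanges)
    sustained_s: float = 0.025
    seed: int = 0

    def thresholds_for(self, task: Task | str) -> Thresholds:
        return self.thresholds[Task(task).value].to_thresholds()


def load_config(path: str | os.PathLike | None) -> RunConfig:
    """Load a JSON config file, or the defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"unreadable config {path}: {exc}") from exc
    return RunConfig.model_validate(payload)
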
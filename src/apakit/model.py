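"""Domain types for APA (anticipatory postural adjustment) analysis.

The carriers here are deliberately small: a uniformly sampled
:class:`TimeSeries`, the two recording containers (force plate at 800 Hz,
inertial at 50 Hz), the five gait-initiation instants, the threshold set of
the inertial detector, and the per-trial spatio-temporal parameters.

Conventions
-----------
* Time is continuous seconds from the start of the recording; sample ``i``
  of a series lives at ``t0 + i / fs`` (no half-sample offset).  Event times
  are real numbers, so 800 Hz and 50 Hz sources compare directly.
* The medio-lateral (ML) axis is positive toward the stepping (leading)
  side; antero-posterior (AP) is positive forward.  With this convention the
  imbalance-phase ML amplitude is positive and the unloading-phase ML
  amplitude negative.  Recordings of a left-stepping trial are mirrored on
  load so the convention holds internally.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Task",
    "Side",
    "EventSource",
    "TimeSeries",
    "ForcePlateRecording",
    "ImuRecording",
    "GaitEvents",
    "Thresholds",
    "ApaParameters",
    "CalibrationResult",
    "SchemaError",
    "IntegrityError",
    "DetectionError",
    "DegenerateBaselineError",
    "DegenerateLineError",
    "CalibrationError",
    "STANDARD_GRAVITY",
]

STANDARD_GRAVITY = 9.80665  # m/s^2


class SchemaError(ValueError):
    """A file or container violates the expected schema."""


class IntegrityError(ValueError):
    """Stored data violates a structural invariant (e.g. event ordering)."""


class DetectionError(RuntimeError):
    """An event detector could not locate its event."""


class DegenerateBaselineError(DetectionError):
    """Quiet-standing SD is zero; caller must supply an absolute threshold."""


class DegenerateLineError(DetectionError):
    """The two anchor points of a reference line coincide."""


class CalibrationError(RuntimeError):
    """Grid-search calibration failed on every grid point."""


class Task(str, enum.Enum):
    GAIT_INITIATION = "gait_initiation"
    STEP_CLIMBING = "step_climbing"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class EventSource(str, enum.Enum):
    FORCE_PLATE = "force_plate"
    IMU = "imu"
    GROUND_TRUTH = "ground_truth"


@dataclass(frozen=True)
class TimeSeries:
    """One uniformly sampled channel.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    fs : float
        Sampling rate, Hz (> 0).
    values : numpy.ndarray
        Samples, one channel, finite.
    units : str
        Free-text unit tag (``"cm"``, ``"m/s^2"``, ``"deg/s"``, ``"N"``).
    """

    t0: float
    fs: float
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not (self.fs > 0):
            raise SchemaError(f"sampling rate must be positive, got {self.fs}")
        if vals.ndim != 1:
            raise SchemaError("TimeSeries holds exactly one channel")
        if vals.size and not np.all(np.isfinite(vals)):
            raise SchemaError("TimeSeries values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span from first to one-past-last sample, seconds."""
        return len(self) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (clipped to range)."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), len(self) - 1)

    def time_at(self, i: int) -> float:
        return self.t0 + i / self.fs

    def value_at(self, t: float) -> float:
        """Value at the nearest sample to ``t``."""
        return float(self.values[self.index_at(t)])

    def slice(self, start: float, stop: float) -> "TimeSeries":
        """Sub-series covering sample instants in ``[start, stop)``."""
        i0 = max(0, int(math.ceil((start - self.t0) * self.fs - 1e-9)))
        i1 = min(len(self), int(math.floor((stop - self.t0) * self.fs - 1e-9)) + 1)
        if i1 <= i0:
            raise SchemaError(f"empty slice [{start}, {stop}) of series starting {self.t0}")
        return TimeSeries(self.time_at(i0), self.fs, self.values[i0:i1], self.units)

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(self.t0, self.fs, values, self.units)


def _check_aligned(series: Iterable[TimeSeries]) -> None:
    series = list(series)
    fs0, t00, n0 = series[0].fs, series[0].t0, len(series[0])
    for s in series[1:]:
        if s.fs != fs0 or s.t0 != t00 or len(s) != n0:
            raise SchemaError("all channels of a recording must share fs, t0 and length")


def _check_quiet_window(qw: tuple[float, float], t0: float) -> tuple[float, float]:
    a, b = float(qw[0]), float(qw[1])
    if not (b - a >= 1.0):
        raise SchemaError(f"quiet window must be at least 1 s long, got {qw}")
    if a < t0 - 1e-9:
        raise SchemaError("quiet window starts before the recording")
    return (a, b)


@dataclass(frozen=True)
class ForcePlateRecording:
    """Two-plate COP / vertical-GRF recording (gold standard).

    Plate 1 carries both feet during quiet stance and the trailing foot
    during the first swing; plate 2 receives the leading foot.  COP is the
    plate-1 centre of pressure in cm, Fz the per-plate vertical ground
    reaction force in N.
    """

    cop1_ml: TimeSeries
    cop1_ap: TimeSeries
    fz1: TimeSeries
    fz2: TimeSeries
    body_weight: float
    quiet_window: tuple[float, float]
    task: Task = Task.GAIT_INITIATION
    stepping_side: Side = Side.RIGHT

    def __post_init__(self) -> None:
        _check_aligned([self.cop1_ml, self.cop1_ap, self.fz1, self.fz2])
        if not (self.body_weight > 0):
            raise SchemaError(f"body weight must be positive, got {self.body_weight}")
        object.__setattr__(
            self, "quiet_window", _check_quiet_window(self.quiet_window, self.cop1_ml.t0)
        )
        object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "stepping_side", Side(self.stepping_side))

    @property
    def fs(self) -> float:
        return self.cop1_ml.fs


@dataclass(frozen=True)
class ImuRecording:
    """Two-unit wearable recording: lower-trunk 3D accelerometer (m/s^2)
    and a shank gyroscope channel about the limb ML axis (deg/s)."""

    trunk_acc_v: TimeSeries
    trunk_acc_ml: TimeSeries
    trunk_acc_ap: TimeSeries
    shank_gyro_ml: TimeSeries
    quiet_window: tuple[float, float]
    task: Task = Task.GAIT_INITIATION
    stepping_side: Side = Side.RIGHT

    def __post_init__(self) -> None:
        _check_aligned(
            [self.trunk_acc_v, self.trunk_acc_ml, self.trunk_acc_ap, self.shank_gyro_ml]
        )
        object.__setattr__(
            self, "quiet_window", _check_quiet_window(self.quiet_window, self.trunk_acc_v.t0)
        )
        object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "stepping_side", Side(self.stepping_side))

    @property
    def fs(self) -> float:
        return self.trunk_acc_v.fs


@dataclass(frozen=True)
class GaitEvents:
    """The detected instants of one trial, seconds.

    ``apa_onset <= heel_off <= toe_off <= foot_contact`` always;
    ``heel_off <= toe_off <= trailing_toe_off`` when the trailing toe-off is
    present (plate-1 lift-off happens after the leading foot has left).
    """

    apa_onset: float
    heel_off: float
    toe_off: float
    foot_contact: float
    trailing_toe_off: float | None = None
    source: EventSource = EventSource.GROUND_TRUTH

    def __post_init__(self) -> None:
        seq = [self.apa_onset, self.heel_off, self.toe_off, self.foot_contact]
        if any(b < a - 1e-12 for a, b in zip(seq, seq[1:])):
            raise IntegrityError(
                "event ordering violated: require apa_onset <= heel_off <= "
                f"toe_off <= foot_contact, got {seq}"
            )
        if self.trailing_toe_off is not None and self.trailing_toe_off < self.toe_off - 1e-12:
            raise IntegrityError(
                "trailing toe-off precedes leading toe-off: "
                f"{self.trailing_toe_off} < {self.toe_off}"
            )
        object.__setattr__(self, "source", EventSource(self.source))

    def as_dict(self) -> dict:
        d = {
            "apa_onset": self.apa_onset,
            "heel_off": self.heel_off,
            "toe_off": self.toe_off,
            "foot_contact": self.foot_contact,
            "source": self.source.value,
        }
        if self.trailing_toe_off is not None:
            d["trailing_toe_off"] = self.trailing_toe_off
        return d


# Calibrated multiplicative factors of the inertial detector (per task):
# gait initiation A=2, H=0.07, T=0.25; step climbing A=2, H=0.08, T=1.
@dataclass(frozen=True)
class Thresholds:
    """Multiplicative factors of the threshold-based inertial detectors.

    ``A`` scales the quiet-standing SD of the trunk ML acceleration for APA
    onset; ``H`` and ``T`` scale the first shank angular-velocity peak
    (Ωpk) for heel-off and toe-off.  ``fc_grf_fraction`` is the
    body-weight fraction of the vertical-GRF foot-contact threshold.
    """

    A: float
    H: float
    T: float
    fc_grf_fraction: float = 0.065

    def __post_init__(self) -> None:
        if self.A < 0:
            raise SchemaError(f"A must be non-negative, got {self.A}")
        if not (0 <= self.H <= 1):
            raise SchemaError(f"H must lie in [0, 1], got {self.H}")
        if not (0 <= self.T <= 1):
            raise SchemaError(f"T must lie in [0, 1], got {self.T}")
        if not (0 < self.fc_grf_fraction < 1):
            raise SchemaError(
                f"fc_grf_fraction must lie in (0, 1), got {self.fc_grf_fraction}"
            )


DEFAULT_THRESHOLDS: dict[Task, Thresholds] = {
    Task.GAIT_INITIATION: Thresholds(A=2, H=0.07, T=0.25),
    Task.STEP_CLIMBING: Thresholds(A=2, H=0.08, T=1.0),
}


@dataclass(frozen=True)
class ApaParameters:
    """Per-trial spatio-temporal parameters.

    Durations in seconds; amplitudes in the source's signal units (cm for
    COP, m/s^2 for trunk acceleration).  ``dur_apa = dur_imbalance +
    dur_unloading`` and ``dur_step = dur_apa + dur_swing`` hold exactly.
    """

    dur_imbalance: float
    dur_unloading: float
    dur_apa: float
    dur_swing: float
    dur_step: float
    amp_imbalance_ml: float = math.nan
    amp_imbalance_ap: float = math.nan
    amp_unloading_ml: float = math.nan
    amp_unloading_ap: float = math.nan
    source: EventSource = EventSource.GROUND_TRUTH

    _DURATIONS = ("dur_imbalance", "dur_unloading", "dur_apa", "dur_swing", "dur_step")
    _AMPLITUDES = (
        "amp_imbalance_ml",
        "amp_imbalance_ap",
        "amp_unloading_ml",
        "amp_unloading_ap",
    )

    def __post_init__(self) -> None:
        for name in self._DURATIONS:
            if getattr(self, name) < -1e-12:
                raise IntegrityError(f"{name} must be non-negative")
        if abs(self.dur_apa - (self.dur_imbalance + self.dur_unloading)) > 1e-9:
            raise IntegrityError("dur_apa must equal dur_imbalance + dur_unloading")
        if abs(self.dur_step - (self.dur_apa + self.dur_swing)) > 1e-9:
            raise IntegrityError("dur_step must equal dur_apa + dur_swing")
        object.__setattr__(self, "source", EventSource(self.source))

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self._DURATIONS + self._AMPLITUDES}
        d["source"] = self.source.value
        return d


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the A/H/T grid search against force-plate ground truth.

    ``grid`` maps each visited ``(A, H, T)`` triple to the per-event MAEs
    (seconds) averaged across subjects, for audit and exhaustive re-scan.
    """

    best: Thresholds
    mae_onset: float
    mae_heel_off: float
    mae_toe_off: float
    mae_foot_contact: float
    grid: Mapping[tuple[float, float, float], dict[str, float]] = field(default_factory=dict)
    task: Task = Task.GAIT_INITIATION

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))


def events_from_mapping(d: Mapping, default_source: str = "ground_truth") -> GaitEvents:
    """Build :class:`GaitEvents` from a plain mapping (JSON payload)."""
    required = ("apa_onset", "heel_off", "toe_off", "foot_contact")
    missing = [k for k in required if k not in d]
    if missing:
        raise SchemaError(f"event fields absent: {', '.join(missing)}")
    try:
        vals = {k: float(d[k]) for k in required}
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric event time: {exc}") from exc
    tto = d.get("trailing_toe_off")
    return GaitEvents(
        **vals,
        trailing_toe_off=None if tto is None else float(tto),
        source=EventSource(d.get("source", default_source)),
    )
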
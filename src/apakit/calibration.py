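"""Grid-search calibration of the inertial detector factors A, H, T.

The factors are tuned against force-plate events on paired trials
(subjects recorded with both systems simultaneously): ``A`` over 1..5 in
unit steps, ``H`` over 0..1 in steps of 0.01, ``T`` over 0..1 in steps
of 0.05.  For every grid value the mean absolute error (MAE) between the
inertial and the force-plate event times is computed per subject and
averaged across subjects; the selected factors minimise the averaged MAE
of their respective event (onset for A, heel-off for H given A, toe-off
for T given A — toe-off does not depend on H, and heel-off depends on A
only through the onset).  Foot contact has no free parameter; its MAE is
reported but not optimised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fp_events import DEFAULT_SUSTAINED_S, first_sustained_crossing
from .imu_events import (
    detect_foot_contact_imu,
    extract_gyro_features,
    preprocess_imu,
)
from .io import GridRanges
from .model import (
    CalibrationError,
    CalibrationResult,
    DetectionError,
    GaitEvents,
    ImuRecording,
    Task,
    Thresholds,
)

__all__ = ["PairedTrial", "MaeReport", "mae_per_event", "calibrate"]

log = logging.getLogger("apakit.calibration")

EVENT_NAMES = ("apa_onset", "heel_off", "toe_off", "foot_contact")


@dataclass(frozen=True)
class PairedTrial:
    """One trial recorded simultaneously with both systems: the
    force-plate events (gold standard) and the raw inertial recording."""

    fp_events: GaitEvents
    imu_rec: ImuRecording
    subject: str
    task: Task = Task.GAIT_INITIATION

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))


@dataclass(frozen=True)
class MaeReport:
    """Per-event mean absolute errors between two event sources.

    ``mae`` in seconds; ``pct`` as a percentage of the (force-plate)
    step duration, both averaged per subject first and then across
    subjects.
    """

    mae: dict[str, float]
    pct: dict[str, float]
    n_subjects: int
    n_pairs: int
    n_excluded: int = 0


def _subject_then_grand_mean(values: np.ndarray, subjects: list[str]) -> float:
    """Mean over trials within each subject, then across subjects
    (NaN-aware; a subject with no valid trial is dropped)."""
    per_subject = []
    for s in sorted(set(subjects)):
        v = values[[i for i, x in enumerate(subjects) if x == s]]
        if np.isfinite(v).any():
            per_subject.append(np.nanmean(v))
    if not per_subject:
        return float("nan")
    return float(np.mean(per_subject))


def mae_per_event(
    pairs: list[tuple[GaitEvents | None, GaitEvents | None]],
    subjects: list[str] | None = None,
) -> MaeReport:
    """MAE between paired event sets, per event.

    ``pairs`` holds (reference, candidate) tuples — typically
    (force-plate, inertial).  Pairs with a missing member are excluded
    with a warning.  When ``subjects`` is given, errors are averaged per
    subject before the across-subject mean (the reported value);
    otherwise each pair counts as its own subject.
    """
    if not pairs:
        raise ValueError("need at least one event pair")
    if subjects is None:
        subjects = [str(i) for i in range(len(pairs))]
    if len(subjects) != len(pairs):
        raise ValueError("subjects must align with pairs")

    kept_idx = [i for i, (a, b) in enumerate(pairs) if a is not None and b is not None]
    n_excluded = len(pairs) - len(kept_idx)
    if n_excluded:
        log.warning("excluded %d pair(s) with missing events", n_excluded)
    if not kept_idx:
        raise ValueError("no complete event pairs")

    mae: dict[str, float] = {}
    pct: dict[str, float] = {}
    kept_subjects = [subjects[i] for i in kept_idx]
    steps = np.array(
        [pairs[i][0].foot_contact - pairs[i][0].apa_onset for i in kept_idx]
    )
    for name in EVENT_NAMES:
        errs = np.array(
            [abs(getattr(pairs[i][1], name) - getattr(pairs[i][0], name)) for i in kept_idx]
        )
        mae[name] = _subject_then_grand_mean(errs, kept_subjects)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(steps > 0, errs / steps, np.nan)
        pct[name] = _subject_then_grand_mean(100.0 * rel, kept_subjects)
    return MaeReport(
        mae=mae,
        pct=pct,
        n_subjects=len(set(kept_subjects)),
        n_pairs=len(kept_idx),
        n_excluded=n_excluded,
    )


@dataclass
class _TrialScan:
    """Per-trial detection results across the A grid (computed once)."""

    subject: str
    fp: GaitEvents
    onset: dict[float, float] = field(default_factory=dict)  # A -> time
    heel: dict[float, np.ndarray] = field(default_factory=dict)  # A -> per-H times
    toe: dict[float, np.ndarray] = field(default_factory=dict)  # A -> per-T times
    contact: dict[float, float] = field(default_factory=dict)  # A -> time


def _scan_trial(
    pt: PairedTrial,
    a_values: np.ndarray,
    h_values: np.ndarray,
    t_values: np.ndarray,
    sustained_s: float,
) -> _TrialScan:
    scan = _TrialScan(subject=pt.subject, fp=pt.fp_events)
    _, acc_ml, _, gyro = preprocess_imu(pt.imu_rec)
    qw = pt.imu_rec.quiet_window
    quiet = acc_ml.slice(*qw)
    mean = float(np.mean(quiet.values))
    sd = float(np.std(quiet.values))
    fs = gyro.fs

    for a in a_values:
        try:
            t_on = first_sustained_crossing(acc_ml, qw[1], mean, a * sd, sustained_s)
            feats = extract_gyro_features(gyro, t_on)
        except DetectionError as exc:
            log.debug("subject %s: A=%g failed: %s", pt.subject, a, exc)
            continue
        scan.onset[a] = t_on
        scan.contact[a] = detect_foot_contact_imu(feats)

        i_on = int(np.floor((t_on - gyro.t0) * fs + 1e-9)) + 1
        i_pk1 = gyro.index_at(feats.t_pk1)
        rising = feats.sign * gyro.values[i_on : i_pk1 + 1]
        heel_times = np.full(h_values.size, np.nan)
        for hi, h in enumerate(h_values):
            idx = np.flatnonzero(rising > h * feats.omega_pk)
            if idx.size:
                heel_times[hi] = gyro.time_at(i_on + int(idx[0]))
        scan.heel[a] = heel_times

        falling = feats.sign * gyro.values[i_pk1 + 1 :]
        toe_times = np.full(t_values.size, np.nan)
        for ti, tt in enumerate(t_values):
            idx = np.flatnonzero(falling < tt * feats.omega_pk)
            if idx.size:
                toe_times[ti] = gyro.time_at(i_pk1 + 1 + int(idx[0]))
        scan.toe[a] = toe_times
    return scan


def calibrate(
    pairs: list[PairedTrial],
    grid: GridRanges | None = None,
    sustained_s: float = DEFAULT_SUSTAINED_S,
) -> CalibrationResult:
    """Exhaustive A/H/T grid search minimising per-event averaged MAE.

    Returns the selected thresholds together with the full MAE surface
    (for audit: the optimum is re-verifiable by re-scanning ``grid``).
    Raises :class:`CalibrationError` when detection fails everywhere.
    """
    if not pairs:
        raise CalibrationError("no paired trials supplied")
    tasks = {pt.task for pt in pairs}
    if len(tasks) > 1:
        raise CalibrationError(f"mixed tasks in one calibration set: {sorted(t.value for t in tasks)}")
    grid = grid or GridRanges()
    a_values = np.asarray(grid.a_values, dtype=float)
    h_values = grid.h_values()
    t_values = grid.t_values()

    scans = [_scan_trial(pt, a_values, h_values, t_values, sustained_s) for pt in pairs]
    subjects = [s.subject for s in scans]

    def grand(errs: np.ndarray) -> float:
        return _subject_then_grand_mean(errs, subjects)

    nan = float("nan")
    mae_onset = np.array(
        [
            grand(
                np.array(
                    [abs(s.onset[a] - s.fp.apa_onset) if a in s.onset else nan for s in scans]
                )
            )
            for a in a_values
        ]
    )
    if not np.isfinite(mae_onset).any():
        raise CalibrationError(
            "onset detection failed for every trial at every A; "
            "check quiet windows and signal quality"
        )
    ia = int(np.nanargmin(mae_onset))  # ties resolve to the smallest factor
    a_best = float(a_values[ia])

    mae_heel = np.array(
        [
            grand(
                np.array(
                    [
                        abs(s.heel[a_best][hi] - s.fp.heel_off) if a_best in s.heel else nan
                        for s in scans
                    ]
                )
            )
            for hi in range(h_values.size)
        ]
    )
    mae_toe = np.array(
        [
            grand(
                np.array(
                    [
                        abs(s.toe[a_best][ti] - s.fp.toe_off) if a_best in s.toe else nan
                        for s in scans
                    ]
                )
            )
            for ti in range(t_values.size)
        ]
    )
    if not (np.isfinite(mae_heel).any() and np.isfinite(mae_toe).any()):
        raise CalibrationError("heel-off/toe-off detection failed across the whole grid")
    ih = int(np.nanargmin(mae_heel))
    it = int(np.nanargmin(mae_toe))
    h_best = float(h_values[ih])
    t_best = float(t_values[it])
    mae_contact = grand(
        np.array(
            [abs(s.contact[a_best] - s.fp.foot_contact) if a_best in s.contact else nan for s in scans]
        )
    )

    # full audit surface: onset/contact vary with A only, heel-off with
    # (A, H), toe-off with (A, T)
    heel_by_a = {
        float(a): np.array(
            [
                grand(np.array([abs(s.heel[a][hi] - s.fp.heel_off) if a in s.heel else nan for s in scans]))
                for hi in range(h_values.size)
            ]
        )
        for a in a_values
    }
    toe_by_a = {
        float(a): np.array(
            [
                grand(np.array([abs(s.toe[a][ti] - s.fp.toe_off) if a in s.toe else nan for s in scans]))
                for ti in range(t_values.size)
            ]
        )
        for a in a_values
    }
    contact_by_a = {
        float(a): grand(
            np.array([abs(s.contact[a] - s.fp.foot_contact) if a in s.contact else nan for s in scans])
        )
        for a in a_values
    }
    surface = {}
    for iaa, a in enumerate(a_values):
        for hi, h in enumerate(h_values):
            for ti, tt in enumerate(t_values):
                surface[(float(a), float(h), float(tt))] = {
                    "apa_onset": float(mae_onset[iaa]),
                    "heel_off": float(heel_by_a[float(a)][hi]),
                    "toe_off": float(toe_by_a[float(a)][ti]),
                    "foot_contact": float(contact_by_a[float(a)]),
                }

    task = next(iter(tasks))
    log.info(
        "calibrated %s: A=%g H=%g T=%g (MAE onset %.3f, heel %.3f, toe %.3f, contact %.3f s)",
        task.value,
        a_best,
        h_best,
        t_best,
        mae_onset[ia],
        mae_heel[ih],
        mae_toe[it],
        mae_contact,
    )
    return CalibrationResult(
        best=Thresholds(A=a_best, H=h_best, T=t_best),
        mae_onset=float(mae_onset[ia]),
        mae_heel_off=float(mae_heel[ih]),
        mae_toe_off=float(mae_toe[it]),
        mae_foot_contact=float(mae_contact),
        grid=surface,
        task=task,
    )
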
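"""Wearable-sensor gait-event detection.

Four instants are extracted per trial from the two-unit inertial setup:

* **APA onset** — first sustained excursion of the tilt-corrected,
  3.5 Hz-filtered trunk ML acceleration beyond ``A`` times its
  quiet-standing SD;
* **heel-off** — first instant after onset at which the filtered shank ML
  angular velocity exceeds ``H`` times its first peak value Ωpk;
* **toe-off** — first instant after that peak at which the signal drops
  below ``T`` times Ωpk;
* **foot contact** — median point between the second angular-velocity
  peak and the preceding zero-crossing.

``A``, ``H`` and ``T`` are the multiplicative factors calibrated against
the force-plate gold standard (gait initiation: A=2, H=0.07, T=0.25;
step climbing: A=2, H=0.08, T=1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .fp_events import (
    DEFAULT_CONFIRM_MULT,
    DEFAULT_SUSTAINED_S,
    NOISELESS_ONSET_THRESHOLD,
    first_sustained_crossing,
)
from .model import (
    DegenerateBaselineError,
    DetectionError,
    EventSource,
    GaitEvents,
    ImuRecording,
    Thresholds,
    TimeSeries,
)
from .preprocess import FilterSpec, tilt_correct, zero_phase_lowpass

__all__ = [
    "GyroFeatures",
    "detect_onset_imu",
    "extract_gyro_features",
    "detect_heel_off_imu",
    "detect_toe_off_imu",
    "detect_foot_contact_imu",
    "preprocess_imu",
    "detect_all_imu",
]

log = logging.getLogger("apakit.imu")

#: local maxima must rise at least this fraction of the post-onset global
#: maximum above their surroundings to qualify as gait peaks
PEAK_PROMINENCE_FRACTION = 0.10


@dataclass(frozen=True)
class GyroFeatures:
    """Landmarks of the (sign-normalized) filtered shank angular velocity.

    ``omega_pk`` is the first-peak value in deg/s; ``t_pk1`` and ``t_pk2``
    the first and second peak times; ``t_zero_cross`` the last
    zero-crossing preceding the second peak (located by linear
    interpolation, so it need not sit on the sample grid).  ``sign`` is
    -1 when the raw signal was negated to make the swing rotation
    positive (mirror-mounted sensor).
    """

    omega_pk: float
    t_pk1: float
    t_pk2: float
    t_zero_cross: float
    sign: float = 1.0

    def __post_init__(self) -> None:
        if not self.omega_pk > 0:
            raise DetectionError(f"Ωpk must be positive, got {self.omega_pk}")
        if not (self.t_pk1 < self.t_zero_cross < self.t_pk2):
            raise DetectionError(
                "gyro landmarks out of order: expected t_pk1 < t_zero_cross "
                f"< t_pk2, got {self.t_pk1}, {self.t_zero_cross}, {self.t_pk2}"
            )


def detect_onset_imu(
    trunk_acc_ml: TimeSeries,
    quiet_window: tuple[float, float],
    A: float,
    sustained_s: float = DEFAULT_SUSTAINED_S,
    abs_threshold: float | None = None,
    confirm_mult: float | None = DEFAULT_CONFIRM_MULT,
) -> float:
    """APA onset from tilt-corrected, filtered trunk ML acceleration.

    Threshold is ``A`` times the quiet-standing SD; crossing
    qualification is as for the force-plate onset detector.
    """
    quiet = trunk_acc_ml.slice(*quiet_window)
    mean = float(np.mean(quiet.values))
    sd = float(np.std(quiet.values))
    scale = float(np.max(np.abs(trunk_acc_ml.values - mean)))
    if abs_threshold is not None:
        threshold = abs_threshold
    elif sd <= 1e-9 * max(scale, 1e-30):
        raise DegenerateBaselineError(
            "quiet-standing SD is zero; supply an absolute onset threshold"
        )
    else:
        threshold = A * sd
    return first_sustained_crossing(
        trunk_acc_ml, quiet_window[1], mean, threshold, sustained_s, confirm_mult
    )


def _qualifying_peaks(seg: np.ndarray) -> np.ndarray:
    """Indices of local maxima with prominence and height >= 10% of the
    segment max (the height floor rejects small ridges whose prominence
    is inflated by a deep neighbouring valley)."""
    floor = PEAK_PROMINENCE_FRACTION * float(np.max(np.abs(seg)))
    if floor <= 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(seg, prominence=floor, height=floor)
    return peaks


def extract_gyro_features(shank_gyro_ml: TimeSeries, t_onset: float) -> GyroFeatures:
    """Locate Ωpk, the second peak and the preceding zero-crossing.

    The search is windowed after the detected APA onset.  If the first
    qualifying extremum after onset is negative the signal is negated
    (mirror-mounted sensor) before peak extraction.
    """
    i0 = shank_gyro_ml.index_at(t_onset)
    seg = shank_gyro_ml.values[i0:]
    if seg.size < 3:
        raise DetectionError("record ends at APA onset; no gyroscope data to scan")

    # mirror-mounted sensor: the dominant extremum (the swing rotation)
    # decides the sign; filter pre-ring can precede the true first peak,
    # so "which extremum comes first" is not a reliable discriminator
    sign = 1.0
    if -float(np.min(seg)) > float(np.max(seg)):
        sign = -1.0
        seg = -seg
    pos = _qualifying_peaks(seg)
    if pos.size < 2:
        raise DetectionError(
            f"found {pos.size} qualifying angular-velocity peak(s) after onset; need 2"
        )
    p1, p2 = int(pos[0]), int(pos[1])
    omega_pk = float(seg[p1])

    # last zero-crossing before the second peak, linearly interpolated
    sgn = np.signbit(seg[: p2 + 1])
    flips = np.flatnonzero(sgn[1:] != sgn[:-1])
    flips = flips[flips >= p1]  # a crossing before Ωpk would not separate the pulses
    if flips.size == 0:
        raise DetectionError("no zero-crossing between the two angular-velocity peaks")
    k = int(flips[-1])
    v0, v1 = float(seg[k]), float(seg[k + 1])
    frac = 0.0 if v1 == v0 else -v0 / (v1 - v0)
    t_zc = shank_gyro_ml.time_at(i0 + k) + frac / shank_gyro_ml.fs

    return GyroFeatures(
        omega_pk=omega_pk,
        t_pk1=shank_gyro_ml.time_at(i0 + p1),
        t_pk2=shank_gyro_ml.time_at(i0 + p2),
        t_zero_cross=t_zc,
        sign=sign,
    )


def detect_heel_off_imu(
    shank_gyro_ml: TimeSeries, t_onset: float, features: GyroFeatures, H: float
) -> float:
    """Heel-off: first sample in (t_onset, t_pk1] above ``H``·Ωpk."""
    if not t_onset < features.t_pk1:
        raise DetectionError("APA onset must precede the first gyro peak")
    i0 = int(np.floor((t_onset - shank_gyro_ml.t0) * shank_gyro_ml.fs + 1e-9)) + 1
    i1 = shank_gyro_ml.index_at(features.t_pk1)
    vals = features.sign * shank_gyro_ml.values[i0 : i1 + 1]
    idx = np.flatnonzero(vals > H * features.omega_pk)
    if idx.size == 0:
        raise DetectionError(
            f"angular velocity never exceeds H·Ωpk = {H * features.omega_pk:.3g} "
            "deg/s before its first peak"
        )
    return shank_gyro_ml.time_at(i0 + int(idx[0]))


def detect_toe_off_imu(
    shank_gyro_ml: TimeSeries, features: GyroFeatures, T: float
) -> float:
    """Toe-off: first sample after the first peak below ``T``·Ωpk."""
    i0 = shank_gyro_ml.index_at(features.t_pk1) + 1
    vals = features.sign * shank_gyro_ml.values[i0:]
    idx = np.flatnonzero(vals < T * features.omega_pk)
    if idx.size == 0:
        raise DetectionError(
            f"angular velocity never drops below T·Ωpk = {T * features.omega_pk:.3g} "
            "deg/s after its first peak"
        )
    return shank_gyro_ml.time_at(i0 + int(idx[0]))


def detect_foot_contact_imu(features: GyroFeatures) -> float:
    """Foot contact: median point between the zero-crossing and the
    second angular-velocity peak."""
    if features.t_zero_cross == features.t_pk2:  # degenerate, flagged
        log.warning(
            "zero-crossing coincides with second gyro peak at %.4f s", features.t_pk2
        )
    return 0.5 * (features.t_zero_cross + features.t_pk2)


def preprocess_imu(
    rec: ImuRecording, imu_filter: FilterSpec | None = None
) -> tuple[TimeSeries, TimeSeries, TimeSeries, TimeSeries]:
    """Tilt-correct the trunk triplet and low-pass everything at 3.5 Hz.

    Returns filtered (acc_v, acc_ml, acc_ap, gyro_ml); the detection
    entry point and the parameter extraction share this path.
    """
    spec = imu_filter or FilterSpec(cutoff=3.5)
    acc_v, acc_ml, acc_ap = tilt_correct(
        rec.trunk_acc_v, rec.trunk_acc_ml, rec.trunk_acc_ap, rec.quiet_window
    )
    return (
        zero_phase_lowpass(acc_v, spec),
        zero_phase_lowpass(acc_ml, spec),
        zero_phase_lowpass(acc_ap, spec),
        zero_phase_lowpass(rec.shank_gyro_ml, spec),
    )


def detect_all_imu(
    rec: ImuRecording,
    thresholds: Thresholds,
    imu_filter: FilterSpec | None = None,
    sustained_s: float = DEFAULT_SUSTAINED_S,
    abs_onset_threshold: float | None = None,
) -> GaitEvents:
    """Run the full inertial detection chain on one trial."""
    _, acc_ml, _, gyro = preprocess_imu(rec, imu_filter)
    try:
        t_onset = detect_onset_imu(
            acc_ml, rec.quiet_window, thresholds.A, sustained_s, abs_onset_threshold
        )
    except DegenerateBaselineError:
        # noiseless record: first departure of the raw (tilt-corrected)
        # channel from baseline
        raw_ml = tilt_correct(
            rec.trunk_acc_v, rec.trunk_acc_ml, rec.trunk_acc_ap, rec.quiet_window
        )[1]
        t_onset = detect_onset_imu(
            raw_ml, rec.quiet_window, thresholds.A, sustained_s, NOISELESS_ONSET_THRESHOLD
        )
    features = extract_gyro_features(gyro, t_onset)
    t_heel = detect_heel_off_imu(gyro, t_onset, features, thresholds.H)
    t_toe = detect_toe_off_imu(gyro, features, thresholds.T)
    t_contact = detect_foot_contact_imu(features)
    log.debug(
        "imu detection: onset=%.4f heel=%.4f toe=%.4f contact=%.4f (Ωpk=%.1f deg/s)",
        t_onset,
        t_heel,
        t_toe,
        t_contact,
        features.omega_pk,
    )
    return GaitEvents(
        apa_onset=t_onset,
        heel_off=t_heel,
        toe_off=t_toe,
        foot_contact=t_contact,
        source=EventSource.IMU,
    )
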
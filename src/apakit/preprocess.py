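"""Signal conditioning applied before any event detection.

Two operations: a fourth-order zero-phase low-pass Butterworth filter
(10 Hz for COP, 3.5 Hz for acceleration and angular velocity — the filter
is designed once and applied forward-backward, so the realised magnitude
response is that of an 8th-order filter and the net phase shift is zero),
and the Moe-Nilssen tilt correction that rotates trunk accelerometer axes
into a horizontal-vertical frame using the quiet-standing mean
acceleration, then removes gravity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .model import STANDARD_GRAVITY, SchemaError, TimeSeries

__all__ = ["FilterSpec", "zero_phase_lowpass", "tilt_correct", "tilt_angles"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth, zero phase.

    ``order`` is the design order of the single pass (nominal 4); the
    forward-backward application doubles the magnitude roll-off.
    """

    cutoff: float
    order: int = 4

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise SchemaError(f"cutoff must be positive, got {self.cutoff}")
        if self.order < 1:
            raise SchemaError(f"order must be >= 1, got {self.order}")


def zero_phase_lowpass(x: TimeSeries, spec: FilterSpec) -> TimeSeries:
    """Apply ``spec`` forward-backward with reflective edge padding.

    Output has the same length, ``t0`` and ``fs``; passband gain is ~1 and
    the group delay is zero.  Raises :class:`SchemaError` when the cutoff
    is not below Nyquist or the series is too short to pad.
    """
    if spec.cutoff >= x.fs / 2:
        raise SchemaError(
            f"cutoff {spec.cutoff} Hz must be below Nyquist ({x.fs / 2} Hz)"
        )
    padlen = 3 * (spec.order + 1)
    if len(x) <= padlen:
        raise SchemaError(
            f"series of {len(x)} samples too short for stable filtering "
            f"(needs > {padlen})"
        )
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=x.fs, output="sos")
    y = sps.sosfiltfilt(sos, x.values, padtype="even", padlen=padlen)
    return x.with_values(y)


def _rotation_ap(theta: float) -> np.ndarray:
    """Rotation in the vertical/AP plane (about the ML axis), (v, ml, ap)."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def tilt_angles(
    acc_v: TimeSeries, acc_ml: TimeSeries, acc_ap: TimeSeries, quiet_window: tuple[float, float]
) -> tuple[float, float]:
    """Estimated sensor tilt (AP pitch, ML roll) in radians, from the
    quiet-standing mean acceleration."""
    mv, mml, map_ = (
        float(np.mean(s.slice(*quiet_window).values)) for s in (acc_v, acc_ml, acc_ap)
    )
    gmag = math.sqrt(mv * mv + mml * mml + map_ * map_)
    theta = math.asin(map_ / gmag)
    # roll from the AP-derotated means
    mv2 = math.cos(theta) * mv + math.sin(theta) * map_
    phi = math.atan2(mml, mv2)
    return theta, phi


def tilt_correct(
    trunk_acc_v: TimeSeries,
    trunk_acc_ml: TimeSeries,
    trunk_acc_ap: TimeSeries,
    quiet_window: tuple[float, float],
) -> tuple[TimeSeries, TimeSeries, TimeSeries]:
    """Moe-Nilssen correction of a tilted trunk accelerometer.

    The sensor tilt is estimated from the mean quiet-standing acceleration
    (which, at rest, is the gravity vector in sensor axes): first the AP
    pitch from an inverse sine, then the ML roll from the derotated means.
    The acceleration triplet is rotated so the first axis is
    gravity-aligned, and the measured gravity magnitude is subtracted from
    the vertical channel.  After correction the quiet-window means of all
    three outputs are ~0.

    Raises :class:`SchemaError` when the quiet-standing acceleration
    magnitude is outside [0.5 g, 1.5 g] (sensor misplacement).
    """
    quiet = [s.slice(*quiet_window).values for s in (trunk_acc_v, trunk_acc_ml, trunk_acc_ap)]
    means = np.array([float(np.mean(q)) for q in quiet])
    gmag = float(np.linalg.norm(means))
    if not (0.5 * STANDARD_GRAVITY <= gmag <= 1.5 * STANDARD_GRAVITY):
        raise SchemaError(
            "quiet-standing acceleration magnitude "
            f"{gmag:.3f} m/s^2 implausible (expect ~g); check sensor placement"
        )
    # two-step inverse-trigonometric alignment (AP pitch, then ML roll),
    # iterated to convergence: a single pass leaves an O(theta*phi)
    # residual when both tilts are non-zero
    rot = np.eye(3)
    m = means.copy()
    for _ in range(10):
        theta = math.asin(m[2] / gmag)  # AP pitch
        r1 = _rotation_ap(theta)
        m1 = r1 @ m
        phi = math.atan2(m1[1], m1[0])  # ML roll of the derotated means
        c, s = math.cos(phi), math.sin(phi)
        r2 = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
        rot = r2 @ r1 @ rot
        m = r2 @ m1
        if max(abs(m[1]), abs(m[2])) < 1e-12 * gmag:
            break

    data = np.vstack([trunk_acc_v.values, trunk_acc_ml.values, trunk_acc_ap.values])
    out = rot @ data
    out[0] -= gmag
    return (
        trunk_acc_v.with_values(out[0]),
        trunk_acc_ml.with_values(out[1]),
        trunk_acc_ap.with_values(out[2]),
    )
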
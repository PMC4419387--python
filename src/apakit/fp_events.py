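"""Gold-standard gait-event detection from force-plate COP and GRF.

Five instants are identified per trial:

* **APA onset** — first sustained excursion of the (10 Hz-filtered) COP ML
  displacement beyond twice the quiet-standing SD;
* **trailing toe-off** — last instant the first plate's vertical force
  stays above a noise floor (6.5% body weight, symmetric with contact);
* **leading toe-off** — instant of maximal perpendicular distance
  (d_1MAX) of the COP from the line L1 joining the COP positions at APA
  onset and trailing toe-off;
* **leading heel-off** — instant of maximal distance (d_2MAX) from the
  line L2 joining the COP positions at APA onset and leading toe-off;
* **foot contact** — first instant the second plate's vertical force
  exceeds 6.5% of body weight.

The same method serves gait initiation and step climbing.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np

from .model import (
    DegenerateBaselineError,
    DegenerateLineError,
    DetectionError,
    EventSource,
    ForcePlateRecording,
    GaitEvents,
    SchemaError,
    TimeSeries,
)
from .preprocess import FilterSpec, zero_phase_lowpass

__all__ = [
    "CopPath",
    "GeoEvent",
    "detect_onset_cop",
    "detect_trailing_toe_off",
    "detect_toe_off_cop",
    "detect_heel_off_cop",
    "detect_foot_contact_grf",
    "detect_all_fp",
    "first_sustained_crossing",
]

log = logging.getLogger("apakit.fp")

#: default duration a threshold crossing must hold to count as onset
DEFAULT_SUSTAINED_S = 0.025

#: an onset excursion must reach this multiple of the threshold before
#: first dropping back below it; rejects quiet-period noise excursions
#: that a duration criterion alone cannot (the crossing level is a fixed
#: small multiple of the baseline SD of the same filtered signal, so the
#: exceedance rate is independent of the noise amplitude).  Stands in for
#: the interactive visual check of laboratory practice.
DEFAULT_CONFIRM_MULT = 5.0

#: absolute onset threshold applied to the *raw* channel when the quiet
#: baseline is noiseless (SD = 0): a noiseless channel departs from its
#: baseline exactly at the event, whereas the zero-phase filter pre-smears
#: the onset by tens of milliseconds
NOISELESS_ONSET_THRESHOLD = 1e-4


class CopPath(NamedTuple):
    """Filtered COP trajectory: point ``i`` is ``(ml[i], ap[i])`` in cm."""

    ml: TimeSeries
    ap: TimeSeries

    def point(self, t: float) -> np.ndarray:
        return np.array([self.ml.value_at(t), self.ap.value_at(t)])


class GeoEvent(NamedTuple):
    """A geometric detection: event time, attained distance (cm) and a
    degeneracy flag (all candidate distances ~0, earliest sample used)."""

    time: float
    distance: float
    degenerate: bool = False


def first_sustained_crossing(
    x: TimeSeries,
    start: float,
    baseline_mean: float,
    threshold: float,
    sustained_s: float,
    confirm_mult: float | None = DEFAULT_CONFIRM_MULT,
) -> float:
    """Time of the first qualifying threshold crossing at or after ``start``.

    A crossing qualifies when the absolute deviation from
    ``baseline_mean`` exceeds ``threshold`` and (a) keeps exceeding it for
    ``sustained_s`` seconds, and (b) — when ``confirm_mult`` is given —
    reaches ``confirm_mult * threshold`` before first dropping back below
    the threshold.  The returned time is the crossing sample itself.

    Raises :class:`DetectionError` when no such crossing exists.
    """
    dev = np.abs(x.values - baseline_mean)
    above = dev > threshold
    i0 = max(0, int(np.ceil((start - x.t0) * x.fs - 1e-9)))
    n_sustain = max(1, int(np.ceil(sustained_s * x.fs - 1e-9)))

    # runs of consecutive samples above threshold, from i0 on
    a = above[i0:]
    if not a.any():
        raise DetectionError(
            f"no crossing of threshold {threshold:.6g} after t={start:.3f} s"
        )
    padded = np.concatenate([[False], a, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]  # half-open [start, stop)
    for s, e in zip(starts, stops):
        if e - s < n_sustain:
            continue
        if confirm_mult is not None and dev[i0 + s : i0 + e].max() < confirm_mult * threshold:
            continue
        return x.time_at(i0 + int(s))
    raise DetectionError(
        f"no sustained crossing of threshold {threshold:.6g} after t={start:.3f} s"
    )


def detect_onset_cop(
    cop_ml: TimeSeries,
    quiet_window: tuple[float, float],
    sustained_s: float = DEFAULT_SUSTAINED_S,
    abs_threshold: float | None = None,
    confirm_mult: float | None = DEFAULT_CONFIRM_MULT,
) -> float:
    """APA onset from the filtered COP ML displacement.

    The threshold is twice the SD of the signal over the quiet-standing
    window (deviations measured from the quiet-window mean); the crossing
    must hold for ``sustained_s`` and reach ``confirm_mult`` times the
    threshold to reject baseline excursions.  With a noiseless baseline
    (SD = 0) an ``abs_threshold`` must be supplied, otherwise a
    :class:`DegenerateBaselineError` is raised.
    """
    quiet = cop_ml.slice(*quiet_window)
    mean = float(np.mean(quiet.values))
    sd = float(np.std(quiet.values))
    scale = float(np.max(np.abs(cop_ml.values - mean)))
    if abs_threshold is not None:
        threshold = abs_threshold
    elif sd <= 1e-9 * max(scale, 1e-30):
        # an exactly (or numerically) quiet baseline carries no noise level
        raise DegenerateBaselineError(
            "quiet-standing SD is zero; supply an absolute onset threshold"
        )
    else:
        threshold = 2.0 * sd
    return first_sustained_crossing(
        cop_ml, quiet_window[1], mean, threshold, sustained_s, confirm_mult
    )


def detect_trailing_toe_off(fz1: TimeSeries, noise_floor: float) -> float:
    """Trailing-limb toe-off: last instant plate 1 is loaded.

    Returns the time of the last sample with ``fz1 > noise_floor``.
    Raises :class:`DetectionError` when the force never drops below the
    floor (the record would end with the foot still on the plate).
    """
    above = fz1.values > noise_floor
    if not above.any():
        raise DetectionError("fz1 never rises above the noise floor")
    last = int(np.flatnonzero(above)[-1])
    if last == len(fz1) - 1:
        raise DetectionError(
            "fz1 never drops below the noise floor: trailing foot never lifts"
        )
    return fz1.time_at(last)


def _line_distances(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Perpendicular distances of ``points`` (n x 2) from the line p0-p1."""
    d = p1 - p0
    norm = float(np.hypot(*d))
    if norm < 1e-12:
        raise DegenerateLineError(
            f"line anchors coincide at {tuple(p0)}; reference line undefined"
        )
    rel = points - p0
    return np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0]) / norm


def _window_indices(ts: TimeSeries, t_lo: float, t_hi: float) -> tuple[int, int]:
    """Sample indices strictly inside the open interval (t_lo, t_hi)."""
    i0 = int(np.floor((t_lo - ts.t0) * ts.fs + 1e-9)) + 1
    i1 = int(np.ceil((t_hi - ts.t0) * ts.fs - 1e-9))  # exclusive
    i0 = max(i0, 0)
    i1 = min(i1, len(ts))
    if i1 <= i0:
        raise DetectionError(f"empty search window ({t_lo:.3f}, {t_hi:.3f}) s")
    return i0, i1


def _max_distance_event(
    path: CopPath, t_anchor0: float, t_anchor1: float, t_lo: float, t_hi: float
) -> GeoEvent:
    p0 = path.point(t_anchor0)
    p1 = path.point(t_anchor1)
    i0, i1 = _window_indices(path.ml, t_lo, t_hi)
    pts = np.column_stack([path.ml.values[i0:i1], path.ap.values[i0:i1]])
    dist = _line_distances(pts, p0, p1)
    k = int(np.argmax(dist))  # argmax returns the earliest maximiser
    dmax = float(dist[k])
    degenerate = dmax < 1e-9
    if degenerate:
        k = 0
        log.warning(
            "COP path collinear with reference line in (%.3f, %.3f) s; "
            "earliest sample used",
            t_lo,
            t_hi,
        )
    return GeoEvent(path.ml.time_at(i0 + k), dmax, degenerate)


def detect_toe_off_cop(path: CopPath, t_onset: float, t_trailing_to: float) -> GeoEvent:
    """Leading-foot toe-off: maximal COP distance (d_1MAX) from the line
    L1 through the COP positions at APA onset and trailing toe-off,
    searched among samples strictly between those two instants."""
    if not t_onset < t_trailing_to:
        raise DetectionError(
            f"need t_onset < t_trailing_toe_off, got {t_onset} >= {t_trailing_to}"
        )
    return _max_distance_event(path, t_onset, t_trailing_to, t_onset, t_trailing_to)


def detect_heel_off_cop(path: CopPath, t_onset: float, t_toe_off: float) -> GeoEvent:
    """Leading-foot heel-off: maximal COP distance (d_2MAX) from the line
    L2 through the COP positions at APA onset and leading toe-off,
    searched among samples strictly between those instants."""
    if not t_onset < t_toe_off:
        raise DetectionError(f"need t_onset < t_toe_off, got {t_onset} >= {t_toe_off}")
    return _max_distance_event(path, t_onset, t_toe_off, t_onset, t_toe_off)


def detect_foot_contact_grf(
    fz2: TimeSeries, body_weight: float, fraction: float = 0.065
) -> float:
    """Leading-foot contact: first sample with ``fz2`` above ``fraction``
    (default 6.5%) of body weight."""
    if body_weight <= 0:
        raise SchemaError(f"body weight must be positive, got {body_weight}")
    threshold = fraction * body_weight
    idx = np.flatnonzero(fz2.values > threshold)
    if idx.size == 0:
        raise DetectionError(
            f"fz2 never exceeds the contact threshold ({threshold:.1f} N)"
        )
    return fz2.time_at(int(idx[0]))


def detect_all_fp(
    rec: ForcePlateRecording,
    cop_filter: FilterSpec | None = None,
    sustained_s: float = DEFAULT_SUSTAINED_S,
    fc_grf_fraction: float = 0.065,
    abs_onset_threshold: float | None = None,
) -> GaitEvents:
    """Run the full force-plate detection chain on one trial.

    COP channels are low-pass filtered at 10 Hz (zero phase) before the
    geometric analysis; the vertical forces are used raw.  Detector order
    follows the dependencies: onset, trailing toe-off, leading toe-off
    (L1/d_1MAX), leading heel-off (L2/d_2MAX); foot contact is
    independent.
    """
    spec = cop_filter or FilterSpec(cutoff=10.0)
    path = CopPath(
        ml=zero_phase_lowpass(rec.cop1_ml, spec),
        ap=zero_phase_lowpass(rec.cop1_ap, spec),
    )
    try:
        t_onset = detect_onset_cop(
            path.ml, rec.quiet_window, sustained_s, abs_onset_threshold
        )
    except DegenerateBaselineError:
        # noiseless record: first departure of the raw channel from baseline
        t_onset = detect_onset_cop(
            rec.cop1_ml, rec.quiet_window, sustained_s, NOISELESS_ONSET_THRESHOLD
        )
    floor = fc_grf_fraction * rec.body_weight
    t_trailing = detect_trailing_toe_off(rec.fz1, floor)
    toe = detect_toe_off_cop(path, t_onset, t_trailing)
    heel = detect_heel_off_cop(path, t_onset, toe.time)
    t_contact = detect_foot_contact_grf(rec.fz2, rec.body_weight, fc_grf_fraction)
    log.debug(
        "fp detection: onset=%.4f heel=%.4f (d2max=%.3f cm) toe=%.4f "
        "(d1max=%.3f cm) contact=%.4f trailing=%.4f",
        t_onset,
        heel.time,
        heel.distance,
        toe.time,
        toe.distance,
        t_contact,
        t_trailing,
    )
    return GaitEvents(
        apa_onset=t_onset,
        heel_off=heel.time,
        toe_off=toe.time,
        foot_contact=t_contact,
        trailing_toe_off=t_trailing,
        source=EventSource.FORCE_PLATE,
    )
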
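"""Synthetic paired recordings with known ground-truth gait events.

The generator is the test bed for every detector: it emits a force-plate
recording (COP + per-plate vertical force, 800 Hz) and an inertial
recording (trunk acceleration + shank angular velocity, 50 Hz) of the
same simulated trial, plus the ground-truth event times.

Signal construction is detector-aware by design:

* the COP path is a chain of straight chords between the programmed
  excursion waypoints, traversed with cubic-Hermite timing whose vertex
  speeds are matched so that the point-to-line distance profiles (d_1MAX,
  d_2MAX) are locally symmetric about the programmed toe-off/heel-off —
  a zero-phase filter preserves the argmax of a locally symmetric peak;
* vertical forces cross the 6.5%-body-weight level exactly at the
  programmed foot-contact / trailing-toe-off samples;
* the shank angular-velocity pulse is fitted (small deterministic root
  find) so that, *after* the 3.5 Hz zero-phase filter, it crosses
  ``H_true``·Ωpk and ``T_true``·Ωpk at the programmed heel-off and
  toe-off;
* the trunk ML acceleration is the COP ML path scaled by a coupling gain
  (the working hypothesis that lower-trunk acceleration tracks COP
  displacement during APAs, made literal) with a small lead chosen so
  the inertial onset detector at ``A_true`` agrees with the force-plate
  onset; the AP channel mixes a COP-coupled and an independent component
  to emulate multi-segmental AP motion.

All randomness is driven by the blueprint seed; the same seed reproduces
the same trial bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps

from .model import (
    DEFAULT_THRESHOLDS,
    EventSource,
    ForcePlateRecording,
    GaitEvents,
    ImuRecording,
    STANDARD_GRAVITY,
    Side,
    Task,
    TimeSeries,
)

__all__ = [
    "BlueprintError",
    "TrialBlueprint",
    "Population",
    "CohortTrial",
    "generate_trial",
    "generate_cohort",
]


class BlueprintError(ValueError):
    """A blueprint's timing or geometry is internally inconsistent."""


def _snap(x: float, fs: float) -> float:
    return round(x * fs) / fs


@dataclass(frozen=True)
class TrialBlueprint:
    """Everything needed to synthesise one paired trial.

    Durations in seconds, COP excursions in cm (ML positive toward the
    stepping side, AP positive forward), angular velocities in deg/s,
    accelerations in m/s^2.  ``true_A/H/T`` are the detector factors the
    emitted signals are aligned to; ``None`` selects the task defaults.
    """

    task: Task = Task.GAIT_INITIATION
    quiet_s: float = 10.0
    dur_imbalance: float = 0.40
    dur_unloading: float = 0.30
    dur_swing: float = 0.50
    cop_imb_ml: float = 2.17
    cop_imb_ap: float = -2.0
    cop_unl_ml: float = -9.35
    cop_unl_ap: float = -1.0
    cop_swing_ml: float = -0.3
    cop_swing_ap: float = 11.0
    trunk_gain: float = 0.09  # (m/s^2) per cm of COP displacement
    acc_ap_mix: float = 0.5
    acc_ap_extra: float = 0.0  # amplitude of the independent AP component
    omega_pk1: float = 120.0
    omega_pk2_frac: float = 0.75
    neg_lobe_frac: float = 0.35
    contact_halfspan: float = 0.10  # t_pk2 - t_contact = t_contact - t_zc
    noise_cop: float = 0.05  # cm
    noise_fz: float = 2.0  # N
    noise_acc: float = 0.01  # m/s^2
    noise_gyro: float = 1.0  # deg/s
    tilt_ap_deg: float = 4.0
    tilt_ml_deg: float = 2.0
    fs_fp: float = 800.0
    fs_imu: float = 50.0
    body_weight: float = 700.0
    grf_rate: float = 4000.0  # N/s of the load-transfer ramps
    true_A: float | None = None
    true_H: float | None = None
    true_T: float | None = None
    trailing_delay: float = 0.15
    tail_s: float = 0.6
    stepping_side: Side = Side.RIGHT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_fp < self.fs_imu:
            raise BlueprintError("fs_fp must be at least fs_imu")
        for name in ("quiet_s", "dur_imbalance", "dur_unloading", "dur_swing", "trailing_delay"):
            v = getattr(self, name)
            if v <= 0:
                raise BlueprintError(f"{name} must be positive, got {v}")
            object.__setattr__(self, name, _snap(v, self.fs_fp))
        if self.quiet_s < 3.0:
            raise BlueprintError("quiet lead-in must be at least 3 s")
        if not self.cop_imb_ml > 0:
            raise BlueprintError("imbalance ML excursion must be positive (toward stepping side)")
        if not self.cop_unl_ml < 0:
            raise BlueprintError("unloading ML excursion must be negative (toward stance side)")
        if self.cop_imb_ap > 0:
            raise BlueprintError("imbalance AP excursion must be backward (non-positive)")
        if self.trunk_gain <= 0:
            raise BlueprintError("trunk coupling gain must be positive")
        if not 0 < 2 * self.contact_halfspan < self.dur_swing + self.trailing_delay:
            raise BlueprintError("contact halfspan inconsistent with swing timing")
        if self.body_weight <= 0:
            raise BlueprintError("body weight must be positive")
        object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "stepping_side", Side(self.stepping_side))

    # -- derived ---------------------------------------------------------
    @property
    def thresholds_true(self) -> tuple[float, float, float]:
        base = DEFAULT_THRESHOLDS[self.task]
        return (
            base.A if self.true_A is None else self.true_A,
            base.H if self.true_H is None else self.true_H,
            base.T if self.true_T is None else self.true_T,
        )

    def events(self) -> GaitEvents:
        t_on = self.quiet_s
        t_ho = t_on + self.dur_imbalance
        t_to = t_ho + self.dur_unloading
        t_fc = t_to + self.dur_swing
        return GaitEvents(
            apa_onset=t_on,
            heel_off=t_ho,
            toe_off=t_to,
            foot_contact=t_fc,
            trailing_toe_off=t_fc + self.trailing_delay,
            source=EventSource.GROUND_TRUTH,
        )

    @property
    def quiet_window(self) -> tuple[float, float]:
        return (0.0, self.quiet_s - 2.0)

    @classmethod
    def default(
        cls, task: Task | str = Task.GAIT_INITIATION, pd_like: bool = False, seed: int = 0
    ) -> "TrialBlueprint":
        """Reference conditions per task; ``pd_like`` applies the
        hypometric pattern (imbalance ML scaled by 0.4, no task scaling)."""
        task = Task(task)
        if task is Task.GAIT_INITIATION:
            bp = cls(task=task, seed=seed)
        else:
            bp = cls(
                task=task,
                dur_imbalance=0.48,
                dur_unloading=0.36,
                dur_swing=0.64,
                cop_imb_ml=2.48,
                cop_unl_ml=-9.55,
                seed=seed,
            )
        if pd_like:
            # hypometric imbalance, identical in both tasks (no scaling)
            bp = replace(bp, cop_imb_ml=0.4 * 2.17)
        return bp

    def noiseless(self) -> "TrialBlueprint":
        return replace(
            self,
            noise_cop=0.0,
            noise_fz=0.0,
            noise_acc=0.0,
            noise_gyro=0.0,
            tilt_ap_deg=0.0,
            tilt_ml_deg=0.0,
            acc_ap_extra=0.0,
        )


# ---------------------------------------------------------------------------
# COP path: straight chords, Hermite timing, symmetric distance vertices


def _hermite(u: np.ndarray, s0: float, s1: float) -> np.ndarray:
    u2, u3 = u * u, u * u * u
    return (u3 - 2 * u2 + u) * s0 + (-2 * u3 + 3 * u2) + (u3 - u2) * s1


def _perp_unit(v: np.ndarray) -> np.ndarray:
    n = np.array([-v[1], v[0]])
    return n / np.hypot(*n)


def _build_cop_path(bp: TrialBlueprint) -> Callable[[np.ndarray], np.ndarray]:
    ev = bp.events()
    p0 = np.zeros(2)
    p1 = p0 + np.array([bp.cop_imb_ml, bp.cop_imb_ap])
    p2 = p1 + np.array([bp.cop_unl_ml, bp.cop_unl_ap])
    p3 = p2 + np.array([bp.cop_swing_ml, bp.cop_swing_ap])
    pts = [p0, p1, p2, p3]
    knots = [ev.apa_onset, ev.heel_off, ev.toe_off, ev.trailing_toe_off]
    chords = [pts[i + 1] - pts[i] for i in range(3)]
    lens = [float(np.hypot(*c)) for c in chords]
    if min(lens) < 1e-9:
        raise BlueprintError("degenerate COP waypoints (zero-length chord)")
    units = [c / l for c, l in zip(chords, lens)]
    durs = [knots[i + 1] - knots[i] for i in range(3)]

    n_l2 = _perp_unit(p2 - p0)  # reference line of the heel-off vertex
    n_l1 = _perp_unit(p3 - p0)  # reference line of the toe-off vertex
    a1 = abs(float(n_l2 @ units[0]))
    a2 = abs(float(n_l2 @ units[1]))
    b2 = abs(float(n_l1 @ units[1]))
    b3 = abs(float(n_l1 @ units[2]))
    if min(a1, a2, b2, b3) < 1e-6:
        raise BlueprintError("COP geometry leaves a reference line tangent to the path")

    # vertex speeds matched so the distance-to-line profile is a locally
    # symmetric peak at heel-off and toe-off; the free end speeds are
    # capped so every normalized slope stays in the monotone region
    v_start1 = 1.5 * lens[0] / durs[0]
    v_end1 = min(1.2 * lens[0] / durs[0], 2.8 * lens[1] / durs[1] * a2 / a1)
    v_start2 = v_end1 * a1 / a2
    v_end2 = min(1.0 * lens[1] / durs[1], 2.8 * lens[2] / durs[2] * b3 / b2)
    v_start3 = v_end2 * b2 / b3
    v_end3 = 0.0
    speeds = [(v_start1, v_end1), (v_start2, v_end2), (v_start3, v_end3)]
    sigmas = []
    for (va, vb), L, D in zip(speeds, lens, durs):
        s0, s1 = va * D / L, vb * D / L
        if not (0 <= s0 <= 3 and 0 <= s1 <= 3):
            raise BlueprintError(
                "COP excursion geometry incompatible with monotone timing "
                f"(normalized slopes {s0:.2f}, {s1:.2f} outside [0, 3])"
            )
        sigmas.append((s0, s1))

    def cop(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.empty((t.size, 2))
        out[t < knots[0]] = p0
        out[t >= knots[3]] = p3
        for i in range(3):
            m = (t >= knots[i]) & (t < knots[i + 1])
            if not m.any():
                continue
            u = (t[m] - knots[i]) / durs[i]
            s = _hermite(u, *sigmas[i])
            out[m] = pts[i] + np.outer(s * lens[i], units[i])
        return out

    return cop


# ---------------------------------------------------------------------------
# vertical forces


def _build_fz(bp: TrialBlueprint) -> tuple[Callable, Callable]:
    ev = bp.events()
    w = bp.body_weight
    thr = 0.065 * w
    r = bp.grf_rate
    half = 0.5 * r / bp.fs_fp  # half-sample margin at the crossing sample
    a2 = ev.foot_contact - (thr + half) / r
    a1 = ev.trailing_toe_off - (w - thr - half) / r

    def fz2(t: np.ndarray) -> np.ndarray:
        return np.clip(r * (np.asarray(t) - a2), 0.0, 0.55 * w)

    def fz1(t: np.ndarray) -> np.ndarray:
        return w - np.clip(r * (np.asarray(t) - a1), 0.0, w)

    return fz1, fz2


# ---------------------------------------------------------------------------
# filtered-noise SD ratio and onset lead


@lru_cache(maxsize=None)
def _filtfilt_sd_ratio(fs: float, cutoff: float, order: int = 4) -> float:
    """SD of zero-phase-filtered unit white noise (digital response)."""
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=16384, fs=fs)
    return float(np.sqrt(np.mean(np.abs(h) ** 4)))


def _sampled_filtered(fun: Callable, fs: float, t_end: float, cutoff: float) -> np.ndarray:
    t = np.arange(int(round(t_end * fs))) / fs
    sos = sps.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, fun(t), padtype="even", padlen=15)


#: decay constant of the trunk-over-COP lead: the lead is full at APA
#: onset and essentially gone by heel-off, so event-instant amplitudes
#: are unaffected
ONSET_LEAD_DECAY_S = 0.15


def _warped_time(t: np.ndarray, t_on: float, lam: float) -> np.ndarray:
    """Time axis of the trunk channel: leads the COP by ``lam`` at the
    APA onset, decaying exponentially afterwards (monotone for
    ``lam`` < decay constant)."""
    t = np.asarray(t, dtype=float)
    decay = np.where(t <= t_on, 1.0, np.exp(-(t - t_on) / ONSET_LEAD_DECAY_S))
    return t + lam * decay


def _compute_onset_lead(bp: TrialBlueprint, cop: Callable, t_end: float) -> float:
    """Lead of the trunk ML channel over the COP ML shape at onset.

    Chosen so that the *expected detected* inertial onset (crossing of
    ``A_true``·SD on the filtered trunk ML channel) coincides with the
    force-plate onset (crossing of 2·SD on the filtered COP ML channel).
    The inertial expectation is the median over a small Monte-Carlo of
    the actual detector on noisy realisations: the first-crossing time
    of a threshold near the noise floor is biased and left-skewed in a
    way a noiseless template cannot capture, and the median is the
    L1-optimal centre for a mean-absolute-error calibration objective.
    Zero for noiseless blueprints, where both detectors fall back to the
    raw-channel departure.
    """
    if bp.noise_acc == 0.0 or bp.noise_cop == 0.0:
        return 0.0
    from .fp_events import first_sustained_crossing
    from .model import DetectionError, TimeSeries

    a_true = bp.thresholds_true[0]
    t_on = bp.quiet_s

    cop_ml = lambda t: cop(t)[:, 0]
    y_fp = _sampled_filtered(cop_ml, bp.fs_fp, t_end, 10.0)
    thr_fp = 2.0 * bp.noise_cop * _filtfilt_sd_ratio(bp.fs_fp, 10.0)
    try:
        # same qualification rules as the detector, so brief pre-smear
        # ripples below the sustained duration are skipped identically
        t_fp = first_sustained_crossing(
            TimeSeries(0.0, bp.fs_fp, y_fp), bp.quiet_window[1], 0.0, thr_fp, 0.025
        )
    except DetectionError as exc:
        raise BlueprintError(
            "COP excursion never clears the expected onset threshold"
        ) from exc
    target = t_fp  # absolute time of the expected force-plate onset

    sos = sps.butter(4, 3.5, btype="low", fs=bp.fs_imu, output="sos")
    rng = np.random.default_rng([bp.seed, 0x0A5E])
    qw = bp.quiet_window
    lam = 0.0
    for _ in range(3):
        acc_ml = lambda t: bp.trunk_gain * cop(_warped_time(t, t_on, lam))[:, 0]
        template = _sampled_filtered(acc_ml, bp.fs_imu, t_end, 3.5)
        detected = []
        for _rep in range(48):
            noise = sps.sosfiltfilt(
                sos, rng.normal(0.0, bp.noise_acc, template.size), padtype="even", padlen=15
            )
            y = TimeSeries(0.0, bp.fs_imu, template + noise)
            quiet = y.slice(*qw).values
            try:
                t_det = first_sustained_crossing(
                    y, qw[1], float(np.mean(quiet)), a_true * float(np.std(quiet)), 0.025
                )
            except DetectionError:
                continue
            detected.append(t_det)
        if len(detected) < 12:
            raise BlueprintError(
                "trunk acceleration never clears the expected onset threshold"
            )
        err = float(np.median(detected)) - target
        if abs(err) < 1e-4:
            break
        lam = min(lam + err, 0.8 * ONSET_LEAD_DECAY_S)  # keep the warp monotone
    return lam


# ---------------------------------------------------------------------------
# shank angular velocity


def _raised_cosine(t: np.ndarray, center: float, halfwidth: float, amp: float) -> np.ndarray:
    u = (np.asarray(t) - center) / halfwidth
    out = np.zeros_like(u)
    m = np.abs(u) < 1.0
    out[m] = amp * 0.5 * (1.0 + np.cos(np.pi * u[m]))
    return out


def _asym_raised_cosine(
    t: np.ndarray, center: float, w_left: float, w_right: float, amp: float
) -> np.ndarray:
    """Raised cosine with independent rising/falling half-widths."""
    t = np.asarray(t, dtype=float)
    u = np.where(t < center, (t - center) / w_left, (t - center) / w_right)
    out = np.zeros_like(u)
    m = np.abs(u) < 1.0
    out[m] = amp * 0.5 * (1.0 + np.cos(np.pi * u[m]))
    return out


def _lobe(t: np.ndarray, t0: float, t1: float, depth: float) -> np.ndarray:
    """Negative inter-pulse lobe: smooth (C1) leading edge to minimise
    filter ringing next to the first pulse, quarter-cosine trailing edge
    with non-zero end slope for a crisp zero-crossing at ``t1``."""
    u = (np.asarray(t) - t0) / (t1 - t0)
    out = np.zeros_like(u)
    m1 = (u >= 0) & (u <= 0.6)
    out[m1] = depth * np.sin(np.pi * u[m1] / 1.2) ** 2
    m2 = (u > 0.6) & (u <= 1.0)
    out[m2] = depth * np.cos(np.pi * (u[m2] - 0.6) / 0.8)
    return out  # positive magnitude; caller subtracts


def _build_gyro(bp: TrialBlueprint, t_end: float) -> Callable[[np.ndarray], np.ndarray]:
    """Fit the swing pulse so the *filtered* signal crosses H·Ωpk and
    T·Ωpk exactly half an IMU sample before the ground-truth heel-off
    and toe-off (the first on-grid sample beyond each crossing is then
    the ground-truth sample itself)."""
    _, h_true, t_true = bp.thresholds_true
    ev = bp.events()
    fs = bp.fs_imu
    dt_half = 0.5 / fs
    t_ho_target = ev.heel_off - dt_half
    alpha = math.acos(2 * min(h_true, 1.0) - 1)
    if alpha < 1e-6:
        raise BlueprintError("H_true = 1 leaves no rising flank to cross")
    omega2 = bp.omega_pk2_frac * bp.omega_pk1
    depth = bp.neg_lobe_frac * bp.omega_pk1

    peak_mode = t_true >= 1.0
    if peak_mode:
        t_to_target = ev.toe_off - 1.2 / fs  # argmax biased to the earlier sample
        width0 = math.pi * (t_to_target - t_ho_target) / alpha
        center0 = t_to_target
    else:
        beta = math.acos(2 * t_true - 1)
        t_to_target = ev.toe_off - dt_half
        width0 = math.pi * (t_to_target - t_ho_target) / (alpha + beta)
        center0 = t_ho_target + width0 * alpha / math.pi

    sos = sps.butter(4, 3.5, btype="low", fs=fs, output="sos")
    grid = np.arange(int(round(t_end * fs))) / fs
    i_on = int(round(bp.quiet_s * fs))

    def make_builder(shift: float):
        """Lobe/second-pulse layout with the contact pair shifted by
        ``shift`` (compensates the filter's displacement of the measured
        zero-crossing/second-peak midpoint)."""
        t_zc = ev.foot_contact - bp.contact_halfspan + shift
        t_pk2 = ev.foot_contact + bp.contact_halfspan + shift
        # keep the lobe clear of the toe-off landmark (the peak itself in
        # the T=1 regime); cap its width at 0.30 s so it stays within the
        # filter passband
        # start the lobe right after the toe-off landmark: a flat gap
        # between pulse tail and lobe rings when filtered, and the ring
        # can masquerade as a peak
        lobe0 = max(ev.toe_off + (0.12 if peak_mode else 0.02), t_zc - 0.30)
        if t_zc - lobe0 < 0.12:
            raise BlueprintError("swing too short for the inter-pulse negative lobe")

        def build(center: float, width: float) -> Callable[[np.ndarray], np.ndarray]:
            # in the T=1 regime the falling flank carries no crossing, so
            # it is kept short and fixed to decouple the pulse from the lobe
            w_fall = min(width, 0.12) if peak_mode else width
            # deepen the lobe by whatever the first pulse's tail adds over
            # the lobe window, so the dip (hence the zero-crossing) survives
            tail = np.linspace(lobe0, t_zc, 33)
            depth_eff = depth + min(
                float(np.max(_asym_raised_cosine(tail, center, width, w_fall, bp.omega_pk1))),
                0.3 * bp.omega_pk1,
            )

            def gyro(t: np.ndarray) -> np.ndarray:
                t = np.asarray(t, dtype=float)
                return (
                    _asym_raised_cosine(t, center, width, w_fall, bp.omega_pk1)
                    - _lobe(t, lobe0, t_zc, depth_eff)
                    + _raised_cosine(t, t_pk2, bp.contact_halfspan, omega2)
                )

            return gyro

        return build, t_zc

    shift = 0.0
    center, width = center0, width0
    for _outer in range(5):
        build, t_zc = make_builder(shift)
        for _ in range(40):
            g = build(center, width)(grid)
            gf = sps.sosfiltfilt(sos, g, padtype="even", padlen=15)
            m = i_on + int(np.argmax(gf[i_on : i_on + int((t_zc - bp.quiet_s) * fs)]))
            omega_f = float(gf[m])

            k = np.flatnonzero(gf[i_on : m + 1] > h_true * omega_f)
            if k.size == 0 or k[0] == 0:
                raise BlueprintError("gyro pulse fit lost its rising flank")
            j = i_on + int(k[0])
            frac = (h_true * omega_f - gf[j - 1]) / (gf[j] - gf[j - 1])
            t_h = (j - 1 + frac) / fs

            if peak_mode:
                # quadratic-interpolated peak time
                y0, y1, y2 = gf[m - 1], gf[m], gf[m + 1]
                denom = y0 - 2 * y1 + y2
                off = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
                t_t = (m + off) / fs
            else:
                k = np.flatnonzero(gf[m:] < t_true * omega_f)
                if k.size == 0:
                    raise BlueprintError("gyro pulse fit lost its falling flank")
                j = m + int(k[0])
                frac = (t_true * omega_f - gf[j - 1]) / (gf[j] - gf[j - 1])
                t_t = (j - 1 + frac) / fs

            err_h = t_ho_target - t_h
            err_t = t_to_target - t_t
            if abs(err_h) < 1e-5 and abs(err_t) < 1e-5:
                break
            width *= float(np.clip((t_to_target - t_ho_target) / (t_t - t_h), 0.5, 2.0))
            width = max(width, 0.05)
            center += 0.5 * (err_h + err_t)
        if abs(err_h) > 5e-3 or abs(err_t) > 5e-3:
            raise BlueprintError(
                "requested heel-off/toe-off crossing times are infeasible at the "
                "3.5 Hz bandwidth (unloading phase too short for the H/T levels)"
            )

        g = build(center, width)(grid)
        gf = sps.sosfiltfilt(sos, g, padtype="even", padlen=15)
        err_c = ev.foot_contact - _measure_contact(gf, fs, i_on)
        if abs(err_c) < 2e-3:
            break
        shift += err_c

    if center - width < bp.quiet_s + 0.02:
        raise BlueprintError("fitted gyro pulse would start before the APA onset")
    return build(center, width)


def _measure_contact(gf: np.ndarray, fs: float, i_on: int) -> float:
    """Foot-contact midpoint exactly as the detector measures it."""
    seg = gf[i_on:]
    floor = 0.10 * float(np.max(np.abs(seg)))
    peaks, _ = sps.find_peaks(seg, prominence=floor, height=floor)
    if peaks.size < 2:
        raise BlueprintError("gyro construction lost its second peak")
    p1, p2 = int(peaks[0]), int(peaks[1])
    sgn = np.signbit(seg[: p2 + 1])
    flips = np.flatnonzero(sgn[1:] != sgn[:-1])
    flips = flips[flips >= p1]
    if flips.size == 0:
        raise BlueprintError("gyro construction lost its zero-crossing")
    k = int(flips[-1])
    v0, v1 = float(seg[k]), float(seg[k + 1])
    frac = 0.0 if v1 == v0 else -v0 / (v1 - v0)
    t_zc = (i_on + k + frac) / fs
    return 0.5 * (t_zc + (i_on + p2) / fs)


# ---------------------------------------------------------------------------
# trial assembly


def _tilt_matrix(ap_deg: float, ml_deg: float) -> np.ndarray:
    """Sensor-from-world rotation for a pitched/rolled trunk sensor,
    axes ordered (v, ml, ap)."""
    th, ph = math.radians(ap_deg), math.radians(ml_deg)
    r_pitch = np.array(
        [
            [math.cos(th), 0.0, math.sin(th)],
            [0.0, 1.0, 0.0],
            [-math.sin(th), 0.0, math.cos(th)],
        ]
    )
    r_roll = np.array(
        [
            [math.cos(ph), math.sin(ph), 0.0],
            [-math.sin(ph), math.cos(ph), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    return (r_pitch @ r_roll).T


def generate_trial(
    bp: TrialBlueprint,
) -> tuple[ForcePlateRecording, ImuRecording, GaitEvents]:
    """Synthesise one paired trial from its blueprint.

    Deterministic under ``bp.seed``.  Raises :class:`BlueprintError` on
    inconsistent timing or geometry.
    """
    ev = bp.events()
    t_end = ev.trailing_toe_off + bp.tail_s
    rng = np.random.default_rng(bp.seed)

    cop = _build_cop_path(bp)
    fz1_fun, fz2_fun = _build_fz(bp)
    gyro_fun = _build_gyro(bp, t_end)
    lead = _compute_onset_lead(bp, cop, t_end)

    # force plate, 800 Hz
    t_fp = np.arange(int(round(t_end * bp.fs_fp))) / bp.fs_fp
    cop_xy = cop(t_fp)
    cop_ml = cop_xy[:, 0] + rng.normal(0.0, bp.noise_cop, t_fp.size)
    cop_ap = cop_xy[:, 1] + rng.normal(0.0, bp.noise_cop, t_fp.size)
    fz1 = fz1_fun(t_fp) + rng.normal(0.0, bp.noise_fz, t_fp.size)
    fz2 = fz2_fun(t_fp) + rng.normal(0.0, bp.noise_fz, t_fp.size)

    # inertial, 50 Hz
    t_imu = np.arange(int(round(t_end * bp.fs_imu))) / bp.fs_imu
    cop_led = cop(_warped_time(t_imu, bp.quiet_s, lead))
    acc_ml_w = bp.trunk_gain * cop_led[:, 0]
    ap_bump = np.zeros_like(t_imu)
    if bp.acc_ap_extra != 0.0:
        u = (t_imu - ev.apa_onset) / (ev.toe_off - ev.apa_onset)
        m = (u >= 0) & (u <= 1)
        ap_bump[m] = bp.acc_ap_extra * 0.5 * (1 - np.cos(2 * np.pi * u[m]))
    acc_ap_w = bp.trunk_gain * bp.acc_ap_mix * cop_led[:, 1] + ap_bump
    acc_v_w = np.zeros_like(t_imu)

    world = np.vstack([acc_v_w + STANDARD_GRAVITY, acc_ml_w, acc_ap_w])
    sensor = _tilt_matrix(bp.tilt_ap_deg, bp.tilt_ml_deg) @ world
    sensor += rng.normal(0.0, bp.noise_acc, sensor.shape)
    gyro = gyro_fun(t_imu) + rng.normal(0.0, bp.noise_gyro, t_imu.size)

    fp_rec = ForcePlateRecording(
        cop1_ml=TimeSeries(0.0, bp.fs_fp, cop_ml, "cm"),
        cop1_ap=TimeSeries(0.0, bp.fs_fp, cop_ap, "cm"),
        fz1=TimeSeries(0.0, bp.fs_fp, fz1, "N"),
        fz2=TimeSeries(0.0, bp.fs_fp, fz2, "N"),
        body_weight=bp.body_weight,
        quiet_window=bp.quiet_window,
        task=bp.task,
        stepping_side=bp.stepping_side,
    )
    imu_rec = ImuRecording(
        trunk_acc_v=TimeSeries(0.0, bp.fs_imu, sensor[0], "m/s^2"),
        trunk_acc_ml=TimeSeries(0.0, bp.fs_imu, sensor[1], "m/s^2"),
        trunk_acc_ap=TimeSeries(0.0, bp.fs_imu, sensor[2], "m/s^2"),
        shank_gyro_ml=TimeSeries(0.0, bp.fs_imu, gyro, "deg/s"),
        quiet_window=bp.quiet_window,
        task=bp.task,
        stepping_side=bp.stepping_side,
    )
    return fp_rec, imu_rec, ev


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class Population:
    """Distribution of blueprints across subjects and trials.

    Means follow the reference conditions; between-subject and
    within-subject (trial) SDs emulate the spread of the corresponding
    human measurements.  ``pd_like`` applies the hypometric pattern:
    imbalance ML scaled by ``pd_imb_scale`` and no task scaling of the
    imbalance excursion.
    """

    pd_like: bool = False
    imb_ml_mean: float = 2.17
    imb_ml_sd_subject: float = 0.55
    imb_ml_sd_trial: float = 0.25
    step_scale_imb: float = 2.48 / 2.17
    unl_ml_mean: float = -9.35
    unl_ml_sd_subject: float = 1.3
    unl_ml_sd_trial: float = 0.5
    step_scale_unl: float = 9.55 / 9.35
    dur_sd_subject: tuple[float, float, float] = (0.05, 0.03, 0.05)
    dur_sd_trial: tuple[float, float, float] = (0.02, 0.015, 0.03)
    #: phase-duration floors (imbalance, unloading, swing); the unloading
    #: floor keeps the gyro-pulse crossing span realisable at 3.5 Hz
    dur_floor: tuple[float, float, float] = (0.20, 0.26, 0.40)
    tilt_ap_mean: float = 4.0
    tilt_ap_sd: float = 1.5
    tilt_ml_mean: float = 2.0
    tilt_ml_sd: float = 1.0
    acc_ap_extra_sd: float = 0.12
    body_weight_mean: float = 700.0
    body_weight_sd: float = 90.0
    pd_imb_scale: float = 0.4
    true_A: float | None = None
    true_H: float | None = None
    true_T: float | None = None

    @classmethod
    def healthy(cls) -> "Population":
        return cls()

    @classmethod
    def parkinsonian(cls) -> "Population":
        return cls(pd_like=True, step_scale_imb=1.0)

    @classmethod
    def calibration_reference(
        cls, true_A: float, true_H: float, true_T: float
    ) -> "Population":
        """Conditions for threshold-calibration experiments: excursion
        spread tightened so every trial's onset signal-to-noise ratio
        stays in the band where adjacent A factors are distinguishable."""
        return cls(
            true_A=true_A,
            true_H=true_H,
            true_T=true_T,
            imb_ml_sd_subject=0.35,
            imb_ml_sd_trial=0.15,
        )


@dataclass(frozen=True)
class CohortTrial:
    """One generated paired trial within a cohort."""

    subject: str
    task: Task
    trial: int
    blueprint: TrialBlueprint
    fp: ForcePlateRecording
    imu: ImuRecording
    truth: GaitEvents


def _trunc(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_cohort(
    n_subjects: int,
    trials_per_subject: int = 3,
    population: Population | None = None,
    seed: int = 0,
    tasks: Sequence[Task | str] = (Task.GAIT_INITIATION, Task.STEP_CLIMBING),
    out_dir: str | Path | None = None,
) -> list[CohortTrial]:
    """Draw per-subject blueprints and synthesise all paired trials.

    With ``out_dir`` set, every recording, ground-truth event file and a
    ``manifest.csv`` are written there (same formats the detectors
    consume); the trials are returned either way.  Deterministic under
    ``seed``.
    """
    if n_subjects < 1 or trials_per_subject < 1:
        raise BlueprintError("need at least one subject and one trial")
    pop = population or Population.healthy()
    tasks = [Task(t) for t in tasks]
    rng = np.random.default_rng(seed)
    trials: list[CohortTrial] = []

    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        imb_scale = pop.pd_imb_scale if pop.pd_like else 1.0
        imb_base = _trunc(rng, pop.imb_ml_mean * imb_scale, pop.imb_ml_sd_subject * imb_scale, 0.3 * pop.imb_ml_mean * imb_scale, 2.0 * pop.imb_ml_mean)
        unl_base = _trunc(rng, pop.unl_ml_mean, pop.unl_ml_sd_subject, -13.0, -5.0)
        weight = _trunc(rng, pop.body_weight_mean, pop.body_weight_sd, 450.0, 1100.0)
        tilt_ap = _trunc(rng, pop.tilt_ap_mean, pop.tilt_ap_sd, -10.0, 12.0)
        tilt_ml = _trunc(rng, pop.tilt_ml_mean, pop.tilt_ml_sd, -10.0, 12.0)
        dur_subj: dict[Task, tuple[float, float, float]] = {}
        for task in tasks:
            ref = TrialBlueprint.default(task)
            dur_subj[task] = tuple(
                _trunc(rng, m, sd, max(lo, m - 2.5 * sd), m + 2.5 * sd)
                for m, sd, lo in zip(
                    (ref.dur_imbalance, ref.dur_unloading, ref.dur_swing),
                    pop.dur_sd_subject,
                    pop.dur_floor,
                )
            )

        for task in tasks:
            ref = TrialBlueprint.default(task)
            if task is Task.STEP_CLIMBING:
                imb_mean_t = imb_base * pop.step_scale_imb
                unl_mean_t = unl_base * pop.step_scale_unl
            else:
                imb_mean_t = imb_base
                unl_mean_t = unl_base
            for k in range(trials_per_subject):
                di, du, dsw = (
                    _trunc(rng, m, sd, max(lo, m - 2.5 * sd), m + 2.5 * sd)
                    for m, sd, lo in zip(dur_subj[task], pop.dur_sd_trial, pop.dur_floor)
                )
                bp = replace(
                    ref,
                    # reaction-time dither; also de-synchronises the event
                    # phase from the coarser IMU sample grid
                    quiet_s=ref.quiet_s + int(rng.integers(0, 16)) / ref.fs_fp,
                    dur_imbalance=di,
                    dur_unloading=du,
                    dur_swing=dsw,
                    cop_imb_ml=_trunc(
                        rng, imb_mean_t, pop.imb_ml_sd_trial, 0.25 * imb_mean_t, 2.5 * imb_mean_t
                    ),
                    cop_unl_ml=_trunc(rng, unl_mean_t, pop.unl_ml_sd_trial, -14.0, -4.0),
                    body_weight=weight,
                    tilt_ap_deg=tilt_ap,
                    tilt_ml_deg=tilt_ml,
                    acc_ap_extra=float(rng.normal(0.0, pop.acc_ap_extra_sd)),
                    true_A=pop.true_A,
                    true_H=pop.true_H,
                    true_T=pop.true_T,
                    seed=int(rng.integers(2**31)),
                )
                fp, imu, truth = generate_trial(bp)
                trials.append(CohortTrial(subject, task, k + 1, bp, fp, imu, truth))

    if out_dir is not None:
        _write_cohort(trials, Path(out_dir))
    return trials


def _write_cohort(trials: list[CohortTrial], out_dir: Path) -> None:
    import pandas as pd

    from .io import write_events, write_recording

    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trials:
        stem = f"{tr.subject.lower()}_{tr.task.value.split('_')[0]}_t{tr.trial}"
        fp_file = out_dir / f"{stem}_fp.csv"
        imu_file = out_dir / f"{stem}_imu.csv"
        ev_file = out_dir / f"{stem}_truth.json"
        write_recording(tr.fp, fp_file)
        write_recording(tr.imu, imu_file)
        write_events(tr.truth, ev_file)
        rows.append(
            {
                "subject": tr.subject,
                "task": tr.task.value,
                "trial": tr.trial,
                "fp_file": fp_file.name,
                "imu_file": imu_file.name,
                "truth_file": ev_file.name,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
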
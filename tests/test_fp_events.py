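"""Force-plate event detectors against hand-built and simulated signals."""

from __future__ import annotations

import numpy as np
import pytest

from apakit.fp_events import (
    CopPath,
    detect_all_fp,
    detect_foot_contact_grf,
    detect_heel_off_cop,
    detect_onset_cop,
    detect_toe_off_cop,
    detect_trailing_toe_off,
)
from apakit.model import (
    DegenerateBaselineError,
    DegenerateLineError,
    DetectionError,
    TimeSeries,
)

FS = 800.0


def _series(values, t0=0.0, fs=FS):
    return TimeSeries(t0, fs, np.asarray(values, dtype=float))


def _brute_force_max_distance(path: CopPath, t0, t1, anchor0, anchor1):
    """Independent oracle: scan every sample strictly inside (t0, t1)."""
    p0 = path.point(anchor0)
    p1 = path.point(anchor1)
    d = p1 - p0
    norm = np.hypot(*d)
    best_i, best_d = None, -1.0
    times = path.ml.times()
    for i, t in enumerate(times):
        if not (t0 + 1e-12 < t < t1 - 1e-12):
            continue
        p = np.array([path.ml.values[i], path.ap.values[i]])
        rel = p - p0
        dist = abs(rel[0] * d[1] - rel[1] * d[0]) / norm
        if dist > best_d + 1e-15:
            best_i, best_d = i, dist
    return times[best_i], best_d


class TestOnset:
    def test_linear_scan_example(self, rng):
        """Baseline noise SD such that the threshold is 0.2 cm; a ramp
        crossing it (sustained) is found at the first crossing sample."""
        fs = FS
        n_quiet = int(9.0 * fs)
        noise = rng.normal(0.0, 0.1, n_quiet)
        noise = noise / noise.std() * 0.1 - noise.mean()  # exact SD, zero mean
        t_rest = np.arange(int(1.0 * fs)) / fs
        ramp = np.where(t_rest >= 0.4, (t_rest - 0.4) * 30.0, 0.0)
        x = _series(np.concatenate([noise, ramp]))
        onset = detect_onset_cop(x, (0.0, 9.0), sustained_s=0.025, confirm_mult=None)
        # independent linear scan for the first sample above 2*SD
        expect = 9.0 + 0.4 + 0.2 / 30.0
        idx = np.flatnonzero(np.abs(x.values) > 0.2)
        idx = idx[idx >= int(9.0 * fs)]
        assert onset == pytest.approx(idx[0] / fs, abs=1e-9)
        assert onset == pytest.approx(expect, abs=2 / fs)

    def test_constant_signal_has_no_onset(self):
        x = _series(np.zeros(int(10 * FS)))
        with pytest.raises(DegenerateBaselineError):
            detect_onset_cop(x, (0.0, 8.0))
        with pytest.raises(DetectionError):
            detect_onset_cop(x, (0.0, 8.0), abs_threshold=0.1)

    def test_confirmation_rejects_transient_noise_burst(self):
        """A short above-threshold excursion that never reaches the
        confirmation level is not an onset; the later real rise is."""
        fs = FS
        rng = np.random.default_rng(3)
        quiet = rng.normal(0.0, 0.05, int(8 * fs))
        gap = np.zeros(int(1 * fs))
        sd = np.std(np.concatenate([quiet]))
        burst = np.zeros(int(0.5 * fs))
        burst[:80] = 3.0 * sd  # 100 ms burst above 2*SD but below 10*SD
        t_rest = np.arange(int(0.5 * fs)) / fs
        rise = t_rest * 30.0
        x = _series(np.concatenate([quiet, gap, burst, rise]))
        onset = detect_onset_cop(x, (0.0, 8.0))
        assert onset >= 9.5

    def test_sign_flip_invariance(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 0.05, int(8.5 * FS)), np.linspace(0, 3, int(1.5 * FS))]
        )
        a = detect_onset_cop(_series(vals), (0.0, 8.0))
        b = detect_onset_cop(_series(-vals), (0.0, 8.0))
        assert a == b


class TestTrailingToeOff:
    def test_linear_drop_crossing(self):
        """700 N held until 2.00 s, linear drop to 45.5 N at 2.20 s: the
        last loaded sample is at 2.20 s."""
        fs = FS
        t = np.arange(int(2.5 * fs)) / fs
        fz = np.where(t < 2.0, 700.0, np.maximum(700.0 - (t - 2.0) * ((700.0 - 45.5) / 0.2), 0.0))
        out = detect_trailing_toe_off(_series(fz), noise_floor=45.5)
        assert out == pytest.approx(2.20, abs=1.01 / fs)

    def test_constant_load_is_error(self):
        with pytest.raises(DetectionError, match="never drops"):
            detect_trailing_toe_off(_series(np.full(1000, 700.0)), 45.5)

    def test_never_loaded_is_error(self):
        with pytest.raises(DetectionError, match="never rises"):
            detect_trailing_toe_off(_series(np.zeros(1000)), 45.5)


class TestGeometry:
    def _path_through(self, points, fs=100.0):
        pts = np.asarray(points, dtype=float)
        return CopPath(
            ml=TimeSeries(0.0, fs, pts[:, 0]), ap=TimeSeries(0.0, fs, pts[:, 1])
        )

    def test_toe_off_farthest_point_example(self):
        """Line through (0,0)-(4,0); a path visiting (2,3) has its
        farthest point there with d_1MAX = 3."""
        pts = [(0, 0), (0.5, 1), (1, 2), (2, 3), (3, 2), (3.5, 1), (4, 0)]
        path = self._path_through(pts)
        out = detect_toe_off_cop(path, t_onset=0.0, t_trailing_to=0.06)
        assert out.time == pytest.approx(0.03)
        assert out.distance == pytest.approx(3.0)
        assert not out.degenerate

    def test_heel_off_distance_formula_example(self):
        """Line through (0,0)-(2,3); the point (2,0) lies at 6/sqrt(13)."""
        pts = [(0, 0), (1, 0), (2, 0), (2, 1), (2, 2), (2, 3)]
        path = self._path_through(pts)
        out = detect_heel_off_cop(path, t_onset=0.0, t_toe_off=0.05)
        assert out.distance == pytest.approx(6 / np.sqrt(13))
        assert out.time == pytest.approx(0.02)

    def test_collinear_path_flagged_degenerate_earliest(self):
        pts = [(0, 0), (1, 0), (2, 0), (3, 0), (4, 0)]
        path = self._path_through(pts)
        out = detect_toe_off_cop(path, 0.0, 0.04)
        assert out.degenerate
        assert out.time == pytest.approx(0.01)  # earliest interior sample

    def test_coincident_anchors_rejected(self):
        pts = [(1, 1)] * 6
        path = self._path_through(pts)
        with pytest.raises(DegenerateLineError):
            detect_toe_off_cop(path, 0.0, 0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_smooth_paths(self, seed):
        rng = np.random.default_rng(seed)
        fs = 200.0
        t = np.arange(int(2.0 * fs)) / fs
        ml = np.cumsum(rng.normal(0, 0.1, t.size))
        ap = np.cumsum(rng.normal(0, 0.1, t.size))
        path = CopPath(TimeSeries(0.0, fs, ml), TimeSeries(0.0, fs, ap))
        out = detect_toe_off_cop(path, 0.1, 1.9)
        t_ref, d_ref = _brute_force_max_distance(path, 0.1, 1.9, 0.1, 1.9)
        assert out.time == t_ref
        assert out.distance == pytest.approx(d_ref)

    def test_rigid_motion_invariance(self, gait_trial):
        """Rotating + translating the COP path leaves the geometric
        event times and distances unchanged."""
        from apakit.fp_events import GeoEvent
        from apakit.preprocess import FilterSpec, zero_phase_lowpass

        fp, _, truth = gait_trial
        spec = FilterSpec(10.0)
        ml = zero_phase_lowpass(fp.cop1_ml, spec)
        ap = zero_phase_lowpass(fp.cop1_ap, spec)
        path = CopPath(ml, ap)
        base = detect_toe_off_cop(path, truth.apa_onset, truth.trailing_toe_off)

        th = 0.7
        c, s = np.cos(th), np.sin(th)
        ml2 = c * ml.values - s * ap.values + 11.0
        ap2 = s * ml.values + c * ap.values - 4.0
        path2 = CopPath(ml.with_values(ml2), ap.with_values(ap2))
        rot = detect_toe_off_cop(path2, truth.apa_onset, truth.trailing_toe_off)
        assert isinstance(rot, GeoEvent)
        assert rot.time == base.time
        assert rot.distance == pytest.approx(base.distance, rel=1e-9)


class TestFootContact:
    def test_threshold_is_fraction_of_body_weight(self):
        """6.5% of 700 N = 45.5 N, crossed at 1.95 s."""
        fs = FS
        t = np.arange(int(2.5 * fs)) / fs
        fz = np.where(t >= 1.95, (t - 1.95 + 1 / fs) * 3000.0 + 45.5, 0.0)
        out = detect_foot_contact_grf(_series(fz), body_weight=700.0)
        assert out == pytest.approx(1.95, abs=0.51 / fs)

    def test_zero_force_is_error(self):
        with pytest.raises(DetectionError, match="never exceeds"):
            detect_foot_contact_grf(_series(np.zeros(1000)), 700.0)


class TestDetectAll:
    def test_noiseless_trial_recovered_within_one_sample(self, gait_trial_noiseless):
        fp, _, truth = gait_trial_noiseless
        ev = detect_all_fp(fp)
        for name in ("apa_onset", "heel_off", "toe_off", "foot_contact"):
            assert abs(getattr(ev, name) - getattr(truth, name)) <= 1.0 / fp.fs + 1e-12, name
        assert abs(ev.trailing_toe_off - truth.trailing_toe_off) <= 1.0 / fp.fs + 1e-12

    @pytest.mark.parametrize("fixture", ["gait_trial", "step_trial"])
    def test_noisy_trial_tolerances(self, fixture, request):
        fp, _, truth = request.getfixturevalue(fixture)
        ev = detect_all_fp(fp)
        assert abs(ev.apa_onset - truth.apa_onset) <= 0.025
        assert abs(ev.toe_off - truth.toe_off) <= 2.0 / fp.fs
        assert abs(ev.heel_off - truth.heel_off) <= 2.0 / fp.fs
        assert abs(ev.foot_contact - truth.foot_contact) <= 1.0 / fp.fs
        assert abs(ev.trailing_toe_off - truth.trailing_toe_off) <= 1.0 / fp.fs

    def test_event_order_holds_across_cohort(self, small_cohort):
        for trial in small_cohort:
            ev = detect_all_fp(trial.fp)
            assert ev.apa_onset < ev.heel_off < ev.toe_off < ev.foot_contact
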
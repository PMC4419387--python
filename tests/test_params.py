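"""Spatio-temporal parameters and comparison statistics."""

from __future__ import annotations

import numpy as np
import pytest

from apakit.model import (
    EventSource,
    GaitEvents,
    IntegrityError,
    SchemaError,
    Task,
    TimeSeries,
)
from apakit.params import (
    average_trials,
    compare_groups,
    compute_amplitudes,
    compute_durations,
    trial_summary,
    validate_against_fp,
)


def _ev(onset, heel, toe, contact):
    return GaitEvents(onset, heel, toe, contact)


def _const_summary(subject, value, task=Task.GAIT_INITIATION, source=EventSource.IMU,
                   imb=0.4, unl=0.3, swing=0.5):
    from apakit.model import ApaParameters

    params = ApaParameters(
        dur_imbalance=imb, dur_unloading=unl, dur_apa=imb + unl, dur_swing=swing,
        dur_step=imb + unl + swing,
        amp_imbalance_ml=value, amp_imbalance_ap=-value / 2,
        amp_unloading_ml=-3 * value, amp_unloading_ap=-value,
        source=source,
    )
    from apakit.params import TrialSummary

    return TrialSummary(subject=subject, task=task, source=source, params=params)


class TestDurations:
    def test_subtraction_example(self):
        d = compute_durations(_ev(8.40, 8.80, 9.10, 9.60))
        assert d == pytest.approx(
            {
                "dur_imbalance": 0.40,
                "dur_unloading": 0.30,
                "dur_apa": 0.70,
                "dur_swing": 0.50,
                "dur_step": 1.20,
            }
        )

    def test_zero_imbalance(self):
        d = compute_durations(_ev(8.4, 8.4, 9.1, 9.6))
        assert d["dur_imbalance"] == 0.0

    @pytest.mark.parametrize("fixture", ["gait_trial", "step_trial"])
    def test_additive_identities_exact_on_detected_trials(self, fixture, request):
        from apakit.fp_events import detect_all_fp

        fp, _, _ = request.getfixturevalue(fixture)
        d = compute_durations(detect_all_fp(fp))
        assert d["dur_apa"] == d["dur_imbalance"] + d["dur_unloading"]
        assert d["dur_step"] == d["dur_apa"] + d["dur_swing"]


class TestAmplitudes:
    def _series_at(self, mapping, fs=100.0, dur=12.0):
        values = np.zeros(int(dur * fs))
        t_prev, v_prev = 0.0, 0.0
        # simple step-hold construction through the given (time, value) knots
        for tt, vv in mapping:
            values[int(tt * fs) :] = vv
        return TimeSeries(0.0, fs, values)

    def test_cop_sign_pattern_example(self):
        """COP ML 0.0 cm at onset, 2.2 at heel-off, -7.2 at toe-off:
        imbalance +2.2 cm, unloading -9.4 cm."""
        ml = self._series_at([(8.4, 0.0), (8.8, 2.2), (9.1, -7.2)])
        ap = self._series_at([(8.4, 0.0), (8.8, -2.0), (9.1, -2.5)])
        amps = compute_amplitudes(ml, ap, _ev(8.40, 8.80, 9.10, 9.60))
        assert amps["amp_imbalance_ml"] == pytest.approx(2.2)
        assert amps["amp_unloading_ml"] == pytest.approx(-9.4)
        assert amps["amp_imbalance_ap"] == pytest.approx(-2.0)
        assert amps["amp_unloading_ap"] == pytest.approx(-0.5)

    def test_flat_signal_zero_amplitudes(self):
        flat = TimeSeries(0.0, 100.0, np.full(1200, 1.23))
        amps = compute_amplitudes(flat, flat, _ev(8.4, 8.8, 9.1, 9.6))
        assert all(v == 0.0 for v in amps.values())

    def test_event_outside_record_rejected(self):
        short = TimeSeries(0.0, 100.0, np.zeros(100))
        with pytest.raises(SchemaError, match="outside"):
            compute_amplitudes(short, short, _ev(8.4, 8.8, 9.1, 9.6))


class TestAverageTrials:
    def test_mean_example(self):
        s = [_const_summary("s1", v) for v in (0.18, 0.20, 0.19)]
        avg = average_trials(s)
        assert avg.params.amp_imbalance_ml == pytest.approx(0.19)
        assert avg.params.dur_apa == avg.params.dur_imbalance + avg.params.dur_unloading

    def test_single_trial_identity(self):
        s = _const_summary("s1", 0.2)
        assert average_trials([s]).params == s.params

    def test_mixed_groups_rejected(self):
        a = _const_summary("s1", 0.2)
        b = _const_summary("s1", 0.2, task=Task.STEP_CLIMBING)
        with pytest.raises(SchemaError, match="mixed"):
            average_trials([a, b])


class TestValidateAgainstFp:
    def test_proportional_pairs_have_unit_correlation(self):
        fp = [_const_summary(f"s{i}", 0.1 * i, source=EventSource.FORCE_PLATE) for i in range(1, 8)]
        imu = [_const_summary(f"s{i}", 0.25 * i, source=EventSource.IMU) for i in range(1, 8)]
        rows = validate_against_fp(fp, imu)
        assert rows["amp_imbalance_ml"].r == pytest.approx(1.0)
        assert rows["amp_imbalance_ml"].p_value < 1e-6

    def test_independent_noise_uncorrelated_on_average(self, rng):
        rs = []
        for rep in range(20):
            fp = [_const_summary(f"s{i}", rng.normal(), source=EventSource.FORCE_PLATE) for i in range(50)]
            imu = [_const_summary(f"s{i}", rng.normal(), source=EventSource.IMU) for i in range(50)]
            rows = validate_against_fp(fp, imu)
            rs.append(rows["amp_imbalance_ml"].r)
        assert abs(np.mean(rs)) < 0.1
        assert np.mean([abs(r) for r in rs]) < 0.25

    def test_zero_variance_flagged(self):
        fp = [_const_summary(f"s{i}", 0.5, source=EventSource.FORCE_PLATE) for i in range(5)]
        imu = [_const_summary(f"s{i}", 0.1 * i, source=EventSource.IMU) for i in range(5)]
        rows = validate_against_fp(fp, imu)
        assert rows["amp_imbalance_ml"].degenerate
        assert np.isnan(rows["amp_imbalance_ml"].r)

    def test_too_few_subjects_rejected(self):
        fp = [_const_summary("s1", 0.1), _const_summary("s2", 0.2)]
        with pytest.raises(ValueError, match="3 paired"):
            validate_against_fp(fp, fp)


class TestCompareGroups:
    def test_identical_groups_null_result(self):
        a = [_const_summary(f"s{i}", 0.2) for i in range(5)]
        rep = compare_groups(a, a)
        for row in rep.rows.values():
            assert row.statistic == 0.0
            assert row.p_value == 1.0
            assert not row.significant

    def test_identical_paired_groups_null_result(self):
        a = [_const_summary(f"s{i}", 0.2 + 0.01 * i) for i in range(5)]
        rep = compare_groups(a, a, paired=True)
        for row in rep.rows.values():
            assert row.statistic == 0.0
            assert row.p_value == 1.0

    def test_paired_matches_by_subject_not_order(self, rng):
        a = [_const_summary(f"s{i}", 0.2 + 0.05 * i) for i in range(6)]
        b = [_const_summary(f"s{i}", 0.25 + 0.05 * i) for i in range(6)]
        rep1 = compare_groups(a, b, paired=True)
        rep2 = compare_groups(a, list(reversed(b)), paired=True)
        assert rep1.rows["amp_imbalance_ml"].p_value == pytest.approx(
            rep2.rows["amp_imbalance_ml"].p_value
        )

    def test_small_groups_rejected(self):
        a = [_const_summary("s1", 0.2)]
        with pytest.raises(ValueError):
            compare_groups(a, a)

    def test_separated_groups_significant(self, rng):
        a = [_const_summary(f"s{i}", 0.20 + 0.01 * rng.normal()) for i in range(8)]
        b = [_const_summary(f"t{i}", 0.08 + 0.01 * rng.normal()) for i in range(8)]
        rep = compare_groups(a, b)
        assert rep.rows["amp_imbalance_ml"].significant


class TestTrialSummaryPipeline:
    def test_source_agnostic_amplitude_path(self, gait_trial):
        """The same code path serves COP (cm) and trunk acceleration
        (m/s^2): swapping the input series only changes units/scale."""
        from apakit.fp_events import detect_all_fp
        from apakit.preprocess import FilterSpec, zero_phase_lowpass

        fp, imu, _ = gait_trial
        ev = detect_all_fp(fp)
        spec = FilterSpec(10.0)
        ml = zero_phase_lowpass(fp.cop1_ml, spec)
        ap = zero_phase_lowpass(fp.cop1_ap, spec)
        s_fp = trial_summary("s1", fp.task, ev, ml, ap)
        assert s_fp.params.amp_imbalance_ml > 0
        assert s_fp.params.amp_unloading_ml < 0

        from apakit.imu_events import detect_all_imu, preprocess_imu
        from apakit.model import DEFAULT_THRESHOLDS

        ev_imu = detect_all_imu(imu, DEFAULT_THRESHOLDS[imu.task])
        _, aml, aap, _ = preprocess_imu(imu)
        s_imu = trial_summary("s1", imu.task, ev_imu, aml, aap)
        assert s_imu.params.amp_imbalance_ml > 0
        assert s_imu.params.amp_unloading_ml < 0
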
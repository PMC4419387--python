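"""Spatio-temporal APA parameters and the study's comparison statistics.

From one trial's events the five phase durations are derived
(imbalance, unloading, APA = imbalance + unloading, swing,
step = APA + swing) together with four amplitudes: the signal change
over the imbalance and unloading phases in the ML and AP directions.
Amplitudes are computed identically for both sources — COP displacement
(cm) from the force plate and trunk acceleration (m/s^2) from the
wearable — by sampling the filtered signal at the nearest sample to each
event time.

The statistics mirror the study design: per-subject averaging over the
three repetitions, Pearson correlation between paired force-plate and
inertial parameters (concurrent validity), and Student's t-tests —
unpaired between groups, paired between tasks.  Normality
(Shapiro-Wilk) and homoscedasticity (Bartlett) screens are run and
logged but never switch the test family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import (
    ApaParameters,
    EventSource,
    GaitEvents,
    IntegrityError,
    SchemaError,
    Task,
    TimeSeries,
)

__all__ = [
    "TrialSummary",
    "CorrelationRow",
    "ComparisonRow",
    "GroupReport",
    "compute_durations",
    "compute_amplitudes",
    "trial_summary",
    "average_trials",
    "validate_against_fp",
    "compare_groups",
    "PARAMETER_NAMES",
]

log = logging.getLogger("apakit.params")

PARAMETER_NAMES = (
    "dur_imbalance",
    "dur_unloading",
    "dur_apa",
    "dur_swing",
    "dur_step",
    "amp_imbalance_ml",
    "amp_imbalance_ap",
    "amp_unloading_ml",
    "amp_unloading_ap",
)


@dataclass(frozen=True)
class TrialSummary:
    """Parameters of one trial (or of a subject's trial average)."""

    subject: str
    task: Task
    source: EventSource
    params: ApaParameters

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "source", EventSource(self.source))


def compute_durations(events: GaitEvents) -> dict[str, float]:
    """The five phase durations (seconds) from ordered events.

    ``dur_apa = dur_imbalance + dur_unloading`` and ``dur_step = dur_apa
    + dur_swing`` hold exactly by construction.
    """
    imb = events.heel_off - events.apa_onset
    unl = events.toe_off - events.heel_off
    swing = events.foot_contact - events.toe_off
    if min(imb, unl, swing) < -1e-12:
        raise IntegrityError(f"events out of order: {events}")
    apa = imb + unl
    return {
        "dur_imbalance": imb,
        "dur_unloading": unl,
        "dur_apa": apa,
        "dur_swing": swing,
        "dur_step": apa + swing,
    }


def _value_at_event(ts: TimeSeries, t: float) -> float:
    if not (ts.t0 - 0.5 / ts.fs <= t <= ts.t0 + (len(ts) - 0.5) / ts.fs):
        raise SchemaError(f"event time {t:.3f} s outside the recorded range")
    return ts.value_at(t)


def compute_amplitudes(
    signal_ml: TimeSeries, signal_ap: TimeSeries, events: GaitEvents
) -> dict[str, float]:
    """Imbalance and unloading amplitudes in ML and AP.

    Imbalance amplitude is the signal at heel-off minus the signal at
    APA onset; unloading amplitude the signal at toe-off minus at
    heel-off, each taken at the nearest sample.  With ML positive toward
    the stepping side the imbalance ML amplitude is positive and the
    unloading ML amplitude negative.
    """
    out = {}
    for axis, ts in (("ml", signal_ml), ("ap", signal_ap)):
        v_on = _value_at_event(ts, events.apa_onset)
        v_ho = _value_at_event(ts, events.heel_off)
        v_to = _value_at_event(ts, events.toe_off)
        out[f"amp_imbalance_{axis}"] = v_ho - v_on
        out[f"amp_unloading_{axis}"] = v_to - v_ho
    return out


def trial_summary(
    subject: str,
    task: Task | str,
    events: GaitEvents,
    signal_ml: TimeSeries,
    signal_ap: TimeSeries,
) -> TrialSummary:
    """Durations + amplitudes of one trial as a :class:`TrialSummary`."""
    params = ApaParameters(
        **compute_durations(events),
        **compute_amplitudes(signal_ml, signal_ap, events),
        source=events.source,
    )
    return TrialSummary(subject=subject, task=Task(task), source=events.source, params=params)


def average_trials(summaries: list[TrialSummary]) -> TrialSummary:
    """Arithmetic mean of every parameter over one subject's trials.

    All summaries must share subject, task and source (the study
    averages the three repetitions of each test per subject).
    """
    if not summaries:
        raise ValueError("no trials to average")
    keys = {(s.subject, s.task, s.source) for s in summaries}
    if len(keys) > 1:
        raise SchemaError(f"cannot average across mixed groups: {sorted(map(str, keys))}")
    mean = {
        name: float(np.mean([getattr(s.params, name) for s in summaries]))
        for name in PARAMETER_NAMES
    }
    # re-impose the additive identities against accumulated round-off
    mean["dur_apa"] = mean["dur_imbalance"] + mean["dur_unloading"]
    mean["dur_step"] = mean["dur_apa"] + mean["dur_swing"]
    first = summaries[0]
    return TrialSummary(
        subject=first.subject,
        task=first.task,
        source=first.source,
        params=ApaParameters(**mean, source=first.source),
    )


@dataclass(frozen=True)
class CorrelationRow:
    """Pearson correlation between paired measurements of one parameter."""

    parameter: str
    r: float
    p_value: float
    n: int
    degenerate: bool = False  # zero variance in one member


@dataclass(frozen=True)
class ComparisonRow:
    """Two-group comparison of one parameter: means ± SD per group with
    the test statistic and p-value."""

    parameter: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    paired: bool

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class GroupReport:
    rows: dict[str, ComparisonRow]


def _match_by_subject(
    a: list[TrialSummary], b: list[TrialSummary]
) -> list[tuple[TrialSummary, TrialSummary]]:
    bm = {s.subject: s for s in b}
    matched = [(s, bm[s.subject]) for s in a if s.subject in bm]
    if len(matched) < len(a) or len(b) != len(bm):
        log.warning("subject sets differ; %d matched pairs used", len(matched))
    return matched


def validate_against_fp(
    fp_summaries: list[TrialSummary],
    imu_summaries: list[TrialSummary],
    parameters: tuple[str, ...] = PARAMETER_NAMES,
) -> dict[str, CorrelationRow]:
    """Concurrent validity: Pearson r (and p) per parameter between
    per-subject force-plate and inertial summaries, matched by subject."""
    matched = _match_by_subject(fp_summaries, imu_summaries)
    if len(matched) < 3:
        raise ValueError(f"need at least 3 paired subjects, got {len(matched)}")
    rows: dict[str, CorrelationRow] = {}
    for name in parameters:
        x = np.array([getattr(f.params, name) for f, _ in matched])
        y = np.array([getattr(i.params, name) for _, i in matched])
        tiny = 1e-12
        if np.std(x) <= tiny * (abs(np.mean(x)) + 1) or np.std(y) <= tiny * (abs(np.mean(y)) + 1):
            rows[name] = CorrelationRow(name, math.nan, math.nan, len(matched), degenerate=True)
            log.warning("zero variance for %s; correlation undefined", name)
            continue
        r, p = stats.pearsonr(x, y)
        rows[name] = CorrelationRow(name, float(r), float(p), len(matched))
    return rows


def _screen_assumptions(name: str, xa: np.ndarray, xb: np.ndarray) -> None:
    """Shapiro-Wilk / Bartlett screens, logged only (never switches the
    test family)."""
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(xa) >= 3 and np.ptp(xa) > 0:
                _, p_sw = stats.shapiro(xa)
                if p_sw < 0.05:
                    log.info("normality screen: %s group A Shapiro-Wilk p=%.3f", name, p_sw)
            if len(xb) >= 3 and np.ptp(xb) > 0:
                _, p_sw = stats.shapiro(xb)
                if p_sw < 0.05:
                    log.info("normality screen: %s group B Shapiro-Wilk p=%.3f", name, p_sw)
            if np.std(xa) > 0 and np.std(xb) > 0:
                _, p_b = stats.bartlett(xa, xb)
                if p_b < 0.05:
                    log.info("homoscedasticity screen: %s Bartlett p=%.3f", name, p_b)
    except ValueError:  # pragma: no cover - degenerate screen input
        pass


def compare_groups(
    group_a: list[TrialSummary],
    group_b: list[TrialSummary],
    paired: bool = False,
    parameters: tuple[str, ...] = PARAMETER_NAMES,
) -> GroupReport:
    """Student's t-test per parameter between two sets of per-subject
    summaries.

    ``paired=False`` compares independent groups (e.g. patients vs
    controls); ``paired=True`` compares matched conditions (e.g. gait
    initiation vs step climbing within subjects, matched by subject id).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 summaries per group")
    if paired:
        matched = _match_by_subject(group_a, group_b)
        if len(matched) < 2:
            raise ValueError("need at least 2 matched subjects for a paired test")
    rows: dict[str, ComparisonRow] = {}
    for name in parameters:
        if paired:
            xa = np.array([getattr(a.params, name) for a, _ in matched])
            xb = np.array([getattr(b.params, name) for _, b in matched])
            diffs = xa - xb
            if np.allclose(diffs, 0):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_rel(xa, xb)
        else:
            xa = np.array([getattr(s.params, name) for s in group_a])
            xb = np.array([getattr(s.params, name) for s in group_b])
            if np.std(xa) == 0 and np.std(xb) == 0 and np.mean(xa) == np.mean(xb):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_ind(xa, xb)
        _screen_assumptions(name, xa, xb)
        rows[name] = ComparisonRow(
            parameter=name,
            mean_a=float(np.mean(xa)),
            sd_a=float(np.std(xa, ddof=1)),
            mean_b=float(np.mean(xb)),
            sd_b=float(np.std(xb, ddof=1)),
            statistic=float(t_stat),
            p_value=float(p),
            n_a=len(xa),
            n_b=len(xb),
            paired=paired,
        )
    return GroupReport(rows=rows)
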
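# apakit

Detection and quantification of **anticipatory postural adjustments
(APAs)** — the feed-forward postural phase between quiet standing and the
first step — from two complementary instruments:

* **force plates** (the laboratory gold standard): centre-of-pressure
  (COP) trajectory and per-plate vertical ground reaction force at
  800 Hz;
* a **two-unit wearable setup**: a lower-trunk 3D accelerometer and a
  shank gyroscope at 50 Hz, usable in clinical settings where force
  plates are unavailable.

The package targets the analysis of gait initiation and single-step
climbing, including the hypometric APAs typical of Parkinson's disease,
and ships a synthetic-trial generator that emits paired recordings with
known ground-truth events — the test bed for every detector.

## Method

Per trial, five instants are identified. From the force plate (COP
low-pass filtered at 10 Hz, zero-phase 4th-order Butterworth):

* **APA onset** — first sustained excursion of the COP ML displacement
  beyond 2·SD of the quiet-standing baseline;
* **trailing toe-off** — last instant plate 1 stays above a 6.5 %
  body-weight floor;
* **leading toe-off** — instant of maximal perpendicular distance
  *d*<sub>1MAX</sub> of the COP from the line **L1** joining the COP
  positions at APA onset and trailing toe-off;
* **leading heel-off** — maximal distance *d*<sub>2MAX</sub> from the
  line **L2** joining the COP positions at APA onset and leading
  toe-off;
* **foot contact** — first instant plate 2 exceeds 6.5 % body weight.

From the wearable (tilt-corrected to a horizontal-vertical frame via the
quiet-standing gravity estimate, filtered at 3.5 Hz):

* onset when the trunk ML acceleration exceeds **A**·SD of its quiet
  baseline;
* heel-off when the shank ML angular velocity first exceeds
  **H**·Ω<sub>pk</sub> (Ω<sub>pk</sub> = first angular-velocity peak);
* toe-off when it first drops below **T**·Ω<sub>pk</sub> after the
  peak;
* foot contact at the median point between the second angular-velocity
  peak and the preceding zero-crossing.

The factors are calibrated against force-plate events by exhaustive grid
search (A ∈ 1…5 step 1, H ∈ 0…1 step 0.01, T ∈ 0…1 step 0.05) minimising
the per-event mean absolute error averaged per subject, then across
subjects. Calibrated values: gait initiation **A=2, H=0.07, T=0.25**;
step climbing **A=2, H=0.08, T=1**.

From the events, five durations (imbalance, unloading, APA = imbalance +
unloading, swing, step = APA + swing) and four amplitudes (signal change
over the imbalance and unloading phases, ML and AP) are derived, with
per-subject averaging over repetitions, Pearson-correlation validation
of the wearable against the force plate, and Student's *t* comparisons
between groups (unpaired) and tasks (paired).

## Worked example

```python
from apakit import (TrialBlueprint, generate_trial, detect_all_fp,
                    detect_all_imu, DEFAULT_THRESHOLDS)
from apakit.imu_events import preprocess_imu
from apakit.params import trial_summary

bp = TrialBlueprint.default("gait_initiation", seed=42)
fp, imu, truth = generate_trial(bp)
ev_fp = detect_all_fp(fp)
ev_imu = detect_all_imu(imu, DEFAULT_THRESHOLDS[imu.task])
```

With ground-truth events programmed at 10.000 / 10.400 / 10.700 /
11.200 s (onset, heel-off, toe-off, foot contact), the two chains
return:

```
force plate: onset 9.991  heel-off 10.400  toe-off 10.701  contact 11.201
inertial   : onset 9.980  heel-off 10.400  toe-off 10.700  contact 11.201
```

i.e. every event within one or two samples of its stream at default
noise. The derived parameters of the inertial trial:

```
imbalance 0.420 s, unloading 0.300 s, APA 0.720 s, swing 0.501 s, step 1.221 s
ML amplitude: imbalance +0.144, unloading -0.762 m/s^2
```

Durations obey APA = imbalance + unloading and step = APA + swing
exactly; the ML amplitude is positive during imbalance (COP and trunk
move toward the stepping side) and negative during unloading (shift to
the stance side).

A command-line interface mirrors the library:

```
apakit simulate --out cohort/ --subjects 5 --seed 1
apakit detect-fp  cohort/s01_gait_t1_fp.csv  --out fp_events.json
apakit detect-imu cohort/s01_gait_t1_imu.csv --task gait --out imu_events.json
apakit calibrate --pairs cohort/ --task gait --out thresholds.json
apakit report --manifest cohort/ --out report.json
```

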
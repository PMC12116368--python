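# hintspy

Post-processing, event detection and triage for eye/head-tracking
recordings of the **HINTS exam** (Head-Impulse, Nystagmus, Test-of-Skew)
captured with a mixed-reality head-mounted display.

## The problem

Acute vestibular syndrome — sudden vertigo with imbalance, nausea and
nystagmus — is usually benign (e.g. vestibular neuritis) but in 10–33 % of
cases it is a posterior-circulation stroke. The three-part bedside HINTS
exam separates the two more sensitively than early imaging, but it takes
specialist expertise to read. A head-mounted display with built-in eye
tracking can record the exam (gaze rays of each eye and head pose at
60 Hz) so the oculomotor signs can be extracted from the signal instead of
the examiner's eye. This package is the analysis side of that idea: it
turns per-frame recordings into the three findings and the triage
decision, and ships a deterministic simulator that generates synthetic
exams with ground-truth event logs so every detector is testable without
a headset.

## The decision rule

For a patient with acute vestibular syndrome:

* **peripheral pattern** — abnormal head-impulse test (catch-up saccades
  after head impulses with peak velocity ≥ 150°/s), **unidirectional
  horizontal** nystagmus, **no** skew deviation;
* **central pattern** — any dangerous sign: a *normal* head-impulse test
  in the presence of nystagmus, **direction-changing** or **vertical
  (down-beating)** nystagmus, or **skew deviation** on the alternating
  cover test.

The rule is asymmetric by design: any single dangerous sign forces the
central pattern. An exam with no oculomotor abnormality at all is
reported `indeterminate` and mapped to the healthy group in cohort
summaries.

Core signal definitions (all series are mean-centered before plotting):

* eye velocity `v_eye(t)` — finite difference of the horizontal (x)
  component of the combined gaze-ray origin (world frame, m/s);
* head velocity `ω_head(t)` — finite difference of the unwrapped yaw
  Euler angle (deg/s);
* nystagmus trace — left-eye plus right-eye gaze-direction x (or y)
  component over time; slow-phase velocity is the median Theil–Sen slope
  over inter-fast-phase intervals, fast phases are detected at an
  adaptive threshold of `λ·median(|v|)/0.6745` with λ = 5;
* skew trace — per-eye vertical (y) position; a step time-locked to a
  cover alternation above `max(k·σ̂, floor)` with k = 3 is a refixation.

## Worked example

Simulate a 3-subject cohort (one per profile), analyze it, plot a panel:

```
$ hints simulate --out demo/cohort --seed 5 --n-healthy 1 --n-peripheral 1 --n-central 1
wrote 3 subjects to demo/cohort

$ hints analyze --in demo/cohort --out demo/reports
analyzed 3 subject(s), 0 failure(s); summary in demo/reports/summary.csv

$ cat demo/reports/summary.csv
subject_id,diagnosis_label,triage,predicted_group,hit_abnormal,nystagmus_class,skew_present,n_impulses,n_catch_up,n_warnings
S000,healthy,indeterminate,healthy,False,none,False,10,0,0
S001,peripheral,peripheral-pattern,peripheral,True,unidirectional-horizontal,False,10,5,0
S002,central,central-pattern,central,False,direction-changing,True,10,0,0

$ hints plot --subject-dir demo/cohort/S001 --stage hit_left --kind hit-overlay --out hit.png
```

Reading the summary: the peripheral subject (S001) shows ten detected
head impulses, five of them (the ipsilesional side) followed by catch-up
saccades, with right-beating horizontal nystagmus
(`slow_phase_velocity ≈ 0.15` unit-vector components/s on the summed
two-eye trace, beat frequency ≈ 1.6 Hz in its report JSON) and no
vertical refixation on the cover test — the peripheral triad. The central
subject has an intact vestibulo-ocular reflex (no catch-up saccades),
direction-changing gaze-evoked nystagmus and a detected skew deviation —
each alone would force the central pattern.

Each subject's full report (`demo/reports/S001.json`) lists every event,
the thresholds used, and the resolved configuration; it validates against
`src/hintspy/report_schema.json`.

## Library surface

```python
from hintspy import (
    SimulationProfile, simulate_subject,      # synthetic exams + ground truth
    read_recording, trim_initial,             # CSV I/O, initial-seconds trim
    eye_horizontal_velocity, head_yaw_velocity, gaze_component,
    detect_saccades, detect_head_impulses, characterize_nystagmus,
    detect_skew, classify_hints,              # findings and triage
    analyze_subject,                          # the whole pipeline
)
```

All thresholds live in one `AnalysisConfig` block (YAML-overridable); the
CSV column naming and time unit are adapted through a `CsvDialect`, since
real exports vary.

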
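# Methods

## Data model and conventions

A recording is one subject performing one stage of a ten-step exam
protocol (start, calibration check, spontaneous nystagmus, gaze left,
gaze right, fixation at the examiner's nose, head impulses left and
right, alternating cover test, save), sampled nominally at 60 Hz. Each
frame holds the gaze ray (origin in metres, unit direction vector) of the
left, right and combined eye, per-eye tracker validity flags, and the
head pose: position, Euler angles (intrinsic yaw–pitch–roll about
y–x–z, degrees) and a unit quaternion (w, x, y, z).

All modules share one right-handed frame: +y vertical, −z forward, +x
toward the wearer's right. Positive yaw is a leftward head turn (right-
hand rule about +y). Angles are degrees in every external interface;
timestamps are seconds from recording start.

The CSV schema (31 canonical columns, header mandatory, UTF-8, "."
decimal) is a package choice — device exports differ, so a `CsvDialect`
maps canonical names onto file columns and converts the device time unit
to seconds. Floats are written with shortest round-tripping repr, making
read∘write lossless to well below 1e-9.

Frames whose validity flags are false, or whose direction norms are off
unit by more than 1e-3, are retained (timing structure preserved) but
excluded from kinematics. No interpolation, smoothing or artifact
correction is applied anywhere; the only preprocessing is dropping the
first `trim_seconds` of each stage (default 2.0 s, covering the
voice-prompt adherence transient) and unwrapping yaw across ±180°.

## Feature extraction

Velocities are second-order finite differences (central in the interior,
second-order one-sided at the ends, irregular-interval aware via
`numpy.gradient(..., edge_order=2)`). On 60 Hz sinusoids up to 2 Hz the
worst error is ≈1.4 % of the peak derivative; on polynomials of degree
≤ 2 the interior is exact.

* Eye velocity: x component of the combined gaze-ray origin (m/s). A
  config switch (`eye_velocity_channel`) substitutes the gaze-direction x
  component, since either channel can be read as "the positional vector".
* Head velocity: unwrapped yaw, deg/s.
* Impulse overlay: both series mean-centered, multiplied by configurable
  factors (defaults 1000 for the eye, 1 for the head) and reported in
  arbitrary units (AU); factors are recorded in the series metadata.
* Nystagmus traces: the per-frame **sum** of left and right gaze-direction
  components (x for horizontal, y for vertical), mean-centered. Summing
  doubles the conjugate signal while noise grows only by √2. Note the
  summed trace drifts at **twice** the single-eye slow-phase velocity.
* Skew traces: per-eye vertical (y) position, baseline-centered; primary
  channel is the gaze origin (metres), with the direction y component as
  a secondary channel.

## Event detection

Every threshold is an explicit field of one `DetectionThresholds` block,
embedded in every report. Defaults:

| parameter | default | meaning |
|---|---|---|
| `saccade_lambda` | 5.0 | adaptive saccade threshold, robust SDs of \|v\| |
| `motion_floor_deg_s` | 20 | minimum head speed counted as an impulse |
| `adequacy_deg_s` | 150 | peak speed an impulse must reach to be adequate |
| `catchup_window_s` | 0.5 | post-impulse window for corrective saccades |
| `nystagmus_min_beat_hz` | 0.5 | minimum recurring fast-phase rate |
| `nystagmus_sign_consistency` | 0.8 | fraction of slow phases sharing one drift sign |
| `skew_k` | 3.0 | skew step threshold, robust noise SDs |
| `skew_floor_m` / `skew_floor_component` | 2.5e-4 / 5e-3 | absolute skew floors per channel |
| `skew_lock_window_s` | 0.25 | time-lock tolerance around cover switches |

**Saccades** are contiguous runs of |velocity| above threshold, runs
separated by ≤ 1 frame merged; each event carries onset, offset, peak
time, peak speed, signed integral amplitude and direction. The adaptive
threshold `λ·median(|v|)/0.6745` is scale-free and resists contamination
by the saccades themselves.

**Head impulses** are super-floor excursions of |yaw velocity| lasting at
least 3 samples (50 ms; shorter excursions are sensor noise), graded
adequate at ≥ 150 deg/s. Sides with no adequate impulse are reported *not
testable*, never normal.

**Catch-up saccades** are saccades on the eye-velocity series whose onset
falls within the window after an adequate impulse's peak, after the head
has come to rest (onset later than the impulse offset — this excludes the
vestibulo-ocular response itself, which also opposes the head), and whose
direction opposes the head movement.

**Nystagmus**: fast phases via the saccade detector on the differenced
gaze trace; slow phases are the intervals between them (one frame of
margin, ≥ 5 samples). Slow-phase velocity is the median absolute
Theil–Sen slope across intervals — robust to residual fast-phase samples
without smoothing the data. The beat rate is the reciprocal median
inter-beat interval when ≥ 3 fast phases exist (the event count per
window quantizes to ±1 beat and is used only as a fallback). Nystagmus is
*present* when beats recur at ≥ 0.5 Hz, the slow-phase drift keeps one
sign in ≥ 80 % of intervals, and at least two fast phases were seen.
Direction-changing nystagmus means both eccentric-gaze stages beat, with
opposite signs.

**Skew**: with cover-alternation times (from the simulation log or an
annotation sidecar — the headset cannot sense the examiner's occluder),
each eye's vertical series is tested for a mean step across every switch
(window means over ±0.25 s, a 50 ms guard band excluded); the disparity
is the median |left − right| during the alternation phase referenced to
the both-uncovered lead-in baseline. The baseline reference matters:
per-eye mean-centering otherwise absorbs a deviation that is present for
most of the stage. Without cover times the fallback is sustained
inter-eye disparity above the floor, which is necessarily weaker.

**Triage** (`classify_hints`): dangerous signs — normal head-impulse test
with nystagmus present, direction-changing or vertical nystagmus, skew —
force the central pattern; the peripheral pattern requires the full triad
(abnormal impulse test, unidirectional horizontal nystagmus, skew tested
and absent); anything else is indeterminate. A skew that could not be
tested never licenses the peripheral label. VOR gain (integrated eye over
integrated head displacement per impulse) is reported as supplementary
evidence but does not enter the rule, which operates on corrective
saccades only.

## The simulator

The simulator emulates the *recording format and the idealized oculomotor
signatures*, not eyeball physiology. Geometry: inter-pupillary distance
63 mm, fixation target (the examiner's nose) 40 cm ahead, eccentric gaze
±15°. Gaze directions are built as baseline-fixation vectors plus
small horizontal/vertical component offsets, renormalized to unit length;
gaze origins trace a scaled copy of the same signal (0.05 m per unit
component) so both candidate channels carry it. Head quaternions are
computed from the (noisy) Euler angles, so the two encodings agree
exactly.

* **Nystagmus**: ideal sawtooth — linear slow drift at the slow-phase
  velocity, fast reset spread over 2 frames; amplitude = SPV/beat-rate.
  No velocity decay, no Alexander's-law modulation.
* **Head impulse**: flat-topped raised-cosine yaw velocity pulse, 11
  frames (~183 ms) with a 3-frame plateau — the plateau makes the
  finite-difference peak equal the nominal peak exactly, so the
  adequacy boundary is measurable to ±1 deg/s by bisection. Each pulse
  displaces the head by peak/10 degrees; the head holds 0.8 s, then
  returns over 3 s (≤ 12 deg/s, below the motion floor). The eye counter-
  rotates at the side's VOR gain; with gain < 1 the residual gaze error
  is cleared by a corrective saccade 150 ms after the pulse (3 frames,
  amplitude (1−gain)·displacement, logged).
* **Cover test**: 3.5 s both-uncovered lead-in (so a baseline survives
  the 2 s trim), then six 2 s occlusion epochs alternating left/right.
  The covered eye deviates by the skew offset (left up, right down) with
  100 ms ramps; every switch and refixation is logged.
* **Noise**: i.i.d. Gaussian per component per frame, SD 0.002 in
  direction units (scaled copies on origins, 0.05° on Euler angles).
* **Artifact**: a half-sine drift in the first 1.5 s of each stage
  (amplitude 0.05 components, 2° yaw) emulating voice-prompt adherence;
  this is what `trim_initial` removes.

Default study conditions: cohort of 30 (21 healthy / 7 peripheral / 2
central); peripheral subjects draw single-eye SPV from 0.05–0.12
components/s (≈ 3–7 deg/s), beat frequency 1.2–2.2 Hz, lesioned-side VOR
gain 0.3–0.6, beating away from the lesion; central subjects alternate
direction-changing and down-beating variants, skew offset 0.012–0.03
components (≈ 0.7–1.7°), intact gains; impulse peaks 180–230 deg/s, five
per side. Ages/sexes are drawn to match the group demographics as fixture
colour only. The seed drives **only** the noise realization; event
structure is a pure function of the parameters, which is what makes
same-seed output byte-identical and the ground-truth log an exact oracle.

What passing tests on these traces show: the pipeline recovers the
parameters and labels of *idealized* signals under Gaussian noise. What
they do not show: robustness to blinks and tracker dropouts, pursuit
intrusions, torsional movements, velocity-decaying slow phases,
Alexander's-law gain changes, head-unrestrained artifacts, or real
device noise spectra — none of which the simulator emulates.

## Numerical choices and degenerate inputs

Re-trimming an already-trimmed recording is idempotent (the applied
offset is tracked). A saccade run's direction is the sign at its absolute
peak; ties in `argmax` resolve to the earliest sample. The adequacy
comparison is inclusive (≥ threshold) on the *measured* peak. Time series
must be strictly increasing; zero inter-sample intervals are data errors,
not warnings. Empty recordings, all-invalid frames, sub-2 s nystagmus
traces and misaligned skew series raise typed errors rather than
returning findings. Problem sizes throughout (10 s fixation stages, five
impulses per side, six cover alternations, 30-subject cohorts) are the
package's default study conditions and keep the full suite and the
acceptance script each under a minute.

## Known limitations

The detector thresholds are defaults chosen for the idealized traces, not
clinically validated operating points. Beat direction is reported in the
shared sign convention (+ = rightward/upward) and "down" for vertical;
torsional nystagmus is out of scope. The skew fallback without cover
annotations cannot distinguish a constant vertical tracker bias from a
true deviation. The triage rule presumes the exam was performed as
specified; it flags, but cannot repair, missing stages.
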
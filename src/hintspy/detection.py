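"""Event detection and the HINTS triage rule.

Turns feature series into clinical findings: saccades, head impulses and
their adequacy, catch-up saccades after inadequate vestibulo-ocular
compensation, nystagmus characterization (beat frequency, slow-phase
velocity, beat direction), skew deviation on the alternating cover test,
and finally the peripheral-vs-central HINTS decision.

The decision rule is deliberately asymmetric toward safety: any single
dangerous sign (normal head-impulse test in the presence of nystagmus,
direction-changing or vertical nystagmus, skew deviation) forces the
central pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import theilslopes

from .errors import AlignmentError, ContractError, InsufficientDataError
from .kinematics import FeatureSeries, finite_difference

VELOCITY_UNITS_SUFFIX = "/s"

# Triage labels
PERIPHERAL_PATTERN = "peripheral-pattern"
CENTRAL_PATTERN = "central-pattern"
INDETERMINATE = "indeterminate"

# Nystagmus classes
NYSTAGMUS_NONE = "none"
NYSTAGMUS_UNIDIRECTIONAL = "unidirectional-horizontal"
NYSTAGMUS_DIRECTION_CHANGING = "direction-changing"
NYSTAGMUS_VERTICAL = "vertical"


@dataclass(frozen=True)
class SaccadeEvent:
    """A contiguous super-threshold velocity excursion."""

    onset: float
    offset: float
    peak_time: float
    peak_velocity: float  # magnitude, units of the source series
    amplitude: float  # signed integral of velocity over the event
    direction: int  # +1 rightward/upward, -1 leftward/downward
    threshold: float

    def to_dict(self) -> dict:
        return {
            "onset": self.onset, "offset": self.offset,
            "peak_time": self.peak_time, "peak_velocity": self.peak_velocity,
            "amplitude": self.amplitude, "direction": self.direction,
            "threshold": self.threshold,
        }


@dataclass(frozen=True)
class HeadImpulse:
    onset: float
    offset: float
    peak_time: float
    peak_angular_velocity: float  # magnitude, deg/s
    direction: int
    adequate: bool

    def to_dict(self) -> dict:
        return {
            "onset": self.onset, "offset": self.offset,
            "peak_time": self.peak_time,
            "peak_angular_velocity": self.peak_angular_velocity,
            "direction": self.direction, "adequate": self.adequate,
        }


@dataclass
class CatchUpResult:
    """Catch-up saccades keyed by impulse index; not_testable when no
    impulse reached the adequacy threshold."""

    by_impulse: dict[int, list[SaccadeEvent]]
    not_testable: bool

    def any_catch_up(self) -> bool:
        return any(len(v) > 0 for v in self.by_impulse.values())


@dataclass
class NystagmusFinding:
    present: bool
    plane: str  # horizontal | vertical
    beat_direction: object  # +1 / -1 / "down" / None
    slow_phase_velocity: float
    beat_frequency: float
    direction_changing: bool = False
    gaze_condition: str = ""
    n_fast_phases: int = 0

    def to_dict(self) -> dict:
        return {
            "present": self.present, "plane": self.plane,
            "beat_direction": self.beat_direction,
            "slow_phase_velocity": self.slow_phase_velocity,
            "beat_frequency": self.beat_frequency,
            "direction_changing": self.direction_changing,
            "gaze_condition": self.gaze_condition,
            "n_fast_phases": self.n_fast_phases,
        }


@dataclass
class SkewFinding:
    present: bool
    vertical_disparity: float
    refixation_events: list[tuple[float, float, str]] = field(default_factory=list)
    threshold: float = 0.0
    matched_switch_fraction: float | None = None

    def to_dict(self) -> dict:
        return {
            "present": self.present,
            "vertical_disparity": self.vertical_disparity,
            "refixation_events": [list(e) for e in self.refixation_events],
            "threshold": self.threshold,
            "matched_switch_fraction": self.matched_switch_fraction,
        }


@dataclass
class HintsResult:
    hit_abnormal: bool
    hit_testable: bool
    nystagmus_class: str
    skew_present: bool | None  # None = not testable
    triage: str
    evidence: dict[str, str] = field(default_factory=dict)

    @property
    def predicted_group(self) -> str:
        """Map the triage pattern onto the cohort group vocabulary.

        An exam with adequate impulses, normal VOR, no nystagmus and no
        skew shows no oculomotor abnormality at all and maps to healthy.
        """
        if self.triage == PERIPHERAL_PATTERN:
            return "peripheral"
        if self.triage == CENTRAL_PATTERN:
            return "central"
        if (
            self.hit_testable
            and not self.hit_abnormal
            and self.nystagmus_class == NYSTAGMUS_NONE
            and self.skew_present is not True
        ):
            return "healthy"
        return "unknown"

    def to_dict(self) -> dict:
        return {
            "hit_abnormal": self.hit_abnormal,
            "hit_testable": self.hit_testable,
            "nystagmus_class": self.nystagmus_class,
            "skew_present": self.skew_present,
            "triage": self.triage,
            "predicted_group": self.predicted_group,
            "evidence": dict(self.evidence),
        }


# -- saccades ---------------------------------------------------------------

def _require_velocity_units(series: FeatureSeries) -> None:
    if not (series.units.endswith(VELOCITY_UNITS_SUFFIX) or series.units == "AU"):
        raise ContractError(
            f"saccade detection needs a velocity series, got units "
            f"{series.units!r}"
        )


def robust_sd(values: np.ndarray) -> float:
    """Median-absolute-value estimate of the SD of a zero-mean signal."""
    return float(np.median(np.abs(values)) / 0.6745)


def detect_saccades(
    vel: FeatureSeries,
    threshold_mode: str = "adaptive",
    threshold: float | None = None,
    adaptive_lambda: float = 5.0,
    merge_gap_frames: int = 1,
) -> list[SaccadeEvent]:
    """Detect rapid eye movements as super-threshold velocity runs.

    Contiguous samples with |v| above threshold are grouped into events;
    runs separated by at most merge_gap_frames sub-threshold samples are
    merged.  In adaptive mode the threshold is lambda times the robust SD
    of |v| (median/0.6745), which resists contamination by the saccades
    themselves.
    """
    _require_velocity_units(vel)
    if len(vel) == 0:
        return []
    v = vel.values
    t = vel.timestamps
    if threshold_mode == "adaptive":
        thr = adaptive_lambda * robust_sd(v)
    elif threshold_mode == "fixed":
        if threshold is None:
            raise ContractError("fixed threshold mode needs an explicit threshold")
        thr = float(threshold)
    else:
        raise ContractError(f"unknown threshold_mode {threshold_mode!r}")

    above = np.abs(v) > thr
    runs = _runs(above)
    runs = _merge_runs(runs, merge_gap_frames)

    events = []
    for start, stop in runs:  # stop exclusive
        seg_v = v[start:stop]
        seg_t = t[start:stop]
        ipk = int(np.argmax(np.abs(seg_v)))
        amplitude = float(np.trapezoid(seg_v, seg_t)) if stop - start > 1 else 0.0
        events.append(SaccadeEvent(
            onset=float(seg_t[0]),
            offset=float(seg_t[-1]),
            peak_time=float(seg_t[ipk]),
            peak_velocity=float(np.abs(seg_v[ipk])),
            amplitude=amplitude,
            direction=int(np.sign(seg_v[ipk])) or 1,
            threshold=thr,
        ))
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (exclusive) indices of True runs."""
    if not np.any(mask):
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.nonzero(diff == 1)[0]
    stops = np.nonzero(diff == -1)[0]
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for start, stop in runs[1:]:
        if start - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


# -- head impulses ----------------------------------------------------------

def detect_head_impulses(
    head_vel: FeatureSeries,
    adequacy_threshold: float = 150.0,
    motion_floor: float = 20.0,
    min_duration_frames: int = 3,
) -> list[HeadImpulse]:
    """Detect head-impulse velocity pulses and grade their adequacy.

    A pulse is a contiguous excursion of |angular velocity| above the
    motion floor with one dominant peak, lasting at least
    min_duration_frames samples (a real manual impulse spans well over
    50 ms; shorter excursions are sensor noise); it is adequate when its
    peak reaches the adequacy threshold (default 150 deg/s), the minimum
    speed at which the impulse outruns smooth visual tracking.
    """
    if head_vel.units != "deg/s":
        raise ContractError(
            f"head impulse detection needs deg/s, got {head_vel.units!r}"
        )
    v = head_vel.values
    t = head_vel.timestamps
    impulses = []
    for start, stop in _runs(np.abs(v) > motion_floor):
        if stop - start < min_duration_frames:
            continue
        seg_v = v[start:stop]
        seg_t = t[start:stop]
        ipk = int(np.argmax(np.abs(seg_v)))
        peak = float(np.abs(seg_v[ipk]))
        impulses.append(HeadImpulse(
            onset=float(seg_t[0]),
            offset=float(seg_t[-1]),
            peak_time=float(seg_t[ipk]),
            peak_angular_velocity=peak,
            direction=int(np.sign(seg_v[ipk])) or 1,
            adequate=peak >= adequacy_threshold,
        ))
    return impulses


def detect_catch_up_saccades(
    eye_vel: FeatureSeries,
    impulses: Sequence[HeadImpulse],
    window: float = 0.5,
    **saccade_kwargs,
) -> CatchUpResult:
    """Corrective saccades time-locked to head impulses.

    For each adequate impulse, keeps saccades whose onset falls in
    (impulse peak, impulse peak + window], that start after the head has
    come to rest (onset > impulse offset, excluding the vestibulo-ocular
    response itself) and whose direction opposes the head movement.
    """
    saccades = detect_saccades(eye_vel, **saccade_kwargs)
    by_impulse: dict[int, list[SaccadeEvent]] = {}
    any_adequate = False
    for i, imp in enumerate(impulses):
        hits: list[SaccadeEvent] = []
        if imp.adequate:
            any_adequate = True
            for s in saccades:
                in_window = imp.peak_time < s.onset <= imp.peak_time + window
                after_rest = s.onset > imp.offset
                opposite = s.direction == -imp.direction
                if in_window and after_rest and opposite:
                    hits.append(s)
        by_impulse[i] = hits
    return CatchUpResult(by_impulse=by_impulse, not_testable=not any_adequate)


# -- nystagmus --------------------------------------------------------------

def characterize_nystagmus(
    series: FeatureSeries,
    plane: str,
    min_beat_frequency: float = 0.5,
    sign_consistency: float = 0.8,
    adaptive_lambda: float = 5.0,
    min_slow_samples: int = 5,
) -> NystagmusFinding:
    """Segment a fixation trace into fast and slow phases.

    Fast phases are detected as saccades on the differenced gaze series;
    slow phases are the intervals between them.  Slow-phase velocity is
    the median absolute Theil-Sen slope over slow intervals (robust to
    residual fast-phase samples), beat frequency the fast-phase count per
    analyzed second, and beat direction the modal fast-phase sign.
    Nystagmus is present when beats recur at >= min_beat_frequency and the
    slow-phase drift keeps one sign in >= sign_consistency of intervals.
    """
    if series.duration < 2.0:
        raise InsufficientDataError(
            f"nystagmus characterization needs >= 2 s, got {series.duration:.2f} s"
        )
    vel = finite_difference(
        series.values, series.timestamps,
        units=series.units + VELOCITY_UNITS_SUFFIX, source=series.source,
    )
    fast = detect_saccades(vel, threshold_mode="adaptive",
                           adaptive_lambda=adaptive_lambda)
    duration = series.duration
    # Beat rate from the median inter-beat interval when possible: the
    # count-per-duration estimate quantizes to +-1 beat per window, which
    # is coarse for short traces at low beat rates.
    if len(fast) >= 3:
        intervals = np.diff([e.peak_time for e in fast])
        freq = float(1.0 / np.median(intervals))
    else:
        freq = len(fast) / duration

    t, x = series.timestamps, series.values
    # Slow intervals: between consecutive fast phases, one frame of margin.
    starts = [t[0]] + [e.offset for e in fast]
    stops = [e.onset for e in fast] + [t[-1]]
    slopes = []
    median_dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0 / 60.0
    for a, b in zip(starts, stops):
        sel = (t > a + median_dt) & (t < b - median_dt)
        if sel.sum() < min_slow_samples:
            continue
        slope, *_ = theilslopes(x[sel], t[sel])
        slopes.append(float(slope))

    if slopes:
        spv = float(np.median(np.abs(slopes)))
        signs = np.sign(slopes)
        nonzero = signs[signs != 0]
        consistency = (
            max((nonzero > 0).mean(), (nonzero < 0).mean()) if len(nonzero) else 0.0
        )
    else:
        spv, consistency = 0.0, 0.0

    if fast:
        dir_sum = sum(e.direction for e in fast)
        beat_sign = 1 if dir_sum >= 0 else -1
    else:
        beat_sign = None

    present = (
        freq >= min_beat_frequency
        and consistency >= sign_consistency
        and spv > 0
        and len(fast) >= 2
    )
    beat_direction: object
    if beat_sign is None:
        beat_direction = None
    elif plane == "vertical" and beat_sign < 0:
        beat_direction = "down"
    else:
        beat_direction = beat_sign
    return NystagmusFinding(
        present=bool(present),
        plane=plane,
        beat_direction=beat_direction,
        slow_phase_velocity=spv,
        beat_frequency=freq,
        gaze_condition=series.source,
        n_fast_phases=len(fast),
    )


def direction_change_across_gaze(
    findings: Mapping[str, NystagmusFinding],
    left_stage: str = "gaze_left",
    right_stage: str = "gaze_right",
) -> bool | None:
    """True when gaze-left and gaze-right both beat, in opposite directions.

    Returns None (not testable) when either gaze stage is missing.
    """
    if left_stage not in findings or right_stage not in findings:
        return None
    fl, fr = findings[left_stage], findings[right_stage]
    if not (fl.present and fr.present):
        return False
    dl = -1 if fl.beat_direction == "down" else fl.beat_direction
    dr = -1 if fr.beat_direction == "down" else fr.beat_direction
    if dl is None or dr is None:
        return False
    return bool(dl == -dr)


# -- skew -------------------------------------------------------------------

def detect_skew(
    left_y: FeatureSeries,
    right_y: FeatureSeries,
    cover_times: Sequence[float] | None = None,
    k: float = 3.0,
    floor: float = 0.0,
    lock_window: float = 0.25,
    guard: float = 0.05,
) -> SkewFinding:
    """Vertical refixation movements during the alternating cover test.

    With cover alternation times, tests each eye's vertical series for a
    mean step across every switch (window means over lock_window on each
    side, a guard band around the switch itself excluded); a step counts
    when it exceeds max(k x robust noise SD, floor).  Without cover times
    the fallback is sustained inter-eye vertical disparity above the same
    threshold.  vertical_disparity is the median |left - right| outside
    transition windows.
    """
    if len(left_y) != len(right_y) or not np.allclose(
        left_y.timestamps, right_y.timestamps, atol=1e-9
    ):
        raise AlignmentError("left and right vertical series are misaligned")
    t = left_y.timestamps
    noise = max(
        _diff_noise_sd(left_y.values), _diff_noise_sd(right_y.values)
    )
    threshold = max(k * noise, floor)

    d = left_y.values - right_y.values
    away_from_switch = np.ones(len(t), bool)
    if cover_times:
        for s in cover_times:
            away_from_switch &= np.abs(t - s) > lock_window
    if cover_times:
        # Reference the occluded-epoch disparity to the both-uncovered
        # baseline before the first switch; per-eye centering otherwise
        # absorbs a deviation that is present most of the stage.
        first, last = min(cover_times), max(cover_times)
        base_sel = t < first - lock_window
        alt_sel = (t > first + lock_window) & (t < last - lock_window) & away_from_switch
        baseline = float(np.median(d[base_sel])) if np.any(base_sel) else float(np.median(d))
        sel = alt_sel if np.any(alt_sel) else away_from_switch
        disparity = float(np.median(np.abs(d[sel] - baseline)))
    else:
        disparity = (
            float(np.median(np.abs(d[away_from_switch])))
            if np.any(away_from_switch) else float(np.median(np.abs(d)))
        )

    refixations: list[tuple[float, float, str]] = []
    matched_fraction: float | None = None
    if cover_times:
        matched = 0
        testable = 0
        for s in cover_times:
            pre = (t >= s - lock_window) & (t < s - guard)
            post = (t > s + guard) & (t <= s + lock_window)
            if pre.sum() < 2 or post.sum() < 2:
                continue
            testable += 1
            found = False
            for eye, series in (("left", left_y), ("right", right_y)):
                step = float(series.values[post].mean() - series.values[pre].mean())
                if abs(step) > threshold:
                    refixations.append((float(s), step, eye))
                    found = True
            matched += found
        matched_fraction = matched / testable if testable else None

    if cover_times is not None and len(cover_times) > 0:
        present = disparity > threshold and bool(refixations)
    else:
        present = disparity > threshold
    return SkewFinding(
        present=bool(present),
        vertical_disparity=disparity,
        refixation_events=refixations,
        threshold=threshold,
        matched_switch_fraction=matched_fraction,
    )


def _diff_noise_sd(values: np.ndarray) -> float:
    """Noise SD estimated from first differences (slope-insensitive)."""
    if len(values) < 3:
        return 0.0
    return float(np.median(np.abs(np.diff(values))) / (0.6745 * np.sqrt(2.0)))


# -- HINTS rule -------------------------------------------------------------

def classify_nystagmus(
    findings: Mapping[str, NystagmusFinding],
) -> str:
    """Overall nystagmus class across the fixation stages."""
    dc = direction_change_across_gaze(findings)
    if dc:
        return NYSTAGMUS_DIRECTION_CHANGING
    present = [f for f in findings.values() if f.present]
    if any(f.plane == "vertical" for f in present):
        return NYSTAGMUS_VERTICAL
    if present:
        return NYSTAGMUS_UNIDIRECTIONAL
    return NYSTAGMUS_NONE


def classify_hints(
    impulses: Sequence[HeadImpulse],
    catch_up: CatchUpResult,
    nystagmus_findings: Mapping[str, NystagmusFinding],
    skew_finding: SkewFinding | None,
) -> HintsResult:
    """Combine the three exam components into the triage decision.

    Peripheral pattern: abnormal head-impulse test (catch-up saccades
    after adequate impulses) with unidirectional horizontal nystagmus and
    no skew.  Any dangerous sign -- normal head-impulse test in the
    presence of nystagmus, direction-changing or vertical nystagmus, or
    skew deviation -- forces the central pattern.  Anything else (notably
    an exam with no oculomotor abnormality at all) is indeterminate.
    """
    hit_testable = any(i.adequate for i in impulses) and not catch_up.not_testable
    hit_abnormal = hit_testable and catch_up.any_catch_up()
    nystagmus_class = classify_nystagmus(nystagmus_findings)
    any_nystagmus = nystagmus_class != NYSTAGMUS_NONE
    skew_present = skew_finding.present if skew_finding is not None else None

    evidence: dict[str, str] = {}
    evidence["head_impulse"] = (
        "not testable (no adequate impulse)" if not hit_testable
        else ("abnormal: catch-up saccades after adequate impulses"
              if hit_abnormal else "normal VOR on adequate impulses")
    )
    evidence["nystagmus"] = nystagmus_class
    evidence["skew"] = (
        "not testable" if skew_present is None
        else ("present" if skew_present else "absent")
    )

    dangerous = (
        (hit_testable and not hit_abnormal and any_nystagmus)
        or nystagmus_class in (NYSTAGMUS_DIRECTION_CHANGING, NYSTAGMUS_VERTICAL)
        or skew_present is True
    )
    if dangerous:
        triage = CENTRAL_PATTERN
    elif (
        hit_abnormal
        and nystagmus_class == NYSTAGMUS_UNIDIRECTIONAL
        and skew_present is False
    ):
        triage = PERIPHERAL_PATTERN
    else:
        triage = INDETERMINATE
        if not hit_testable and not any_nystagmus and skew_present is None:
            evidence["reason"] = (
                "no adequate impulses, no nystagmus, skew not testable"
            )
    return HintsResult(
        hit_abnormal=hit_abnormal,
        hit_testable=hit_testable,
        nystagmus_class=nystagmus_class,
        skew_present=skew_present,
        triage=triage,
        evidence=evidence,
    )
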
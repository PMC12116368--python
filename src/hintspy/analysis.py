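"""Whole-exam analysis: stages in, findings and a triage report out."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import detection as det
from . import kinematics as kin
from .config import AnalysisConfig
from .errors import HintsError, InsufficientDataError
from .recording_io import (
    FIXATION_STAGES,
    HIT_STAGES,
    Recording,
    STAGE_COVER_TEST,
    trim_initial,
)


@dataclass
class AnalysisReport:
    """Per-subject findings, triage and the configuration that produced them."""

    subject_id: str
    diagnosis_label: str
    hints: det.HintsResult
    nystagmus: dict[str, dict] = field(default_factory=dict)
    impulses: list[dict] = field(default_factory=list)
    catch_up_counts: dict[str, int] = field(default_factory=dict)
    skew: dict | None = None
    vor_gain: dict[str, float | None] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "diagnosis_label": self.diagnosis_label,
            "triage": self.hints.triage,
            "predicted_group": self.hints.predicted_group,
            "hints": self.hints.to_dict(),
            "nystagmus": self.nystagmus,
            "impulses": self.impulses,
            "catch_up_counts": self.catch_up_counts,
            "skew": self.skew,
            "vor_gain": self.vor_gain,
            "warnings": self.warnings,
            "config": self.config,
        }


def analyze_subject(
    stages: Mapping[str, Recording],
    config: AnalysisConfig | None = None,
    cover_times: Sequence[float] | None = None,
    subject_id: str | None = None,
    diagnosis_label: str | None = None,
) -> AnalysisReport:
    """Run the full detection pipeline on one subject's stage recordings.

    cover_times are absolute stage-times of the cover alternations (from
    the simulation log or an event-annotation sidecar); they are shifted
    by the initial-seconds trim automatically.  Missing stages degrade the
    corresponding finding to "not testable" instead of failing.
    """
    cfg = config or AnalysisConfig()
    thr = cfg.thresholds
    warnings: list[str] = []

    first = next(iter(stages.values()), None)
    if first is None:
        raise InsufficientDataError("no stage recordings supplied")
    subject_id = subject_id or first.subject_id
    diagnosis_label = diagnosis_label or first.diagnosis_label

    trimmed: dict[str, Recording] = {}
    for stage, rec in stages.items():
        try:
            trimmed[stage] = trim_initial(rec, cfg.trim_seconds)
        except HintsError as exc:
            warnings.append(f"{stage}: {exc}")

    # Nystagmus on the fixation stages, horizontal and vertical planes.
    nystagmus_findings: dict[str, det.NystagmusFinding] = {}
    nystagmus_report: dict[str, dict] = {}
    for stage in FIXATION_STAGES:
        rec = trimmed.get(stage)
        if rec is None:
            warnings.append(f"{stage}: missing, nystagmus not assessed")
            continue
        try:
            horiz = det.characterize_nystagmus(
                kin.gaze_component(rec, "horizontal-x", "left-plus-right"),
                plane="horizontal",
                min_beat_frequency=thr.nystagmus_min_beat_hz,
                sign_consistency=thr.nystagmus_sign_consistency,
                adaptive_lambda=thr.saccade_lambda,
            )
            vert = det.characterize_nystagmus(
                kin.gaze_component(rec, "vertical-y", "left-plus-right"),
                plane="vertical",
                min_beat_frequency=thr.nystagmus_min_beat_hz,
                sign_consistency=thr.nystagmus_sign_consistency,
                adaptive_lambda=thr.saccade_lambda,
            )
        except HintsError as exc:
            warnings.append(f"{stage}: nystagmus characterization failed: {exc}")
            continue
        finding = vert if vert.present else horiz
        finding.gaze_condition = stage
        nystagmus_findings[stage] = finding
        nystagmus_report[stage] = {
            "horizontal": horiz.to_dict(), "vertical": vert.to_dict(),
            "selected": finding.to_dict(),
        }

    # Head impulses and catch-up saccades, both sides pooled.
    all_impulses: list[det.HeadImpulse] = []
    merged_catch_up: dict[int, list[det.SaccadeEvent]] = {}
    impulse_report: list[dict] = []
    catch_up_counts: dict[str, int] = {}
    vor_gain: dict[str, float | None] = {}
    tested_any_side = False
    for stage in HIT_STAGES:
        rec = trimmed.get(stage)
        if rec is None:
            warnings.append(f"{stage}: missing, head impulses not testable")
            catch_up_counts[stage] = 0
            vor_gain[stage] = None
            continue
        try:
            head_vel = kin.head_yaw_velocity(rec)
            eye_vel = kin.eye_horizontal_velocity(rec, channel=cfg.eye_velocity_channel)
        except HintsError as exc:
            warnings.append(f"{stage}: velocity computation failed: {exc}")
            continue
        impulses = det.detect_head_impulses(
            head_vel,
            adequacy_threshold=thr.adequacy_deg_s,
            motion_floor=thr.motion_floor_deg_s,
        )
        catch_up = det.detect_catch_up_saccades(
            eye_vel, impulses,
            window=thr.catchup_window_s,
            adaptive_lambda=thr.saccade_lambda,
        )
        tested_any_side |= not catch_up.not_testable
        offset = len(all_impulses)
        for i, imp in enumerate(impulses):
            merged_catch_up[offset + i] = catch_up.by_impulse.get(i, [])
            entry = imp.to_dict()
            entry["stage"] = stage
            entry["catch_up_saccades"] = [
                s.to_dict() for s in catch_up.by_impulse.get(i, [])
            ]
            impulse_report.append(entry)
        all_impulses.extend(impulses)
        catch_up_counts[stage] = sum(
            len(v) for v in catch_up.by_impulse.values()
        )
        vor_gain[stage] = _mean_vor_gain(eye_vel, head_vel, impulses)

    merged = det.CatchUpResult(
        by_impulse=merged_catch_up, not_testable=not tested_any_side
    )

    # Skew on the cover-test stage.
    skew_finding: det.SkewFinding | None = None
    skew_report: dict | None = None
    rec = trimmed.get(STAGE_COVER_TEST)
    if rec is None:
        warnings.append("cover_test: missing, skew not testable")
    else:
        try:
            left_y, right_y = kin.vertical_position_by_eye(
                rec, channel=cfg.skew_channel
            )
            shifted = None
            if cover_times is not None:
                off = rec.quality.trim_offset
                shifted = [c - off for c in cover_times if c - off >= 0]
            skew_finding = det.detect_skew(
                left_y, right_y, cover_times=shifted,
                k=thr.skew_k, floor=cfg.skew_floor,
                lock_window=thr.skew_lock_window_s,
            )
            skew_report = skew_finding.to_dict()
        except HintsError as exc:
            warnings.append(f"cover_test: skew detection failed: {exc}")

    hints = det.classify_hints(
        all_impulses, merged, nystagmus_findings, skew_finding
    )
    return AnalysisReport(
        subject_id=subject_id,
        diagnosis_label=diagnosis_label,
        hints=hints,
        nystagmus=nystagmus_report,
        impulses=impulse_report,
        catch_up_counts=catch_up_counts,
        skew=skew_report,
        vor_gain=vor_gain,
        warnings=warnings,
        config=cfg.to_dict(),
    )


def _mean_vor_gain(
    eye_vel: kin.FeatureSeries,
    head_vel: kin.FeatureSeries,
    impulses: Sequence[det.HeadImpulse],
) -> float | None:
    """Supplementary evidence: |integrated eye| / |integrated head| per
    impulse, in the eye channel's own units per degree; reported but not
    used by the triage rule."""
    import numpy as np

    gains = []
    for imp in impulses:
        sel_h = (head_vel.timestamps >= imp.onset) & (head_vel.timestamps <= imp.offset)
        sel_e = (eye_vel.timestamps >= imp.onset) & (eye_vel.timestamps <= imp.offset)
        if sel_h.sum() < 2 or sel_e.sum() < 2:
            continue
        head_disp = np.trapezoid(head_vel.values[sel_h], head_vel.timestamps[sel_h])
        eye_disp = np.trapezoid(eye_vel.values[sel_e], eye_vel.timestamps[sel_e])
        if abs(head_disp) > 1e-9:
            gains.append(abs(eye_disp) / abs(head_disp))
    return float(np.mean(gains)) if gains else None


def summarize_cohort(reports: Sequence[AnalysisReport]) -> pd.DataFrame:
    """One row per subject: label, triage, prediction and key metrics."""
    rows = []
    for r in reports:
        rows.append({
            "subject_id": r.subject_id,
            "diagnosis_label": r.diagnosis_label,
            "triage": r.hints.triage,
            "predicted_group": r.hints.predicted_group,
            "hit_abnormal": r.hints.hit_abnormal,
            "nystagmus_class": r.hints.nystagmus_class,
            "skew_present": r.hints.skew_present,
            "n_impulses": len(r.impulses),
            "n_catch_up": sum(r.catch_up_counts.values()),
            "n_warnings": len(r.warnings),
        })
    return pd.DataFrame(rows)


# -- report schema ----------------------------------------------------------

def load_report_schema() -> dict:
    """The JSON schema every serialized report must satisfy."""
    text = resources.files("hintspy").joinpath("report_schema.json").read_text()
    return json.loads(text)


_TYPES = {
    "object": dict, "array": list, "string": str,
    "number": (int, float), "integer": int, "boolean": bool,
}


def validate_report_dict(report: dict, schema: dict | None = None, path: str = "$") -> None:
    """Structural validation against the shipped schema subset.

    Supports type, required, properties, items and nullable -- enough to
    pin the report contract without an external validator.  Raises
    ValueError at the first violation.
    """
    schema = schema if schema is not None else load_report_schema()
    if report is None:
        if schema.get("nullable"):
            return
        raise ValueError(f"{path}: null not allowed")
    expected = schema.get("type")
    if expected is not None:
        py = _TYPES[expected]
        if not isinstance(report, py) or (
            expected in ("number", "integer") and isinstance(report, bool)
        ):
            raise ValueError(
                f"{path}: expected {expected}, got {type(report).__name__}"
            )
    if expected == "object":
        for key in schema.get("required", []):
            if key not in report:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report_dict(report[key], sub, f"{path}.{key}")
    elif expected == "array":
        items = schema.get("items")
        if items is not None:
            for i, entry in enumerate(report):
                validate_report_dict(entry, items, f"{path}[{i}]")
    if "enum" in schema and report not in schema["enum"]:
        raise ValueError(f"{path}: {report!r} not in {schema['enum']}")


def write_report(report: AnalysisReport, path: str | Path) -> None:
    d = report.to_dict()
    validate_report_dict(d)
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True, default=_json_default))


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
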
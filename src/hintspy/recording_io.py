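"""Recording data model and CSV I/O for head-mounted-display exam captures.

A recording is one subject performing one stage of the ten-step exam
protocol, sampled nominally at 60 Hz.  Every frame carries the gaze ray
(origin + unit direction) of the left, right and combined eye, tracker
validity flags, and the head pose (position, Euler angles and quaternion).

Coordinate convention (shared by every module): right-handed, +y vertical,
-z forward, +x toward the wearer's right.  Angles are degrees everywhere
outside of internal trigonometry; timestamps are seconds from recording
start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    ConflictError,
    DataError,
    EmptyRecordingError,
    ParameterError,
    RecordingFormatError,
)

#: Canonical column order of the per-frame CSV export.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "t",
    "lx", "ly", "lz", "ldx", "ldy", "ldz",
    "rx", "ry", "rz", "rdx", "rdy", "rdz",
    "cx", "cy", "cz", "cdx", "cdy", "cdz",
    "hx", "hy", "hz",
    "yaw", "pitch", "roll",
    "qw", "qx", "qy", "qz",
    "lvalid", "rvalid",
)

#: Columns that may be absent from a file; they get a default instead.
_OPTIONAL_COLUMNS = {"lvalid": True, "rvalid": True}

#: Euler convention: intrinsic yaw (about +y), pitch (about +x), roll
#: (about +z), degrees.  Matches the shared right-handed frame.
EULER_SEQ = "YXZ"

DIR_NORM_TOL = 1e-3
QUAT_NORM_TOL = 1e-3
EULER_QUAT_TOL_DEG = 0.5


@dataclass(frozen=True)
class CsvDialect:
    """How a concrete CSV export maps onto the canonical schema.

    column_map maps canonical names to the file's column names; names not
    present map to themselves.  time_scale converts the file's time unit
    into seconds (e.g. 1e-3 for millisecond ticks).
    """

    column_map: Mapping[str, str] = field(default_factory=dict)
    time_scale: float = 1.0

    def file_column(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)


DEFAULT_DIALECT = CsvDialect()


@dataclass(frozen=True)
class FrameSample:
    """One 60 Hz sample of eye and head state."""

    timestamp: float
    left_origin: tuple[float, float, float]
    right_origin: tuple[float, float, float]
    combined_origin: tuple[float, float, float]
    left_dir: tuple[float, float, float]
    right_dir: tuple[float, float, float]
    combined_dir: tuple[float, float, float]
    left_valid: bool
    right_valid: bool
    head_position: tuple[float, float, float]
    head_euler: tuple[float, float, float]  # yaw, pitch, roll (deg)
    head_quat: tuple[float, float, float, float]  # w, x, y, z


@dataclass
class QualityReport:
    """Bookkeeping attached to a Recording by readers and validators."""

    rows_parsed: int = 0
    rows_dropped: int = 0
    invalid_direction_frames: list[int] = field(default_factory=list)
    euler_quat_mismatch_frames: list[int] = field(default_factory=list)
    rate_warning: str | None = None
    trim_offset: float = 0.0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rows_parsed": self.rows_parsed,
            "rows_dropped": self.rows_dropped,
            "invalid_direction_frames": list(self.invalid_direction_frames),
            "euler_quat_mismatch_frames": list(self.euler_quat_mismatch_frames),
            "rate_warning": self.rate_warning,
            "trim_offset": self.trim_offset,
            "warnings": list(self.warnings),
        }


@dataclass
class Recording:
    """Ordered frames of one subject performing one exam stage.

    The frame table is held as a pandas DataFrame with the canonical
    columns; vector-valued accessors return (N, 3) views.
    """

    subject_id: str
    segment: str
    diagnosis_label: str  # healthy | peripheral | central | unknown
    df: pd.DataFrame
    nominal_rate: float = 60.0
    quality: QualityReport = field(default_factory=QualityReport)

    def __post_init__(self) -> None:
        t = self.df["t"].to_numpy(float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise DataError("timestamps must be strictly increasing")

    # -- accessors ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.df)

    @property
    def timestamps(self) -> np.ndarray:
        return self.df["t"].to_numpy(float)

    @property
    def duration(self) -> float:
        t = self.timestamps
        return float(t[-1] - t[0]) if len(t) > 1 else 0.0

    def _vec(self, prefix: str, comps: Sequence[str]) -> np.ndarray:
        return self.df[[prefix + c if prefix else c for c in comps]].to_numpy(float)

    @property
    def left_origin(self) -> np.ndarray:
        return self.df[["lx", "ly", "lz"]].to_numpy(float)

    @property
    def right_origin(self) -> np.ndarray:
        return self.df[["rx", "ry", "rz"]].to_numpy(float)

    @property
    def combined_origin(self) -> np.ndarray:
        return self.df[["cx", "cy", "cz"]].to_numpy(float)

    @property
    def left_dir(self) -> np.ndarray:
        return self.df[["ldx", "ldy", "ldz"]].to_numpy(float)

    @property
    def right_dir(self) -> np.ndarray:
        return self.df[["rdx", "rdy", "rdz"]].to_numpy(float)

    @property
    def combined_dir(self) -> np.ndarray:
        return self.df[["cdx", "cdy", "cdz"]].to_numpy(float)

    @property
    def head_position(self) -> np.ndarray:
        return self.df[["hx", "hy", "hz"]].to_numpy(float)

    @property
    def head_euler(self) -> np.ndarray:
        return self.df[["yaw", "pitch", "roll"]].to_numpy(float)

    @property
    def head_quat(self) -> np.ndarray:
        return self.df[["qw", "qx", "qy", "qz"]].to_numpy(float)

    @property
    def left_valid(self) -> np.ndarray:
        return self.df["lvalid"].to_numpy(bool)

    @property
    def right_valid(self) -> np.ndarray:
        return self.df["rvalid"].to_numpy(bool)

    def valid_mask(self) -> np.ndarray:
        """Frames usable by kinematic operations.

        A frame is valid when both trackers report confidence and every
        gaze direction has unit norm within tolerance.  Invalid frames are
        retained in the table (timing structure is preserved) but skipped
        by kinematics.
        """
        ok = self.left_valid & self.right_valid
        for dirs in (self.left_dir, self.right_dir, self.combined_dir):
            norms = np.linalg.norm(dirs, axis=1)
            ok &= np.abs(norms - 1.0) <= DIR_NORM_TOL
        return ok

    def iter_frames(self) -> Iterator[FrameSample]:
        for row in self.df.itertuples(index=False):
            yield FrameSample(
                timestamp=row.t,
                left_origin=(row.lx, row.ly, row.lz),
                right_origin=(row.rx, row.ry, row.rz),
                combined_origin=(row.cx, row.cy, row.cz),
                left_dir=(row.ldx, row.ldy, row.ldz),
                right_dir=(row.rdx, row.rdy, row.rdz),
                combined_dir=(row.cdx, row.cdy, row.cdz),
                left_valid=bool(row.lvalid),
                right_valid=bool(row.rvalid),
                head_position=(row.hx, row.hy, row.hz),
                head_euler=(row.yaw, row.pitch, row.roll),
                head_quat=(row.qw, row.qx, row.qy, row.qz),
            )

    @property
    def frames(self) -> list[FrameSample]:
        return list(self.iter_frames())


# -- protocol ---------------------------------------------------------------

@dataclass(frozen=True)
class StageDescriptor:
    id: str
    name: str
    instruction: str
    duration: float  # nominal seconds


@dataclass(frozen=True)
class ExamProtocol:
    stages: tuple[StageDescriptor, ...]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.stages]
        if len(self.stages) != 10:
            raise ConflictError(
                f"exam protocol must have exactly 10 stages, got {len(self.stages)}"
            )
        if len(set(ids)) != len(ids):
            raise ConflictError("stage ids must be unique")

    @property
    def stage_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.stages)

    def __contains__(self, stage_id: str) -> bool:
        return stage_id in self.stage_ids


STAGE_START = "start"
STAGE_CALIBRATION = "calibration_check"
STAGE_SPONTANEOUS = "spontaneous"
STAGE_GAZE_LEFT = "gaze_left"
STAGE_GAZE_RIGHT = "gaze_right"
STAGE_GAZE_NOSE = "gaze_nose"
STAGE_HIT_LEFT = "hit_left"
STAGE_HIT_RIGHT = "hit_right"
STAGE_COVER_TEST = "cover_test"
STAGE_SAVE = "save"

#: Stages during which the subject fixates and nystagmus is assessed.
FIXATION_STAGES = (
    STAGE_SPONTANEOUS,
    STAGE_GAZE_LEFT,
    STAGE_GAZE_RIGHT,
    STAGE_GAZE_NOSE,
)
HIT_STAGES = (STAGE_HIT_LEFT, STAGE_HIT_RIGHT)


def default_protocol() -> ExamProtocol:
    """The ten-step exam protocol: bookkeeping, fixation, impulses, cover."""
    return ExamProtocol(stages=(
        StageDescriptor(STAGE_START, "Start", "Put on the headset and hold still.", 3.0),
        StageDescriptor(STAGE_CALIBRATION, "Calibration check",
                        "Fixate the calibration target.", 3.0),
        StageDescriptor(STAGE_SPONTANEOUS, "Spontaneous nystagmus",
                        "Look straight ahead at the examiner's nose.", 10.0),
        StageDescriptor(STAGE_GAZE_LEFT, "Gaze left",
                        "Follow the examiner's finger to your left and hold.", 10.0),
        StageDescriptor(STAGE_GAZE_RIGHT, "Gaze right",
                        "Follow the examiner's finger to your right and hold.", 10.0),
        StageDescriptor(STAGE_GAZE_NOSE, "Fixation at nose",
                        "Fixate the examiner's nose.", 10.0),
        StageDescriptor(STAGE_HIT_LEFT, "Head impulse left",
                        "Keep fixating the nose; the examiner turns your head left.", 26.0),
        StageDescriptor(STAGE_HIT_RIGHT, "Head impulse right",
                        "Keep fixating the nose; the examiner turns your head right.", 26.0),
        StageDescriptor(STAGE_COVER_TEST, "Alternating cover test",
                        "Fixate the nose while each eye is covered in turn.", 16.5),
        StageDescriptor(STAGE_SAVE, "Save", "Hold still while data is saved.", 3.0),
    ))


# -- validation -------------------------------------------------------------

def validate_recording(rec: Recording) -> QualityReport:
    """Check frame invariants; returns a fresh report, never mutates rec.

    Flags frames whose gaze direction norm is off-unit despite a true
    validity flag, frames whose Euler and quaternion orientations disagree
    by more than 0.5 deg, and attaches a rate warning when the median
    inter-frame interval deviates more than 20% from the nominal rate.
    """
    report = QualityReport(rows_parsed=rec.n_frames)
    if rec.n_frames == 0:
        raise EmptyRecordingError("recording has no frames")

    flagged: set[int] = set()
    for dirs, valid in (
        (rec.left_dir, rec.left_valid),
        (rec.right_dir, rec.right_valid),
        (rec.combined_dir, rec.left_valid & rec.right_valid),
    ):
        norms = np.linalg.norm(dirs, axis=1)
        bad = valid & (np.abs(norms - 1.0) > DIR_NORM_TOL)
        flagged.update(np.nonzero(bad)[0].tolist())
    report.invalid_direction_frames = sorted(flagged)

    qn = np.linalg.norm(rec.head_quat, axis=1)
    bad_q = np.abs(qn - 1.0) > QUAT_NORM_TOL
    if np.any(bad_q):
        report.warnings.append(
            f"{int(bad_q.sum())} frame(s) with non-unit head quaternion"
        )

    mismatch = _euler_quat_mismatch(rec.head_euler, rec.head_quat)
    report.euler_quat_mismatch_frames = np.nonzero(mismatch)[0].tolist()
    if report.euler_quat_mismatch_frames:
        report.warnings.append(
            f"{len(report.euler_quat_mismatch_frames)} frame(s) where Euler "
            f"and quaternion orientations disagree by > {EULER_QUAT_TOL_DEG} deg"
        )

    if rec.n_frames >= 2:
        med = float(np.median(np.diff(rec.timestamps)))
        nominal = 1.0 / rec.nominal_rate
        if abs(med - nominal) > 0.2 * nominal:
            report.rate_warning = (
                f"median inter-frame interval {med:.5f}s deviates more than "
                f"20% from nominal {nominal:.5f}s"
            )
    return report


def _euler_quat_mismatch(euler_deg: np.ndarray, quat_wxyz: np.ndarray) -> np.ndarray:
    """True where the two orientation encodings differ by > 0.5 deg."""
    r_euler = Rotation.from_euler(EULER_SEQ, euler_deg, degrees=True)
    # scipy expects (x, y, z, w)
    q = quat_wxyz[:, [1, 2, 3, 0]]
    norms = np.linalg.norm(q, axis=1)
    safe = np.where(norms[:, None] > 0, q / np.maximum(norms, 1e-12)[:, None], [[0, 0, 0, 1]])
    r_quat = Rotation.from_quat(safe)
    angles = np.degrees((r_euler.inv() * r_quat).magnitude())
    return angles > EULER_QUAT_TOL_DEG


# -- I/O --------------------------------------------------------------------

def read_recording(
    path: str | Path,
    dialect: CsvDialect = DEFAULT_DIALECT,
    *,
    subject_id: str = "unknown",
    segment: str = "unknown",
    diagnosis_label: str = "unknown",
    nominal_rate: float = 60.0,
) -> Recording:
    """Read a per-frame CSV export into a Recording.

    Rows with unparseable numerics are dropped and counted in the quality
    report.  Missing mandatory columns raise RecordingFormatError naming
    them; a file with zero parseable rows raises EmptyRecordingError.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [
        c for c in CANONICAL_COLUMNS
        if dialect.file_column(c) not in raw.columns and c not in _OPTIONAL_COLUMNS
    ]
    if missing:
        raise RecordingFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )

    df = pd.DataFrame()
    for canonical in CANONICAL_COLUMNS:
        col = dialect.file_column(canonical)
        if col not in raw.columns:
            df[canonical] = _OPTIONAL_COLUMNS[canonical]
            continue
        if canonical in ("lvalid", "rvalid"):
            df[canonical] = (
                raw[col].str.strip().str.lower().isin(("1", "true", "t", "yes"))
            )
        else:
            df[canonical] = pd.to_numeric(raw[col], errors="coerce")

    numeric_cols = [c for c in CANONICAL_COLUMNS if c not in ("lvalid", "rvalid")]
    good = ~df[numeric_cols].isna().any(axis=1)
    dropped = int((~good).sum())
    df = df.loc[good].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyRecordingError(f"{path}: no parseable data rows")

    t = df["t"].to_numpy(float) * dialect.time_scale
    df["t"] = t - t[0]

    rec = Recording(
        subject_id=subject_id,
        segment=segment,
        diagnosis_label=diagnosis_label,
        df=df,
        nominal_rate=nominal_rate,
    )
    report = validate_recording(rec)
    report.rows_parsed = len(df)
    report.rows_dropped = dropped
    rec.quality = report
    return rec


def write_recording(
    rec: Recording, path: str | Path, dialect: CsvDialect = DEFAULT_DIALECT
) -> None:
    """Write a Recording as header + one CSV row per frame.

    Floats use shortest round-tripping repr, so read(write(r)) is lossless
    well below 1e-9 per field.
    """
    if rec.n_frames == 0:
        raise EmptyRecordingError("refusing to write a recording with no frames")
    out = rec.df.copy()
    out["t"] = out["t"] / dialect.time_scale
    out["lvalid"] = out["lvalid"].astype(int)
    out["rvalid"] = out["rvalid"].astype(int)
    out.columns = [dialect.file_column(c) for c in out.columns]
    out.to_csv(path, index=False)


def trim_initial(rec: Recording, trim_seconds: float) -> Recording:
    """Drop the noisy initial seconds and re-zero timestamps.

    The first moments of each stage contain voice-prompt adherence
    artifacts and are excluded from analysis.  The amount already trimmed
    is tracked in the quality report, making repeated application with the
    same trim_seconds idempotent.
    """
    if trim_seconds < 0:
        raise ParameterError(f"trim_seconds must be >= 0, got {trim_seconds}")
    effective = trim_seconds - rec.quality.trim_offset
    if effective <= 0:
        return rec
    t = rec.timestamps
    keep = t >= effective
    if not np.any(keep):
        raise EmptyRecordingError(
            f"trimming {trim_seconds}s removes all frames "
            f"({rec.duration:.2f}s recording)"
        )
    df = rec.df.loc[keep].reset_index(drop=True)
    removed = float(df["t"].iloc[0])
    df = df.copy()
    df["t"] = df["t"] - removed
    new_quality = replace(
        rec.quality,
        trim_offset=rec.quality.trim_offset + removed,
        invalid_direction_frames=[],
        euler_quat_mismatch_frames=[],
    )
    return Recording(
        subject_id=rec.subject_id,
        segment=rec.segment,
        diagnosis_label=rec.diagnosis_label,
        df=df,
        nominal_rate=rec.nominal_rate,
        quality=new_quality,
    )


def segment_stages(
    recs: Sequence[Recording], protocol: ExamProtocol
) -> tuple[dict[str, Recording], list[str]]:
    """Key recordings by protocol stage.

    Returns (stage -> Recording, missing stage ids).  Duplicate stage
    labels for one subject raise ConflictError; a label not in the
    protocol raises RecordingFormatError.
    """
    out: dict[str, Recording] = {}
    for rec in recs:
        if rec.segment not in protocol:
            raise RecordingFormatError(
                f"segment label {rec.segment!r} not in protocol "
                f"{protocol.stage_ids}"
            )
        if rec.segment in out:
            raise ConflictError(
                f"duplicate recordings for stage {rec.segment!r} "
                f"(subject {rec.subject_id})"
            )
        out[rec.segment] = rec
    missing = [s for s in protocol.stage_ids if s not in out]
    return out, missing


# -- sidecar metadata -------------------------------------------------------

def write_subject_metadata(path: str | Path, meta: dict) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_subject_metadata(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
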
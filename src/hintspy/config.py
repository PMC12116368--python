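"""One configuration block drives every threshold in the pipeline.

The upstream analysis is visual and fixes almost no operating point; to
make it reproducible, every detection threshold is an explicit, logged
default here, overridable from a YAML file.  Reports embed the resolved
configuration so a report plus its inputs reproduces itself.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .recording_io import CsvDialect


@dataclass
class DetectionThresholds:
    """Every tunable decision point of the detection module.

    saccade_lambda: adaptive saccade threshold in robust SDs of |velocity|.
    motion_floor_deg_s: minimum head angular speed treated as an impulse.
    adequacy_deg_s: peak head velocity an impulse must reach to count.
    catchup_window_s: window after the impulse peak searched for
        corrective saccades.
    nystagmus_min_beat_hz / nystagmus_sign_consistency: presence rule for
        nystagmus (recurring fast phases; one-signed slow-phase drift).
    skew_k: skew step threshold in robust noise SDs.
    skew_floor_m / skew_floor_component: absolute skew floors for the
        position (metres) and direction (unit-vector component) channels.
    skew_lock_window_s: tolerance for time-locking steps to cover switches.
    """

    saccade_lambda: float = 5.0
    motion_floor_deg_s: float = 20.0
    adequacy_deg_s: float = 150.0
    catchup_window_s: float = 0.5
    nystagmus_min_beat_hz: float = 0.5
    nystagmus_sign_consistency: float = 0.8
    skew_k: float = 3.0
    skew_floor_m: float = 0.00025
    skew_floor_component: float = 0.005
    skew_lock_window_s: float = 0.25


@dataclass
class AnalysisConfig:
    trim_seconds: float = 2.0
    nominal_rate: float = 60.0
    eye_velocity_channel: str = "origin"  # origin | direction
    skew_channel: str = "origin"  # origin | direction
    au_eye_factor: float = 1000.0
    au_head_factor: float = 1.0
    thresholds: DetectionThresholds = field(default_factory=DetectionThresholds)
    dialect: CsvDialect = field(default_factory=CsvDialect)

    def __post_init__(self) -> None:
        if self.trim_seconds < 0:
            raise ParameterError("trim_seconds must be >= 0")
        if self.nominal_rate <= 0:
            raise ParameterError("nominal_rate must be > 0")
        if self.eye_velocity_channel not in ("origin", "direction"):
            raise ParameterError(
                f"eye_velocity_channel must be origin or direction, "
                f"got {self.eye_velocity_channel!r}"
            )
        if self.skew_channel not in ("origin", "direction"):
            raise ParameterError(
                f"skew_channel must be origin or direction, got {self.skew_channel!r}"
            )

    @property
    def skew_floor(self) -> float:
        t = self.thresholds
        return t.skew_floor_m if self.skew_channel == "origin" else t.skew_floor_component

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dialect"] = {
            "column_map": dict(self.dialect.column_map),
            "time_scale": self.dialect.time_scale,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        thr = d.pop("thresholds", {})
        dia = d.pop("dialect", {})
        known_thr = DetectionThresholds.__dataclass_fields__
        unknown = set(thr) - set(known_thr)
        if unknown:
            raise ParameterError(f"unknown threshold field(s): {sorted(unknown)}")
        known = set(cls.__dataclass_fields__) - {"thresholds", "dialect"}
        bad = set(d) - known
        if bad:
            raise ParameterError(f"unknown config field(s): {sorted(bad)}")
        return cls(
            thresholds=DetectionThresholds(**thr),
            dialect=CsvDialect(
                column_map=dia.get("column_map", {}),
                time_scale=dia.get("time_scale", 1.0),
            ),
            **d,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
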
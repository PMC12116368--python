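"""Figure-style panels: impulse overlay, nystagmus traces, skew traces."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import kinematics as kin
from .config import AnalysisConfig
from .recording_io import Recording

PLOT_KINDS = ("hit-overlay", "nystagmus-x", "nystagmus-y", "skew")


def plot_stage(
    rec: Recording,
    kind: str,
    out_file: str | Path,
    config: AnalysisConfig | None = None,
) -> None:
    """Render one panel for a stage recording.

    hit-overlay: mean-centered, rescaled eye and head velocities on one
    arbitrary-unit axis; nystagmus-x / nystagmus-y: the centered
    horizontal / vertical gaze component; skew: per-eye centered vertical
    position.
    """
    cfg = config or AnalysisConfig()
    fig, ax = plt.subplots(figsize=(8, 3.2), constrained_layout=True)
    if kind == "hit-overlay":
        eye = kin.eye_horizontal_velocity(rec, channel=cfg.eye_velocity_channel)
        head = kin.head_yaw_velocity(rec)
        eye_au, head_au = kin.hit_overlay(
            eye, head, cfg.au_eye_factor, cfg.au_head_factor
        )
        ax.plot(eye_au.timestamps, eye_au.values,
                label=f"eye velocity x{eye_au.scale_factor:g}", lw=0.8)
        ax.plot(head_au.timestamps, head_au.values,
                label=f"head yaw velocity x{head_au.scale_factor:g}", lw=0.8)
        ax.set_ylabel("velocity (AU)")
    elif kind in ("nystagmus-x", "nystagmus-y"):
        axis = "horizontal-x" if kind == "nystagmus-x" else "vertical-y"
        series = kin.gaze_component(rec, axis, "left-plus-right")
        ax.plot(series.timestamps, series.values, lw=0.8,
                label=f"gaze {axis} (L+R, centered)")
        ax.set_ylabel(series.units)
    elif kind == "skew":
        left_y, right_y = kin.vertical_position_by_eye(rec, channel=cfg.skew_channel)
        ax.plot(left_y.timestamps, left_y.values, lw=0.8, label="left eye y")
        ax.plot(right_y.timestamps, right_y.values, lw=0.8, label="right eye y")
        ax.set_ylabel(left_y.units)
    else:
        raise ValueError(f"unknown plot kind {kind!r}; choose from {PLOT_KINDS}")
    ax.set_xlabel("time (s)")
    ax.set_title(f"{rec.subject_id} / {rec.segment} — {kind}")
    ax.legend(loc="upper right", fontsize=8)
    fig.savefig(out_file, dpi=120)
    plt.close(fig)
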
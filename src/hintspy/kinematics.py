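"""Per-frame feature series: velocities, gaze components, vertical position.

All series are computed from the raw samples without smoothing or artifact
correction; the only preprocessing is exclusion of tracker-invalid frames
and, for head yaw, unwrapping across the +-180 deg discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import AlignmentError, DataError, InsufficientDataError
from .recording_io import Recording

VALID_UNITS = ("m/s", "deg/s", "AU", "unit-vector component", "unit-vector component/s", "m")


@dataclass(frozen=True)
class FeatureSeries:
    """A uniformly-typed time series of one scalar feature."""

    timestamps: np.ndarray
    values: np.ndarray
    units: str
    centered: bool = False
    scale_factor: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, float)
        v = np.asarray(self.values, float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)
        if len(t) != len(v):
            raise DataError("timestamps and values must have equal length")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise DataError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if len(self) > 1 else 0.0


def finite_difference(
    values: np.ndarray, timestamps: np.ndarray, units: str = "units/s", source: str = ""
) -> FeatureSeries:
    """Differentiate a sampled signal with second-order finite differences.

    Central differences at interior points and one-sided differences at
    the ends, honouring the actual (possibly irregular) inter-sample
    intervals.  Exact for polynomials of degree <= 2 at interior points.
    """
    t = np.asarray(timestamps, float)
    v = np.asarray(values, float)
    if len(v) < 2:
        raise InsufficientDataError("need at least 2 samples to differentiate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError("zero or negative inter-sample interval")
    dv = np.gradient(v, t, edge_order=2) if len(v) >= 3 else np.gradient(v, t)
    return FeatureSeries(timestamps=t, values=dv, units=units, source=source)


def mean_center(series: FeatureSeries) -> FeatureSeries:
    """Subtract the arithmetic mean; idempotent and linear."""
    if len(series) == 0:
        raise InsufficientDataError("cannot center an empty series")
    return replace(series, values=series.values - series.values.mean(), centered=True)


def eye_horizontal_velocity(rec: Recording, channel: str = "origin") -> FeatureSeries:
    """Horizontal eye velocity of the combined eye.

    Finite difference of the x component of the combined gaze-ray origin
    (metres, the default) or of the combined gaze direction, over frames
    where both eye trackers are valid.
    """
    mask = rec.valid_mask()
    if mask.sum() < 2:
        raise InsufficientDataError("fewer than 2 valid frames")
    t = rec.timestamps[mask]
    if channel == "origin":
        x = rec.combined_origin[mask, 0]
        units = "m/s"
    elif channel == "direction":
        x = rec.combined_dir[mask, 0]
        units = "unit-vector component/s"
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return finite_difference(
        x, t, units=units, source=f"eye horizontal velocity ({channel} x)"
    )


def head_yaw_velocity(rec: Recording) -> FeatureSeries:
    """Angular head velocity about the vertical axis, deg/s.

    The yaw Euler series is unwrapped across the +-180 deg discontinuity
    before differencing, so a crossing from +179 to -179 deg reads as a
    +2 deg step, not a -358 deg jump.
    """
    if rec.n_frames < 2:
        raise InsufficientDataError("fewer than 2 frames")
    yaw = np.unwrap(rec.head_euler[:, 0], period=360.0)
    return finite_difference(
        yaw, rec.timestamps, units="deg/s", source="head yaw velocity"
    )


def hit_overlay(
    eye_vel: FeatureSeries,
    head_vel: FeatureSeries,
    eye_factor: float = 1000.0,
    head_factor: float = 1.0,
) -> tuple[FeatureSeries, FeatureSeries]:
    """Mean-centered, rescaled eye/head velocity overlay in arbitrary units.

    Eye linear velocity (m/s) and head angular velocity (deg/s) live on
    very different scales; each is centered and multiplied by its factor
    so the two pulses can be read off one axis.  The factors are recorded
    in scale_factor.  Series are aligned on the intersection of their
    timestamps (they may differ after invalid-frame exclusion).
    """
    common, ie, ih = np.intersect1d(
        eye_vel.timestamps, head_vel.timestamps, return_indices=True
    )
    if len(common) == 0:
        raise AlignmentError("eye and head velocity series share no timestamps")

    def _scaled(series: FeatureSeries, idx: np.ndarray, factor: float) -> FeatureSeries:
        vals = series.values[idx]
        vals = (vals - vals.mean()) * factor
        return FeatureSeries(
            timestamps=common,
            values=vals,
            units="AU",
            centered=True,
            scale_factor=factor,
            source=series.source + " (AU overlay)",
        )

    return _scaled(eye_vel, ie, eye_factor), _scaled(head_vel, ih, head_factor)


_AXIS_INDEX = {"horizontal-x": 0, "x": 0, "vertical-y": 1, "y": 1}


def gaze_component(rec: Recording, axis: str, eye: str = "left-plus-right") -> FeatureSeries:
    """Mean-centered gaze-direction component over time.

    axis selects the horizontal (x) or vertical (y) unit-vector component;
    eye one of left / right / combined / left-plus-right, the last being
    the per-frame sum of the two monocular components (twice the conjugate
    signal, which doubles nystagmus amplitude relative to sensor noise).
    """
    try:
        col = _AXIS_INDEX[axis]
    except KeyError:
        raise ValueError(f"axis must be horizontal-x or vertical-y, got {axis!r}")

    if eye == "left":
        mask = rec.left_valid
        vals = rec.left_dir[:, col]
    elif eye == "right":
        mask = rec.right_valid
        vals = rec.right_dir[:, col]
    elif eye == "combined":
        mask = rec.left_valid & rec.right_valid
        vals = rec.combined_dir[:, col]
    elif eye == "left-plus-right":
        mask = rec.left_valid & rec.right_valid
        vals = rec.left_dir[:, col] + rec.right_dir[:, col]
    else:
        raise ValueError(f"unknown eye selector {eye!r}")

    if mask.sum() == 0:
        raise InsufficientDataError("no frames with the required eye(s) valid")
    series = FeatureSeries(
        timestamps=rec.timestamps[mask],
        values=vals[mask],
        units="unit-vector component",
        source=f"gaze {axis} component ({eye}), stage {rec.segment}",
    )
    return mean_center(series)


def vertical_position_by_eye(
    rec: Recording, channel: str = "origin"
) -> tuple[FeatureSeries, FeatureSeries]:
    """Per-eye vertical (y) position over time, baseline-centered at zero.

    The primary channel is the gaze-ray origin (metres); the gaze-direction
    y component is available as a secondary channel.  Vertical divergence
    between the two series during alternating occlusion is the skew
    deviation signature.
    """
    out = []
    for name, mask, origin, direction in (
        ("left", rec.left_valid, rec.left_origin, rec.left_dir),
        ("right", rec.right_valid, rec.right_origin, rec.right_dir),
    ):
        if mask.sum() == 0:
            raise InsufficientDataError(f"no valid frames for {name} eye")
        if channel == "origin":
            vals, units = origin[mask, 1], "m"
        elif channel == "direction":
            vals, units = direction[mask, 1], "unit-vector component"
        else:
            raise ValueError(f"unknown channel {channel!r}")
        series = FeatureSeries(
            timestamps=rec.timestamps[mask],
            values=vals,
            units=units,
            source=f"{name} eye vertical position ({channel} y)",
        )
        out.append(mean_center(series))
    return out[0], out[1]


def estimate_fixation_depth(rec: Recording) -> float:
    """Median triangulated fixation distance (metres) from eye vergence.

    Intersects the left and right gaze rays in the horizontal plane frame
    by frame and returns the median forward distance of the crossing point
    in front of the eyes.  A converged fixation at the examiner's nose at
    arm's reach yields roughly 0.4 m.
    """
    mask = rec.valid_mask()
    if mask.sum() < 1:
        raise InsufficientDataError("no valid frames")
    oL, oR = rec.left_origin[mask], rec.right_origin[mask]
    dL, dR = rec.left_dir[mask], rec.right_dir[mask]
    # Solve oL + s*dL = oR + u*dR in the x-z plane.
    a, b = dL[:, 0], -dR[:, 0]
    c, d = dL[:, 2], -dR[:, 2]
    det = a * d - b * c
    rhs_x = oR[:, 0] - oL[:, 0]
    rhs_z = oR[:, 2] - oL[:, 2]
    ok = np.abs(det) > 1e-12
    if not np.any(ok):
        raise InsufficientDataError("gaze rays are parallel; no vergence")
    s = (rhs_x[ok] * d[ok] - rhs_z[ok] * b[ok]) / det[ok]
    z_cross = oL[ok, 2] + s * dL[ok, 2]
    depth = oL[ok, 2] - z_cross  # forward is -z
    return float(np.median(depth))
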
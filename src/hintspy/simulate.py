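"""Synthetic 60 Hz exam recordings with ground-truth event logs.

Generates idealized oculomotor traces for three subject profiles --
healthy, acute peripheral vestibular dysfunction, and central (stroke) --
across all ten protocol stages, replacing the headset for testing:

* nystagmus as an ideal sawtooth (linear slow drift at the slow-phase
  velocity, fast reset over two frames),
* head impulses as flat-topped raised-cosine yaw velocity pulses with a
  vestibulo-ocular eye response at the profile's per-side gain and, when
  the gain is deficient, a corrective saccade after each impulse,
* skew deviation as a vertical offset of the covered eye during the
  alternating cover test, with 100 ms refixation ramps,
* i.i.d. Gaussian sensor noise per component per frame and an optional
  voice-prompt drift artifact in the first 1.5 s of each stage.

Every generator is deterministic in (parameters, seed); the seed drives
only the noise realization, never the event structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .errors import ParameterError
from .recording_io import (
    CANONICAL_COLUMNS,
    EULER_SEQ,
    ExamProtocol,
    FIXATION_STAGES,
    Recording,
    STAGE_CALIBRATION,
    STAGE_COVER_TEST,
    STAGE_GAZE_LEFT,
    STAGE_GAZE_NOSE,
    STAGE_GAZE_RIGHT,
    STAGE_HIT_LEFT,
    STAGE_HIT_RIGHT,
    STAGE_SAVE,
    STAGE_SPONTANEOUS,
    STAGE_START,
    default_protocol,
    write_recording,
    write_subject_metadata,
)

# -- geometry constants (documented in the methods note) --------------------

#: Inter-pupillary distance, metres.
IPD = 0.063
#: Fixation target (the examiner's nose) distance straight ahead, metres.
FIXATION_DISTANCE = 0.40
#: Gaze-ray origins trace a scaled copy of the gaze-direction signal:
#: metres of origin displacement per unit-vector component.
ORIGIN_SCALE = 0.05
#: Eccentric gaze azimuth for the gaze-left/right stages, degrees.
GAZE_ECCENTRICITY_DEG = 15.0
#: Voice-prompt drift artifact: duration (s) and amplitude (components).
ARTIFACT_DURATION = 1.5
ARTIFACT_AMPLITUDE = 0.05
ARTIFACT_YAW_DEG = 2.0

_EYE_BASE = {
    "left": np.array([-IPD / 2, 0.0, 0.0]),
    "right": np.array([IPD / 2, 0.0, 0.0]),
    "combined": np.array([0.0, 0.0, 0.0]),
}


@dataclass(frozen=True)
class SimulationProfile:
    """Generative parameters for one synthetic subject.

    spv is the single-eye slow-phase velocity in unit-vector components
    per second (0.087/s corresponds to about 5 deg/s); skew_offset is the
    vertical deviation of the covered eye in the same component units.
    """

    group: str  # healthy | peripheral | central
    spv: float = 0.0
    beat_frequency: float = 2.0
    beat_plane: str = "horizontal"
    beat_direction: int = 1  # fast-phase sign; -1 means down for vertical
    direction_changing: bool = False
    vor_gain_left: float = 1.0
    vor_gain_right: float = 1.0
    skew_offset: float = 0.0
    noise_sd: float = 0.002
    sample_rate: float = 60.0
    impulse_peak_velocity: float = 200.0
    n_impulses: int = 5
    artifact: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.group not in ("healthy", "peripheral", "central"):
            raise ParameterError(f"unknown group {self.group!r}")
        if not (0 <= self.vor_gain_left <= 1.2 and 0 <= self.vor_gain_right <= 1.2):
            raise ParameterError("VOR gains must lie in [0, 1.2]")
        if self.spv < 0 or self.noise_sd < 0 or self.skew_offset < 0:
            raise ParameterError("spv, noise_sd and skew_offset must be >= 0")
        if self.sample_rate <= 0 or self.beat_frequency < 0:
            raise ParameterError("sample_rate must be > 0 and beat_frequency >= 0")
        if self.beat_plane not in ("horizontal", "vertical"):
            raise ParameterError(f"unknown beat_plane {self.beat_plane!r}")
        if self.group == "healthy" and (
            self.spv != 0 or self.skew_offset != 0
            or self.vor_gain_left != 1.0 or self.vor_gain_right != 1.0
        ):
            raise ParameterError("healthy profile must have no pathological signs")
        if self.group == "peripheral" and not (
            self.spv > 0 and self.beat_plane == "horizontal"
            and not self.direction_changing and self.skew_offset == 0
            and min(self.vor_gain_left, self.vor_gain_right) < 0.8
        ):
            raise ParameterError(
                "peripheral profile needs horizontal unidirectional nystagmus, "
                "one deficient VOR gain and no skew"
            )
        if self.group == "central" and not (
            (self.direction_changing or self.beat_plane == "vertical")
            and self.vor_gain_left == 1.0 and self.vor_gain_right == 1.0
            and self.skew_offset > 0
        ):
            raise ParameterError(
                "central profile needs direction-changing or vertical nystagmus, "
                "intact VOR and a skew offset"
            )

    @classmethod
    def healthy(cls, noise_sd: float = 0.002, **kw) -> "SimulationProfile":
        return cls(group="healthy", spv=0.0, noise_sd=noise_sd, **kw)

    @classmethod
    def peripheral(
        cls,
        spv: float = 0.08,
        beat_frequency: float = 2.0,
        lesion_side: str = "left",
        lesion_gain: float = 0.4,
        noise_sd: float = 0.002,
        **kw,
    ) -> "SimulationProfile":
        """Acute peripheral loss: unidirectional horizontal nystagmus
        beating away from the lesioned ear, deficient ipsilesional VOR."""
        gains = {"left": 1.0, "right": 1.0}
        gains[lesion_side] = lesion_gain
        beat = 1 if lesion_side == "left" else -1
        return cls(
            group="peripheral", spv=spv, beat_frequency=beat_frequency,
            beat_plane="horizontal", beat_direction=beat,
            vor_gain_left=gains["left"], vor_gain_right=gains["right"],
            noise_sd=noise_sd, **kw,
        )

    @classmethod
    def central(
        cls,
        variant: str = "direction-changing",
        spv: float = 0.08,
        beat_frequency: float = 2.0,
        skew_offset: float = 0.02,
        noise_sd: float = 0.002,
        **kw,
    ) -> "SimulationProfile":
        """Central (stroke) pattern: gaze-evoked direction-changing or
        down-beating nystagmus, intact VOR, skew deviation."""
        if variant == "direction-changing":
            return cls(
                group="central", spv=spv, beat_frequency=beat_frequency,
                beat_plane="horizontal", direction_changing=True,
                skew_offset=skew_offset, noise_sd=noise_sd, **kw,
            )
        if variant == "downbeat":
            return cls(
                group="central", spv=spv, beat_frequency=beat_frequency,
                beat_plane="vertical", beat_direction=-1,
                skew_offset=skew_offset, noise_sd=noise_sd, **kw,
            )
        raise ParameterError(f"unknown central variant {variant!r}")


@dataclass
class GroundTruth:
    """Per-stage event log: the oracle every detector is tested against."""

    stage: str
    params: dict = field(default_factory=dict)
    fast_phases: list[float] = field(default_factory=list)
    impulses: list[dict] = field(default_factory=list)
    corrective_saccades: list[dict] = field(default_factory=list)
    cover_switches: list[float] = field(default_factory=list)
    cover_schedule: list[dict] = field(default_factory=list)
    refixations: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "params": self.params,
            "fast_phases": self.fast_phases,
            "impulses": self.impulses,
            "corrective_saccades": self.corrective_saccades,
            "cover_switches": self.cover_switches,
            "cover_schedule": self.cover_schedule,
            "refixations": self.refixations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


# -- waveform primitives ----------------------------------------------------

def _sawtooth(
    n: int, rate: float, spv: float, freq: float, direction: int
) -> tuple[np.ndarray, list[float]]:
    """Ideal nystagmus sawtooth: linear slow drift, 2-frame fast reset.

    Returns the position series (zero-mean-ish, amplitude spv/freq) and
    the fast-phase peak-velocity times.
    """
    pos = np.zeros(n)
    if spv <= 0 or freq <= 0 or n < 3:
        return pos, []
    dt = 1.0 / rate
    period = 1.0 / freq
    amp = spv * (period - 2 * dt)  # closure: slow drift equals fast reset
    resets = []
    k = 1
    while True:
        r = int(round(k * period * rate))
        if r + 2 >= n:
            break
        resets.append(r)
        k += 1
    fast_frames = np.zeros(n, bool)
    for r in resets:
        fast_frames[r + 1] = True
        fast_frames[r + 2] = True
    cur = direction * amp / 2
    pos[0] = cur
    for i in range(1, n):
        cur += direction * amp / 2 if fast_frames[i] else -direction * spv * dt
        pos[i] = cur
    fast_times = [(r + 1) * dt for r in resets]
    return pos, fast_times


def _artifact_bump(t: np.ndarray, amplitude: float) -> np.ndarray:
    """Half-sine drift transient emulating voice-prompt adherence."""
    out = np.zeros_like(t)
    mask = t < ARTIFACT_DURATION
    out[mask] = amplitude * np.sin(np.pi * t[mask] / ARTIFACT_DURATION)
    return out


def _stage_target(stage: str) -> np.ndarray:
    """World position the subject fixates during a stage."""
    if stage == STAGE_GAZE_LEFT:
        az = -np.radians(GAZE_ECCENTRICITY_DEG)
    elif stage == STAGE_GAZE_RIGHT:
        az = np.radians(GAZE_ECCENTRICITY_DEG)
    else:
        az = 0.0
    return FIXATION_DISTANCE * np.array([np.sin(az), 0.0, -np.cos(az)])


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _build_recording(
    *,
    subject_id: str,
    stage: str,
    diagnosis: str,
    t: np.ndarray,
    h: dict[str, np.ndarray],
    w: dict[str, np.ndarray],
    yaw_deg: np.ndarray,
    rate: float,
    noise_sd: float,
    rng: np.random.Generator,
    target: np.ndarray,
) -> Recording:
    """Assemble a Recording from per-eye angular offset series.

    h and w map eye name -> horizontal/vertical component offsets added to
    the eye's baseline fixation direction; directions are renormalized to
    unit length after noise injection, origins receive a scaled copy of
    the same signal, and the head quaternion is kept exactly consistent
    with the (noisy) Euler angles.
    """
    n = len(t)
    cols: dict[str, np.ndarray] = {"t": t}

    base_dirs = {}
    for eye in ("left", "right", "combined"):
        base_dirs[eye] = _normalize(target - _EYE_BASE[eye])

    prefix_o = {"left": ("lx", "ly", "lz"), "right": ("rx", "ry", "rz"),
                "combined": ("cx", "cy", "cz")}
    prefix_d = {"left": ("ldx", "ldy", "ldz"), "right": ("rdx", "rdy", "rdz"),
                "combined": ("cdx", "cdy", "cdz")}

    for eye in ("left", "right", "combined"):
        offset = np.column_stack([h[eye], w[eye], np.zeros(n)])
        raw = base_dirs[eye][None, :] + offset
        raw = raw + rng.normal(0.0, noise_sd, size=(n, 3)) if noise_sd > 0 else raw
        dirs = _normalize(raw)
        origin = (
            _EYE_BASE[eye][None, :]
            + ORIGIN_SCALE * offset
            + (rng.normal(0.0, noise_sd * ORIGIN_SCALE, size=(n, 3))
               if noise_sd > 0 else 0.0)
        )
        for j, c in enumerate(prefix_o[eye]):
            cols[c] = origin[:, j]
        for j, c in enumerate(prefix_d[eye]):
            cols[c] = dirs[:, j]

    euler_noise = noise_sd * 25.0  # degrees; 0.05 deg at the default noise
    yaw = yaw_deg + (rng.normal(0.0, euler_noise, n) if noise_sd > 0 else 0.0)
    pitch = rng.normal(0.0, euler_noise, n) if noise_sd > 0 else np.zeros(n)
    roll = rng.normal(0.0, euler_noise, n) if noise_sd > 0 else np.zeros(n)
    head_pos = (
        rng.normal(0.0, noise_sd * 0.1, size=(n, 3)) if noise_sd > 0
        else np.zeros((n, 3))
    )
    quat_xyzw = Rotation.from_euler(
        EULER_SEQ, np.column_stack([yaw, pitch, roll]), degrees=True
    ).as_quat()

    cols["hx"], cols["hy"], cols["hz"] = head_pos.T
    cols["yaw"], cols["pitch"], cols["roll"] = yaw, pitch, roll
    cols["qw"] = quat_xyzw[:, 3]
    cols["qx"], cols["qy"], cols["qz"] = quat_xyzw[:, 0], quat_xyzw[:, 1], quat_xyzw[:, 2]
    cols["lvalid"] = np.ones(n, bool)
    cols["rvalid"] = np.ones(n, bool)

    df = pd.DataFrame({c: cols[c] for c in CANONICAL_COLUMNS})
    return Recording(
        subject_id=subject_id, segment=stage, diagnosis_label=diagnosis,
        df=df, nominal_rate=rate,
    )


def _stage_nystagmus(
    profile: SimulationProfile, stage: str
) -> tuple[float, float, str, int] | None:
    """(spv, freq, plane, direction) active during a stage, or None.

    Peripheral nystagmus is unidirectional and present in every fixation
    stage; central gaze-evoked nystagmus beats toward the gaze side in the
    eccentric stages only; central down-beat nystagmus is present in all
    fixation stages.  The cover test inherits the straight-ahead
    condition.
    """
    if profile.spv <= 0:
        return None
    fixating = stage in FIXATION_STAGES or stage == STAGE_COVER_TEST
    if not fixating:
        return None
    if profile.group == "peripheral":
        return (profile.spv, profile.beat_frequency, "horizontal",
                profile.beat_direction)
    if profile.group == "central":
        if profile.beat_plane == "vertical":
            return (profile.spv, profile.beat_frequency, "vertical", -1)
        if profile.direction_changing:
            if stage == STAGE_GAZE_LEFT:
                return (profile.spv, profile.beat_frequency, "horizontal", -1)
            if stage == STAGE_GAZE_RIGHT:
                return (profile.spv, profile.beat_frequency, "horizontal", 1)
        return None
    return None


# -- stage generators -------------------------------------------------------

def simulate_fixation(
    profile: SimulationProfile,
    stage: str = STAGE_GAZE_NOSE,
    duration: float = 10.0,
    seed: int = 0,
    quiescent: bool = False,
) -> tuple[Recording, GroundTruth]:
    """A fixation stage: baseline gaze at the stage target plus nystagmus.

    quiescent forces the nystagmus off (bookkeeping stages).
    """
    rate = profile.sample_rate
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)

    nyst = None if quiescent else _stage_nystagmus(profile, stage)
    gt = GroundTruth(stage=stage, params=_echo_params(profile, stage))
    h_conj = np.zeros(n)
    w_conj = np.zeros(n)
    if nyst is not None:
        spv, freq, plane, direction = nyst
        pos, fast = _sawtooth(n, rate, spv, freq, direction)
        if plane == "horizontal":
            h_conj = pos
        else:
            w_conj = pos
        gt.fast_phases = fast
        gt.params.update({
            "active_spv": spv, "active_beat_frequency": freq,
            "active_plane": plane, "active_direction": direction,
        })

    yaw = np.zeros(n)
    if profile.artifact:
        h_conj = h_conj + _artifact_bump(t, ARTIFACT_AMPLITUDE)
        yaw = yaw + _artifact_bump(t, ARTIFACT_YAW_DEG)

    h = {eye: h_conj for eye in ("left", "right", "combined")}
    w = {eye: w_conj for eye in ("left", "right", "combined")}
    rec = _build_recording(
        subject_id="sim", stage=stage, diagnosis=profile.group,
        t=t, h=h, w=w, yaw_deg=yaw, rate=rate,
        noise_sd=profile.noise_sd, rng=rng, target=_stage_target(stage),
    )
    return rec, gt


#: Head-impulse velocity template: raised-cosine ramps around a 3-frame
#: flat top, so the sampled peak equals the nominal peak exactly.
_PULSE_TEMPLATE = np.concatenate([
    0.5 * (1 - np.cos(np.pi * np.arange(5) / 4)),  # 0 .. 1 over 5 frames
    [1.0, 1.0],
    0.5 * (1 - np.cos(np.pi * np.arange(3, -1, -1) / 4)),  # 1 .. 0
])
_PULSE_FRAMES = len(_PULSE_TEMPLATE)  # 11 frames ~ 183 ms at 60 Hz

_SACCADE_LATENCY = 0.15  # s after pulse end
_SACCADE_FRAMES = 3
_HOLD_AFTER_PULSE = 0.8  # s of steady head before the slow return
#: Return-to-centre duration; long enough that the return peaks near
#: 12 deg/s, well under the 20 deg/s impulse-detection floor even with
#: sensor noise on top.
_RETURN_DURATION = 3.0
_REST_AFTER_RETURN = 0.5
_LEAD_IN = 2.5


def simulate_head_impulse_stage(
    profile: SimulationProfile,
    side: str,
    n_impulses: int | None = None,
    peak_velocity: float | None = None,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """A head-impulse stage: abrupt passive yaw rotations toward one side.

    The eye channel counter-rotates at the side's VOR gain; a deficient
    gain leaves a gaze error that is cleared by a corrective saccade
    100-250 ms after the pulse.  Between impulses the head returns slowly
    (below the impulse-detection motion floor) to centre.
    """
    n_impulses = profile.n_impulses if n_impulses is None else n_impulses
    peak_velocity = (
        profile.impulse_peak_velocity if peak_velocity is None else peak_velocity
    )
    if n_impulses < 1:
        raise ParameterError("n_impulses must be >= 1")
    if peak_velocity <= 0:
        raise ParameterError("peak_velocity must be > 0")
    if side not in ("left", "right"):
        raise ParameterError(f"side must be left or right, got {side!r}")

    rate = profile.sample_rate
    dt = 1.0 / rate
    sign = 1 if side == "left" else -1  # +yaw = leftward (right-hand rule, +y up)
    gain = profile.vor_gain_left if side == "left" else profile.vor_gain_right

    block = _PULSE_FRAMES * dt + _HOLD_AFTER_PULSE + _RETURN_DURATION + _REST_AFTER_RETURN
    duration = _LEAD_IN + n_impulses * block + 0.5
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)

    vel = np.zeros(n)
    starts = []
    for j in range(n_impulses):
        i0 = int(round((_LEAD_IN + j * block) * rate))
        vel[i0:i0 + _PULSE_FRAMES] += sign * peak_velocity * _PULSE_TEMPLATE
        starts.append(i0)

    yaw_pulse = np.concatenate([[0.0], cumulative_trapezoid(vel, t)])
    yaw = yaw_pulse.copy()
    gt = GroundTruth(
        stage=STAGE_HIT_LEFT if side == "left" else STAGE_HIT_RIGHT,
        params=_echo_params(profile, side),
    )
    deficit = np.zeros(n)
    for i0 in starts:
        i_end = i0 + _PULSE_FRAMES - 1
        delta = yaw_pulse[i_end] - yaw_pulse[i0]
        # slow return to centre after the hold period
        r0 = t[i_end] + _HOLD_AFTER_PULSE
        u = np.clip((t - r0) / _RETURN_DURATION, 0.0, 1.0)
        yaw -= delta * 0.5 * (1 - np.cos(np.pi * u))

        gt.impulses.append({
            "onset": float(t[i0]),
            "peak_time": float(t[i0 + _PULSE_FRAMES // 2]),
            "peak_velocity": float(sign * peak_velocity),
            "direction": sign,
            "side": side,
        })
        if gain < 0.999:
            deficit[i0:i_end + 1] = (1 - gain) * (yaw_pulse[i0:i_end + 1] - yaw_pulse[i0])
            s0 = i_end + 1 + int(round(_SACCADE_LATENCY * rate))
            deficit[i_end + 1:s0] = (1 - gain) * delta
            for m in range(_SACCADE_FRAMES):
                frac = 1.0 - (m + 1) / _SACCADE_FRAMES
                if s0 + m < n:
                    deficit[s0 + m] = (1 - gain) * delta * frac
            gt.corrective_saccades.append({
                "time": float(t[s0]) if s0 < n else float(t[-1]),
                "amplitude_deg": float(-(1 - gain) * delta),
                "direction": -sign,
            })

    eye_deg = -yaw + deficit  # eye-in-head horizontal angle
    h_conj = np.sin(np.radians(eye_deg))
    if profile.artifact:
        h_conj = h_conj + _artifact_bump(t, ARTIFACT_AMPLITUDE)
        yaw = yaw + _artifact_bump(t, ARTIFACT_YAW_DEG)

    h = {eye: h_conj for eye in ("left", "right", "combined")}
    w = {eye: np.zeros(n) for eye in ("left", "right", "combined")}
    rec = _build_recording(
        subject_id="sim", stage=gt.stage, diagnosis=profile.group,
        t=t, h=h, w=w, yaw_deg=yaw, rate=rate,
        noise_sd=profile.noise_sd, rng=rng, target=_stage_target(STAGE_GAZE_NOSE),
    )
    return rec, gt


_COVER_RAMP = 0.1  # s: deviation/refixation ramp at cover transitions
#: Both-uncovered lead-in; long enough that a baseline epoch survives the
#: default 2 s initial trim.
_COVER_LEAD = 3.5


def simulate_cover_test(
    profile: SimulationProfile,
    n_alternations: int = 6,
    epoch_seconds: float = 2.0,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Alternating cover test: the covered eye deviates by the skew offset.

    The left eye deviates upward (+skew_offset), the right downward, each
    with a 100 ms ramp at cover onset and a refixation ramp at uncover.
    Cover-switch times, the schedule and all refixation events are logged.
    """
    if n_alternations < 2:
        raise ParameterError("n_alternations must be >= 2")
    rate = profile.sample_rate
    duration = _COVER_LEAD + n_alternations * epoch_seconds + 1.0
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)

    switches = [_COVER_LEAD + k * epoch_seconds for k in range(n_alternations + 1)]
    gt = GroundTruth(
        stage=STAGE_COVER_TEST, params=_echo_params(profile, "cover"),
    )
    gt.cover_switches = [float(s) for s in switches]
    gt.params["skew_offset_origin_m"] = profile.skew_offset * ORIGIN_SCALE

    def _rise(x: np.ndarray) -> np.ndarray:
        u = np.clip(x / _COVER_RAMP, 0.0, 1.0)
        return 0.5 * (1 - np.cos(np.pi * u))

    coverage = {"left": np.zeros(n), "right": np.zeros(n)}
    for k in range(n_alternations):
        eye = "left" if k % 2 == 0 else "right"
        a, b = switches[k], switches[k + 1]
        coverage[eye] += _rise(t - a) - _rise(t - b)
        gt.cover_schedule.append({"start": float(a), "end": float(b), "covered": eye})
        if profile.skew_offset > 0:
            amp = profile.skew_offset if eye == "left" else -profile.skew_offset
            gt.refixations.append({
                "time": float(b), "eye": eye, "amplitude": float(-amp),
            })

    delta = profile.skew_offset
    w = {
        "left": delta * coverage["left"],
        "right": -delta * coverage["right"],
    }
    w["combined"] = 0.5 * (w["left"] + w["right"])

    nyst = _stage_nystagmus(profile, STAGE_COVER_TEST)
    h_conj = np.zeros(n)
    if nyst is not None:
        spv, freq, plane, direction = nyst
        pos, fast = _sawtooth(n, rate, spv, freq, direction)
        if plane == "horizontal":
            h_conj = pos
        else:
            w = {eye: w[eye] + pos for eye in w}
        gt.fast_phases = fast
    if profile.artifact:
        h_conj = h_conj + _artifact_bump(t, ARTIFACT_AMPLITUDE)

    h = {eye: h_conj for eye in ("left", "right", "combined")}
    yaw = _artifact_bump(t, ARTIFACT_YAW_DEG) if profile.artifact else np.zeros(n)
    rec = _build_recording(
        subject_id="sim", stage=STAGE_COVER_TEST, diagnosis=profile.group,
        t=t, h=h, w=w, yaw_deg=yaw, rate=rate,
        noise_sd=profile.noise_sd, rng=rng, target=_stage_target(STAGE_GAZE_NOSE),
    )
    return rec, gt


def _echo_params(profile: SimulationProfile, context: str) -> dict:
    return {
        "group": profile.group, "spv": profile.spv,
        "beat_frequency": profile.beat_frequency,
        "beat_plane": profile.beat_plane,
        "beat_direction": profile.beat_direction,
        "direction_changing": profile.direction_changing,
        "vor_gain_left": profile.vor_gain_left,
        "vor_gain_right": profile.vor_gain_right,
        "skew_offset": profile.skew_offset,
        "noise_sd": profile.noise_sd,
        "sample_rate": profile.sample_rate,
        "impulse_peak_velocity": profile.impulse_peak_velocity,
        "context": context,
    }


# -- whole-exam generators --------------------------------------------------

def simulate_subject(
    profile: SimulationProfile,
    protocol: ExamProtocol | None = None,
    seed: int = 0,
    subject_id: str = "sim",
) -> dict[str, tuple[Recording, GroundTruth]]:
    """All ten protocol stages for one subject.

    Per-stage seeds are derived deterministically from the subject seed,
    so the same (profile, seed) reproduces every stage bit for bit.
    """
    profile.validate()
    protocol = protocol or default_protocol()
    stage_seeds = np.random.SeedSequence(seed).generate_state(len(protocol.stages))
    out: dict[str, tuple[Recording, GroundTruth]] = {}
    for desc, raw_seed in zip(protocol.stages, stage_seeds):
        s = int(raw_seed) & 0x7FFFFFFF
        if desc.id in (STAGE_START, STAGE_CALIBRATION, STAGE_SAVE):
            rec, gt = simulate_fixation(
                profile, stage=desc.id, duration=desc.duration, seed=s,
                quiescent=True,
            )
        elif desc.id in FIXATION_STAGES:
            rec, gt = simulate_fixation(
                profile, stage=desc.id, duration=desc.duration, seed=s,
            )
        elif desc.id == STAGE_HIT_LEFT:
            rec, gt = simulate_head_impulse_stage(profile, "left", seed=s)
        elif desc.id == STAGE_HIT_RIGHT:
            rec, gt = simulate_head_impulse_stage(profile, "right", seed=s)
        elif desc.id == STAGE_COVER_TEST:
            rec, gt = simulate_cover_test(profile, seed=s)
        else:
            rec, gt = simulate_fixation(
                profile, stage=desc.id, duration=desc.duration, seed=s,
                quiescent=True,
            )
        rec.subject_id = subject_id
        out[desc.id] = (rec, gt)
    return out


@dataclass
class CohortSubject:
    subject_id: str
    group: str
    age: float
    sex: str
    seed: int
    profile: SimulationProfile

    def metadata(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "diagnosis_label": self.group,
            "age": self.age,
            "sex": self.sex,
            "seed": self.seed,
        }


def simulate_study_cohort(
    n_healthy: int = 21,
    n_peripheral: int = 7,
    n_central: int = 2,
    seed: int = 0,
    noise_sd: float = 0.002,
    randomize: bool = True,
) -> list[CohortSubject]:
    """The default study cohort: 21 healthy, 7 peripheral, 2 central.

    Within-profile parameters are drawn from documented ranges (slow-phase
    velocity 0.05-0.12 components/s, beat frequency 1.2-2.2 Hz, lesioned
    VOR gain 0.3-0.6, skew offset 0.012-0.03, impulse peak 180-230 deg/s);
    group ages are drawn around the study means (healthy 33, peripheral
    58, central mid-70s) as fixture colour only.
    """
    if min(n_healthy, n_peripheral, n_central) < 0:
        raise ParameterError("cohort counts must be >= 0")
    rng = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []

    def _seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    def _u(lo: float, hi: float, default: float) -> float:
        return float(rng.uniform(lo, hi)) if randomize else default

    idx = 0
    for _ in range(n_healthy):
        prof = SimulationProfile.healthy(
            noise_sd=noise_sd,
            impulse_peak_velocity=_u(180, 230, 200),
        )
        age = float(np.clip(rng.normal(33, 8), 18, 90))
        sex = "F" if rng.random() < 0.66 else "M"
        subjects.append(CohortSubject(f"S{idx:03d}", "healthy", age, sex, _seed(), prof))
        idx += 1
    for _ in range(n_peripheral):
        side = "left" if rng.random() < 0.5 else "right"
        prof = SimulationProfile.peripheral(
            spv=_u(0.05, 0.12, 0.08),
            beat_frequency=_u(1.2, 2.2, 2.0),
            lesion_side=side,
            lesion_gain=_u(0.3, 0.6, 0.4),
            noise_sd=noise_sd,
            impulse_peak_velocity=_u(180, 230, 200),
        )
        age = float(np.clip(rng.normal(58, 10), 18, 95))
        sex = "F" if rng.random() < 0.71 else "M"
        subjects.append(
            CohortSubject(f"S{idx:03d}", "peripheral", age, sex, _seed(), prof)
        )
        idx += 1
    for j in range(n_central):
        variant = "direction-changing" if j % 2 == 0 else "downbeat"
        prof = SimulationProfile.central(
            variant=variant,
            spv=_u(0.05, 0.12, 0.08),
            beat_frequency=_u(1.2, 2.2, 2.0),
            skew_offset=_u(0.012, 0.03, 0.02),
            noise_sd=noise_sd,
            impulse_peak_velocity=_u(180, 230, 200),
        )
        age = float(np.clip(rng.normal(73, 7), 18, 95))
        sex = "M"
        subjects.append(
            CohortSubject(f"S{idx:03d}", "central", age, sex, _seed(), prof)
        )
        idx += 1
    return subjects


def write_subject(
    subject: CohortSubject,
    out_dir: str | Path,
    protocol: ExamProtocol | None = None,
) -> dict:
    """Simulate a cohort subject and write CSVs, ground truth and metadata.

    Returns the subject's manifest entry (stage -> file map).
    """
    protocol = protocol or default_protocol()
    out_dir = Path(out_dir)
    subj_dir = out_dir / subject.subject_id
    subj_dir.mkdir(parents=True, exist_ok=True)
    stages = simulate_subject(
        subject.profile, protocol, seed=subject.seed, subject_id=subject.subject_id
    )
    stage_files = {}
    gt_all = {}
    for stage_id, (rec, gt) in stages.items():
        fname = f"{stage_id}.csv"
        write_recording(rec, subj_dir / fname)
        stage_files[stage_id] = fname
        gt_all[stage_id] = gt.to_dict()
    meta = subject.metadata()
    meta["stages"] = stage_files
    write_subject_metadata(subj_dir / "metadata.json", meta)
    (subj_dir / "ground_truth.json").write_text(
        json.dumps(gt_all, indent=2, sort_keys=True)
    )
    return {"subject_id": subject.subject_id, "dir": subject.subject_id,
            "stages": stage_files, "diagnosis_label": subject.group}
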
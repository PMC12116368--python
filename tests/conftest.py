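import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from hintspy.recording_io import CANONICAL_COLUMNS, EULER_SEQ, Recording


def build_recording(
    t,
    *,
    left_dir=None,
    right_dir=None,
    combined_dir=None,
    left_origin=None,
    right_origin=None,
    combined_origin=None,
    yaw=None,
    pitch=None,
    roll=None,
    lvalid=None,
    rvalid=None,
    segment="spontaneous",
    subject_id="TEST",
    rate=60.0,
):
    """Hand-built Recording with sane defaults (straight-ahead gaze,
    static head, quaternion consistent with the Euler angles)."""
    t = np.asarray(t, float)
    n = len(t)

    def vec(x, default):
        if x is None:
            return np.tile(np.asarray(default, float), (n, 1))
        return np.asarray(x, float)

    ld = vec(left_dir, [0.0, 0.0, -1.0])
    rd = vec(right_dir, [0.0, 0.0, -1.0])
    cd = vec(combined_dir, [0.0, 0.0, -1.0])
    lo = vec(left_origin, [-0.03, 0.0, 0.0])
    ro = vec(right_origin, [0.03, 0.0, 0.0])
    co = vec(combined_origin, [0.0, 0.0, 0.0])
    yaw = np.zeros(n) if yaw is None else np.asarray(yaw, float)
    pitch = np.zeros(n) if pitch is None else np.asarray(pitch, float)
    roll = np.zeros(n) if roll is None else np.asarray(roll, float)
    lv = np.ones(n, bool) if lvalid is None else np.asarray(lvalid, bool)
    rv = np.ones(n, bool) if rvalid is None else np.asarray(rvalid, bool)

    quat = Rotation.from_euler(
        EULER_SEQ, np.column_stack([yaw, pitch, roll]), degrees=True
    ).as_quat()
    cols = {
        "t": t,
        "lx": lo[:, 0], "ly": lo[:, 1], "lz": lo[:, 2],
        "ldx": ld[:, 0], "ldy": ld[:, 1], "ldz": ld[:, 2],
        "rx": ro[:, 0], "ry": ro[:, 1], "rz": ro[:, 2],
        "rdx": rd[:, 0], "rdy": rd[:, 1], "rdz": rd[:, 2],
        "cx": co[:, 0], "cy": co[:, 1], "cz": co[:, 2],
        "cdx": cd[:, 0], "cdy": cd[:, 1], "cdz": cd[:, 2],
        "hx": np.zeros(n), "hy": np.zeros(n), "hz": np.zeros(n),
        "yaw": yaw, "pitch": pitch, "roll": roll,
        "qw": quat[:, 3], "qx": quat[:, 0], "qy": quat[:, 1], "qz": quat[:, 2],
        "lvalid": lv, "rvalid": rv,
    }
    df = pd.DataFrame({c: cols[c] for c in CANONICAL_COLUMNS})
    return Recording(
        subject_id=subject_id, segment=segment, diagnosis_label="unknown",
        df=df, nominal_rate=rate,
    )


@pytest.fixture
def timestamps_60hz():
    return np.arange(600) / 60.0  # 10 s
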
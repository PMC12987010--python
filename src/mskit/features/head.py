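"""Head-direction signals and the vestibulo-ocular-reflex (VOR) proxy.

Head rotation has no natural central reference, so per-frame orientations
are expressed relative to the window-average rotation and applied to the
forward vector (0, 0, 1); the resulting direction vectors are converted to
spherical yaw/pitch signals with the same convention as the gaze angles.
The window-average rotation is the normalized component-wise mean of unit
quaternions after sign-aligning to the first frame (chordal mean; adequate
for the small intra-window rotations of seated head motion).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .eye import gaze_angles

_HEAD_V_FLOOR_DEG_S = 1e-3


def average_rotation(rotations: Rotation) -> Rotation:
    """Chordal mean of unit quaternions, sign-aligned to the first frame."""
    q = rotations.as_quat()
    if q.ndim == 1:
        return Rotation.from_quat(q)
    signs = np.where(q @ q[0] < 0, -1.0, 1.0)
    mean = (q * signs[:, None]).mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm == 0:
        raise ValueError("degenerate orientation data (zero mean quaternion)")
    return Rotation.from_quat(mean / norm)


def head_direction_signals(rotations: Rotation | np.ndarray,
                           euler_order: str = "XYZ",
                           degrees: bool = True,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Window-relative head-direction yaw/pitch signals in degrees.

    ``rotations`` is either a :class:`scipy.spatial.transform.Rotation`
    stack or an (n, 3) Euler-angle array (``euler_order`` convention; the
    default ``XYZ`` reads columns as pitch, yaw, roll).
    """
    if not isinstance(rotations, Rotation):
        arr = np.asarray(rotations, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or not np.isfinite(arr).all():
            raise ValueError("rotation series must be finite (n, 3) Euler angles")
        rotations = Rotation.from_euler(euler_order, arr, degrees=degrees)
    mean_rot = average_rotation(rotations)
    rel = mean_rot.inv() * rotations
    directions = rel.apply(np.array([0.0, 0.0, 1.0]))
    return gaze_angles(directions)


def head_directions(rotations: Rotation | np.ndarray,
                    euler_order: str = "XYZ", degrees: bool = True) -> np.ndarray:
    """Window-relative head-direction unit vectors (for velocity / VOR)."""
    if not isinstance(rotations, Rotation):
        rotations = Rotation.from_euler(euler_order,
                                        np.asarray(rotations, dtype=float),
                                        degrees=degrees)
    mean_rot = average_rotation(rotations)
    rel = mean_rot.inv() * rotations
    return rel.apply(np.array([0.0, 0.0, 1.0]))


def vor(gaze_velocity: np.ndarray, head_velocity: np.ndarray) -> float:
    """Mean gaze-to-head velocity ratio, excluding near-stationary frames.

    Frames with head velocity below 1e-3 deg/s are excluded; if none remain
    the feature is missing (NaN).
    """
    gv = np.asarray(gaze_velocity, dtype=float)
    hv = np.asarray(head_velocity, dtype=float)
    if gv.shape != hv.shape:
        raise ValueError("gaze and head velocity must have equal length")
    ok = (hv >= _HEAD_V_FLOOR_DEG_S) & ~np.isnan(gv) & ~np.isnan(hv)
    if not ok.any():
        return float("nan")
    return float((gv[ok] / hv[ok]).mean())
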
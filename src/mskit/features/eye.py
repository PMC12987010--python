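"""Eye-tracking features: closure signals, vergence, gaze angles and kinematics.

Eye closure is classified per frame from the tracked eye position: a null
(NaN) position, or one within 1 mm (L-infinity) of the HMD gaze origin,
marks a closed eye.  Single-frame inversions are suppressed iteratively
until a fixed point.  The convergence distance is the minimum Euclidean
distance between the two (generally skew) gaze lines; near-parallel gazes
(cross-product norm below 1e-3) yield NaN, and the per-window NaN fraction
is the vergence-loss window-derived feature.
"""

from __future__ import annotations

import warnings

import numpy as np

_CLOSURE_TOL_M = 1e-3
_PARALLEL_TOL = 1e-3
SACCADE_THRESHOLD_DEG_S = 100.0

#: Registry order of the seven eye WdFs.
EYE_WDF_NAMES = ("blink_rate", "vergence_loss", "saccade_ratio",
                 "fixation_ratio", "vor", "path_length", "heatmap_entropy")


def eye_closure(eye_pos: np.ndarray, center_pos: np.ndarray) -> np.ndarray:
    """Binary closure signal: 1 where the eye is closed, 0 where open."""
    eye_pos = np.asarray(eye_pos, dtype=float)
    center_pos = np.asarray(center_pos, dtype=float)
    isnull = np.isnan(eye_pos).any(axis=1)
    dist = np.abs(eye_pos - center_pos).max(axis=1)
    closed = isnull | (np.nan_to_num(dist, nan=np.inf) < _CLOSURE_TOL_M)
    closed[isnull] = True
    return closed.astype(np.int8)


def denoise_closure(binary: np.ndarray) -> np.ndarray:
    """Suppress isolated single-frame inversions until convergence.

    Each sweep scans left to right applying the isolated-one rule
    (0-1-0 -> 0-0-0) and then the isolated-zero rule (1-0-1 -> 1-1-1);
    sweeps repeat until the signal is a fixed point of both rules.
    """
    s = np.asarray(binary).astype(np.int8).copy()
    if not np.isin(s, (0, 1)).all():
        raise ValueError("closure signal must be binary")
    n = len(s)
    if n < 3:
        return s
    changed = True
    while changed:
        changed = False
        for lo, hi, mid in ((0, 1, 0), (1, 0, 1)):
            for i in range(1, n - 1):
                if s[i - 1] == lo and s[i] == hi and s[i + 1] == mid:
                    s[i] = mid if lo == mid else lo
                    changed = True
    return s


def closure_combination(cs_l: np.ndarray, cs_r: np.ndarray,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Frame-by-frame logical AND (both closed) and OR (either closed)."""
    cs_l = np.asarray(cs_l).astype(np.int8)
    cs_r = np.asarray(cs_r).astype(np.int8)
    if cs_l.shape != cs_r.shape:
        raise ValueError("closure signals must have equal length")
    return cs_l & cs_r, cs_l | cs_r


def blink_rate(cs_l: np.ndarray, cs_r: np.ndarray, window_s: float) -> float:
    """Blinks per minute: rising-edge counts per eye, averaged over eyes."""
    def _count(s: np.ndarray) -> int:
        s = np.asarray(s).astype(np.int8)
        return int(((s[1:] == 1) & (s[:-1] == 0)).sum())

    per_min = 60.0 / window_s
    return 0.5 * (_count(cs_l) + _count(cs_r)) * per_min


def convergence_distance(p_l: np.ndarray, p_r: np.ndarray,
                         d_l: np.ndarray, d_r: np.ndarray) -> np.ndarray:
    """Per-frame minimum distance (m) between the binocular gaze lines.

    ``d[k] = |(P_L - P_R) . (D_L x D_R)| / ||D_L x D_R||`` when the cross
    product norm is at least 1e-3, NaN otherwise (near-parallel gazes).
    Non-unit direction vectors are normalized first (with a warning).
    """
    d_l = np.atleast_2d(np.asarray(d_l, dtype=float))
    d_r = np.atleast_2d(np.asarray(d_r, dtype=float))
    p_l = np.broadcast_to(np.atleast_2d(np.asarray(p_l, dtype=float)), d_l.shape)
    p_r = np.broadcast_to(np.atleast_2d(np.asarray(p_r, dtype=float)), d_r.shape)
    nl = np.linalg.norm(d_l, axis=1, keepdims=True)
    nr = np.linalg.norm(d_r, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        if np.nanmax(np.abs(np.concatenate([nl, nr]) - 1.0)) > 1e-6:
            warnings.warn("gaze directions not unit-norm; normalizing",
                          stacklevel=2)
        d_l = d_l / nl
        d_r = d_r / nr
        cross = np.cross(d_l, d_r)
        cn = np.linalg.norm(cross, axis=1)
        sep = p_l - p_r
        num = np.abs(np.einsum("ij,ij->i", sep, cross))
        out = np.where(cn >= _PARALLEL_TOL, num / np.where(cn > 0, cn, 1.0),
                       np.nan)
    out[np.isnan(cn)] = np.nan
    return out


def gaze_angles(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spherical gaze angles in degrees from (approximately) unit vectors.

    ``yaw = atan2(g_x, g_z)``; ``pitch = asin(clip(g_y, -1, 1))``; forward is
    (0, 0, 1).
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    norms = np.linalg.norm(g, axis=1)
    if np.any(np.nan_to_num(norms) == 0):
        raise ValueError("zero gaze vector")
    yaw = np.degrees(np.arctan2(g[:, 0], g[:, 2]))
    pitch = np.degrees(np.arcsin(np.clip(g[:, 1], -1.0, 1.0)))
    return yaw, pitch


def heatmap_entropy(yaw: np.ndarray, pitch: np.ndarray, bins: int = 64,
                    angle_range: float = 90.0) -> float:
    """Shannon entropy (bits) of the 2-D gaze-angle heatmap.

    64 x 64 bins over [-90 deg, 90 deg] squared; samples outside the range are
    clipped into the edge bins.
    """
    yaw = np.asarray(yaw, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    ok = ~(np.isnan(yaw) | np.isnan(pitch))
    yaw, pitch = yaw[ok], pitch[ok]
    if len(yaw) == 0:
        raise ValueError("empty window")
    eps = 1e-9
    yaw = np.clip(yaw, -angle_range, angle_range - eps)
    pitch = np.clip(pitch, -angle_range, angle_range - eps)
    h, _, _ = np.histogram2d(yaw, pitch, bins=bins,
                             range=[[-angle_range, angle_range],
                                    [-angle_range, angle_range]])
    p = h.ravel() / h.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def gaze_velocity(directions: np.ndarray, frame_rate: float,
                  ) -> tuple[np.ndarray, dict[str, float]]:
    """Angular gaze velocity (deg/s) plus saccade/fixation/path WdFs.

    ``v[k] = acos(D[k] . D[k-1]) x frame_rate`` in degrees per second.
    Frames strictly above 100 deg/s are saccades; path length is the
    cumulative per-frame angle over the window.
    """
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if len(d) < 2:
        raise ValueError("need at least two frames")
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = d / norms
    dots = np.clip(np.einsum("ij,ij->i", d[1:], d[:-1]), -1.0, 1.0)
    deg_per_frame = np.degrees(np.arccos(dots))
    v = deg_per_frame * frame_rate
    ok = ~np.isnan(v)
    n_ok = int(ok.sum())
    if n_ok == 0:
        wdfs = {"saccade_ratio": float("nan"), "fixation_ratio": float("nan"),
                "path_length": float("nan")}
    else:
        sacc = float((v[ok] > SACCADE_THRESHOLD_DEG_S).sum() / n_ok)
        wdfs = {"saccade_ratio": sacc, "fixation_ratio": 1.0 - sacc,
                "path_length": float(np.nansum(deg_per_frame))}
    return v, wdfs
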
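"""Small rigid-body geometry toolbox: rotations, superposition, switches."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize zero vector")
    return v / n


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    a, b = unit(np.asarray(a, float)), np.asarray(b, float)
    b = unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-10:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis perpendicular to a
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = unit(np.cross(a, p))
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    s = np.linalg.norm(v)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def axis_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    return Rotation.from_rotvec(unit(np.asarray(axis, float)) * angle_rad).as_matrix()


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray,
                center: np.ndarray | None = None) -> np.ndarray:
    """Rotate coords about `center` (default origin) by R, then translate by t."""
    c = np.zeros(3) if center is None else np.asarray(center, float)
    return (np.asarray(coords, float) - c) @ R.T + c + np.asarray(t, float)


def random_rotation(rng: np.random.Generator, max_angle_rad: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis = axis / np.linalg.norm(axis)
    angle = rng.uniform(-max_angle_rad, max_angle_rad)
    return Rotation.from_rotvec(axis * angle).as_matrix()


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of `mobile` onto `target`.

    Returns (R, t, rmsd) such that mobile @ R.T + t best matches target.
    Degenerate (collinear) point sets are handled by aligning the principal
    axes with the minimal rotation (the spin about the axis is left at zero).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("need >= 3 paired points for a determined fit")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # rank-deficient cross-covariance: collinear points
    if S[1] < 1e-8 * max(S[0], 1.0):
        pa = _principal_axis(P0)
        qa = _principal_axis(Q0)
        if np.dot(P0 @ pa, Q0 @ qa) < 0:
            qa = -qa
        R = rotation_between(pa, qa)
    else:
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        D = np.diag([1.0, 1.0, d])
        R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def _principal_axis(X0: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(X0)
    return vt[0]


def plane_fit(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the best-fit plane through >= 3 points."""
    P = np.asarray(points, float)
    c = P.mean(axis=0)
    _, _, vt = np.linalg.svd(P - c)
    return c, vt[2]


def triangular_switch(x: float, window: tuple[float, float, float]) -> float:
    """1 at the ideal value, linear to 0 at the window edges, 0 outside."""
    lo, ideal, hi = window
    if x <= lo or x >= hi:
        return 0.0
    if x < ideal:
        return (x - lo) / (ideal - lo)
    if x > ideal:
        return (hi - x) / (hi - ideal)
    return 1.0


def angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors in degrees."""
    c = float(np.dot(unit(a), unit(b)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
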
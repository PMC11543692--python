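"""Least-squares rigid superposition (Kabsch algorithm)."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid transform mapping ``mobile`` onto ``target``.

    Both arrays have shape (n, 3) with matched rows. Returns ``(R, t, rmsd)``
    such that ``mobile @ R.T + t`` best fits ``target`` in the least-squares
    sense, with ``R`` a proper rotation (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must have identical (n, 3) shapes")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def rotation_angle_about_z(R: np.ndarray) -> tuple[float, float]:
    """Signed rotation angle about +z (degrees) and the axis tilt from z (degrees).

    The signed angle follows the right-hand convention about +z. The tilt is
    the angle between the true rotation axis and the z axis; callers may warn
    when it is large.
    """
    angle = float(np.degrees(np.arctan2(R[1, 0] - R[0, 1], R[0, 0] + R[1, 1])))
    # rotation axis from the antisymmetric part; undefined for angle ~ 0 or 180
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm = np.linalg.norm(w)
    if norm < 1e-12:
        tilt = 0.0
    else:
        axis = w / norm
        tilt = float(np.degrees(np.arccos(np.clip(abs(axis[2]), -1.0, 1.0))))
    return angle, tilt
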
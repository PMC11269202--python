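"""Rotation conventions shared across the package.

Orientations are stored as ZYZ intrinsic Euler triplets ``(rot, tilt, psi)``
in degrees.  The rotation matrix

    R(rot, tilt, psi) = Rz(rot) @ Ry(tilt) @ Rz(psi)

maps *reference-frame* coordinates into the *volume* frame.  The reference
filament runs along +z, so the filament direction of a record is

    d = R @ (0, 0, 1) = (cos(rot) sin(tilt), sin(rot) sin(tilt), cos(tilt)),

which depends only on ``rot`` and ``tilt``; ``psi`` is the free spin about
the filament axis.  This matches the STAR-dialect layout the particle tables
are exported to.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """3x3 matrix for intrinsic ZYZ Euler angles in degrees.

    Built from the explicit product

        R = Rz(rot) @ Ry(tilt) @ Rz(psi)

    with direct trigonometry (full float64 precision even for near-pole
    tilts, where quaternion round trips lose digits):

        | ca*cb*cc - sa*sc   -ca*cb*sc - sa*cc   ca*sb |
        | sa*cb*cc + ca*sc   -sa*cb*sc + ca*cc   sa*sb |
        |     -sb*cc               sb*sc            cb |

    with a = rot, b = tilt, c = psi.
    """
    a, b, c = np.deg2rad([rot, tilt, psi])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    return np.array([
        [ca * cb * cc - sa * sc, -ca * cb * sc - sa * cc, ca * sb],
        [sa * cb * cc + ca * sc, -sa * cb * sc + ca * cc, sa * sb],
        [-sb * cc, sb * sc, cb],
    ])


def matrix_to_euler(matrix: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`; angles in degrees."""
    rot, tilt, psi = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
    return float(rot), float(tilt), float(psi)


def direction_from_euler(rot: float, tilt: float, psi: float = 0.0) -> np.ndarray:
    """Unit filament direction (rotated +z) for a ZYZ Euler triplet."""
    rot_r, tilt_r = np.deg2rad(rot), np.deg2rad(tilt)
    return np.array(
        [np.cos(rot_r) * np.sin(tilt_r), np.sin(rot_r) * np.sin(tilt_r), np.cos(tilt_r)]
    )


def axis_to_euler(direction: np.ndarray) -> tuple[float, float, float]:
    """Euler triplet (rot, tilt, 0) whose rotation maps +z onto ``direction``.

    The spin about the axis is left at zero: it is the free parameter that
    alignment refines.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("zero-length direction vector")
    d = d / n
    # atan2 keeps the tilt well-conditioned near the poles (arccos is not)
    r_xy = np.hypot(d[0], d[1])
    tilt = np.degrees(np.arctan2(r_xy, d[2]))
    rot = np.degrees(np.arctan2(d[1], d[0])) if r_xy > 0.0 else 0.0
    return float(rot), float(tilt), 0.0


def perpendicular_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane basis ``(e1, e2)`` perpendicular to ``direction``.

    Chosen so that ``[e1, e2, d]`` equals the rotation matrix of
    ``axis_to_euler(direction)``: the swept-template renderer and the particle
    bookkeeping therefore agree on what "in-plane angle zero" means.
    """
    rot, tilt, _ = axis_to_euler(direction)
    m = euler_to_matrix(rot, tilt, 0.0)
    return m[:, 0].copy(), m[:, 1].copy()


def rotz(angle_deg: float) -> np.ndarray:
    """Rotation about z by ``angle_deg`` degrees."""
    return Rotation.from_euler("z", angle_deg, degrees=True).as_matrix()


FLIP_MATRIX = Rotation.from_euler("y", 180, degrees=True).as_matrix()
"""180-degree rotation about y: reverses the filament direction (polarity flip)."""


def compose_offset(
    euler: tuple[float, float, float],
    offset_matrix: np.ndarray,
) -> tuple[float, float, float]:
    """Euler angles of ``R(euler) @ offset_matrix``."""
    return matrix_to_euler(euler_to_matrix(*euler) @ offset_matrix)


def angular_distance_deg(m1: np.ndarray, m2: np.ndarray) -> float:
    """Geodesic angle in degrees between two rotation matrices."""
    tr = np.trace(m1.T @ m2)
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))
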
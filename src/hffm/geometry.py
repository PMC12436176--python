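"""Side-effect-free 3D geometry primitives.

Vectors are ``numpy`` arrays of shape ``(3,)`` in millimetres (lab or segment
frame); rotations are 3x3 orthonormal matrices whose *columns* are the frame
unit axes expressed in the parent frame.  Every downstream construction of the
foot model reduces to the handful of operations defined here.

Cardan angles follow the intrinsic X-Y-Z (sagittal, frontal, transverse)
sequence on the relative rotation ``R_rel = R_proximal.T @ R_distal``, the
standard reading of the Grood-Suntay joint coordinate system for that order.
Angles are in degrees throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DegenerateGeometryError, GimbalLockWarning, NonFiniteInputError

__all__ = [
    "CardanAngles",
    "Frame",
    "apex_angle",
    "euler_xyz_compose",
    "euler_xyz_decompose",
    "midpoint",
    "project_point_onto_line",
    "signed_projected_angle",
    "unit",
]

#: tolerance for orthonormality / unit-norm checks
_ORTHO_TOL = 1e-9
#: |beta| (deg) beyond which the Cardan decomposition is flagged as gimbal-locked
GIMBAL_LOCK_DEG = 89.0


def _as_vec3(v, name: str = "vector") -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must have shape (3,), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise NonFiniteInputError(f"{name} has non-finite components: {a}")
    return a


def unit(v, name: str = "vector") -> np.ndarray:
    """Normalize ``v`` to unit length, rejecting (near-)zero vectors."""
    a = _as_vec3(v, name)
    n = float(np.linalg.norm(a))
    if n < 1e-9:
        raise DegenerateGeometryError(f"cannot normalize near-zero {name} (norm={n:g})")
    return a / n


class CardanAngles(NamedTuple):
    """Intrinsic X-Y-Z Cardan angles in degrees (sagittal, frontal, transverse)."""

    alpha_sagittal: float
    beta_frontal: float
    gamma_transverse: float


@dataclass(frozen=True)
class Frame:
    """A right-handed coordinate frame: origin plus orientation.

    ``rotation`` columns are the frame's x/y/z unit axes in parent coordinates.
    """

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin, "origin"))
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)):
            raise NonFiniteInputError("rotation has non-finite entries")
        object.__setattr__(self, "rotation", R)

    @property
    def x(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.rotation[:, 2]

    def is_orthonormal(self, tol: float = 1e-9) -> bool:
        R = self.rotation
        return (
            np.allclose(R.T @ R, np.eye(3), atol=tol)
            and abs(np.linalg.det(R) - 1.0) <= tol
        )

    def to_local(self, p) -> np.ndarray:
        """Express a parent-frame point in this frame's coordinates."""
        return self.rotation.T @ (_as_vec3(p, "point") - self.origin)

    def to_parent(self, p_local) -> np.ndarray:
        """Express a point given in this frame's coordinates in the parent frame."""
        return self.origin + self.rotation @ _as_vec3(p_local, "point")


def midpoint(a, b) -> np.ndarray:
    """Component-wise mean of two points."""
    return 0.5 * (_as_vec3(a, "a") + _as_vec3(b, "b"))


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def euler_xyz_compose(angles: CardanAngles | tuple[float, float, float]) -> np.ndarray:
    """Compose ``R = Rx(alpha) @ Ry(beta) @ Rz(gamma)`` from degrees."""
    a, b, g = (np.radians(float(x)) for x in angles)
    if not all(np.isfinite([a, b, g])):
        raise NonFiniteInputError("Cardan angles must be finite")
    return _rx(a) @ _ry(b) @ _rz(g)


def euler_xyz_decompose(R) -> CardanAngles:
    """Recover intrinsic X-Y-Z Cardan angles (degrees) from a rotation matrix.

    Near the singularity (|beta| >= 89 deg) only alpha + gamma (or the
    difference) is observable; the tie is broken by setting gamma = 0 so that
    alpha carries the combined rotation, and a :class:`GimbalLockWarning` is
    emitted.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    sb = float(np.clip(R[0, 2], -1.0, 1.0))
    beta = np.arcsin(sb)
    if abs(np.degrees(beta)) >= GIMBAL_LOCK_DEG:
        warnings.warn(
            "Cardan decomposition at |beta| >= 89 deg: gamma set to 0, "
            "alpha carries the combined rotation",
            GimbalLockWarning,
            stacklevel=2,
        )
        # with gamma := 0, R[2,1] = sa*cb? use the well-conditioned block:
        # R = Rx(a) @ Ry(+-90):  R[1,0] = ca? derive from R[1,1], R[2,1]
        alpha = np.arctan2(R[2, 1], R[1, 1])
        gamma = 0.0
    else:
        alpha = np.arctan2(-R[1, 2], R[2, 2])
        gamma = np.arctan2(-R[0, 1], R[0, 0])
    return CardanAngles(
        float(np.degrees(alpha)), float(np.degrees(beta)), float(np.degrees(gamma))
    )


def apex_angle(a, apex, c) -> float:
    """Angle in degrees at ``apex`` subtended by points ``a`` and ``c``.

    This is the medial longitudinal arch measure when evaluated on the
    medial calcaneus, navicular and first metatarsal head markers.
    """
    apex = _as_vec3(apex, "apex")
    u = _as_vec3(a, "a") - apex
    v = _as_vec3(c, "c") - apex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-6 or nv < 1e-6:
        raise DegenerateGeometryError("apex coincides with a limb point")
    cosang = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def project_point_onto_line(p, line_point, line_dir) -> np.ndarray:
    """Orthogonal projection of ``p`` onto the line through ``line_point``."""
    p = _as_vec3(p, "p")
    q = _as_vec3(line_point, "line_point")
    d = unit(line_dir, "line_dir")
    return q + np.dot(p - q, d) * d


def signed_projected_angle(u, v, plane_normal) -> float:
    """Signed angle (deg) from proj(u) to proj(v) in the plane with the given normal.

    Positive by the right-hand rule about ``plane_normal``; antisymmetric under
    swapping ``u`` and ``v``.  Raises if either projection is degenerate.
    """
    n = unit(plane_normal, "plane_normal")
    up = _as_vec3(u, "u")
    vp = _as_vec3(v, "v")
    up = up - np.dot(up, n) * n
    vp = vp - np.dot(vp, n) * n
    if np.linalg.norm(up) < 1e-9 or np.linalg.norm(vp) < 1e-9:
        raise DegenerateGeometryError("vector projects to ~zero in the given plane")
    ang = np.arctan2(float(np.dot(np.cross(up, vp), n)), float(np.dot(up, vp)))
    return float(np.degrees(ang))


def rigid_transform(points: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Apply ``p -> R p + t`` to an ``(..., 3)`` array of points."""
    pts = np.asarray(points, dtype=float)
    return pts @ np.asarray(R, float).T + np.asarray(t, float)


def fit_rigid_transform(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (Kabsch) mapping ``src`` onto ``dst``.

    Both inputs are ``(n, 3)`` arrays of corresponding points, n >= 3 and not
    collinear.  Returns ``(R, t)`` with ``dst ~ src @ R.T + t``.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cd - R @ cs
    return R, t
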
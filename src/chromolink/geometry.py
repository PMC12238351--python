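"""Quaternion and rigid-frame helpers.

Conventions used throughout the package:

* quaternions are **scalar-first** ``(w, x, y, z)`` and unit norm;
* frames are right-handed; a bead's local z-axis is the helical axis of the
  DNA at that bead (for the nucleosome core bead, the disc normal);
* rotations act on column vectors, ``world = R @ body``.

All heavy lifting is delegated to :class:`scipy.spatial.transform.Rotation`;
these wrappers only pin down the scalar-first convention and provide
vectorized frame composition used by the fiber builder and the dynamics
engine.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "quat_identity",
    "quat_normalize",
    "quat_multiply",
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_rotate",
    "quat_from_rotvec",
    "quat_to_rotvec",
    "random_quats",
]

_UNIT_TOL = 1e-9


def quat_identity(n: int | None = None) -> np.ndarray:
    """Identity quaternion, or an ``(n, 4)`` stack of them."""
    if n is None:
        return np.array([1.0, 0.0, 0.0, 0.0])
    q = np.zeros((n, 4))
    q[:, 0] = 1.0
    return q


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero-norm quaternion")
    return q / norm


def check_unit(q: np.ndarray, tol: float = _UNIT_TOL) -> None:
    """Raise ``ValueError`` if any quaternion deviates from unit norm."""
    norm = np.linalg.norm(np.asarray(q, dtype=float), axis=-1)
    if not np.allclose(norm, 1.0, atol=tol):
        raise ValueError(f"non-unit quaternion (|q| deviates by {np.max(np.abs(norm - 1.0)):.3g})")


def _rot(q: np.ndarray) -> Rotation:
    return Rotation.from_quat(np.asarray(q, dtype=float), scalar_first=True)


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product; composed rotation is ``R(q1) @ R(q2)``."""
    out = (_rot(q1) * _rot(q2)).as_quat(scalar_first=True)
    return out


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    return _rot(q).as_matrix()


def matrix_to_quat(m: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(m).as_quat(scalar_first=True)


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` from the body frame to the world frame."""
    return _rot(q).apply(v)


def quat_from_rotvec(rv: np.ndarray, degrees: bool = False) -> np.ndarray:
    return Rotation.from_rotvec(np.asarray(rv, dtype=float), degrees=degrees).as_quat(
        scalar_first=True
    )


def quat_to_rotvec(q: np.ndarray, degrees: bool = False) -> np.ndarray:
    return _rot(q).as_rotvec(degrees=degrees)


def random_quats(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit quaternions (scalar-first), seeded by ``rng``."""
    return Rotation.random(n, rng=rng).as_quat(scalar_first=True)


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)
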
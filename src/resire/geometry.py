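"""Euler-angle conventions and the projection coordinate maps.

Orientations are parameterized by three Euler angles ``(phi, theta, psi)``
in degrees, composed extrinsically (fixed frame) as rotations about the
z, y and x axes: ``R = Z_phi @ Y_theta @ X_psi``.  A single-axis tilt
series about y is the triple ``(0, theta, 0)``.

Sign convention: a positive ``theta`` rotates the object's +x axis toward
+z (right-handed rotation about +y).  The same convention is used by the
forward projector, the back projector and the angular refinement, so it
cancels internally; only the sign of angles read from external files has
to match it.

The rotation center of an ``N``-sized axis is the voxel at index
``N // 2`` (0-based), matching the FFT-centering convention used by the
Fourier-slice projector.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "EulerAngles",
    "euler_to_matrix",
    "slice_transform",
    "as_angle_array",
    "is_single_axis",
]

#: Orthogonality / determinant tolerance for rotation matrices.
ROTATION_TOL = 1e-10


class EulerAngles(NamedTuple):
    """Euler angle triple in degrees: rotations about z, y, x (applied in
    that order, fixed frame)."""

    phi: float = 0.0
    theta: float = 0.0
    psi: float = 0.0


def as_angle_array(angles) -> np.ndarray:
    """Coerce angles to a float array of shape (n, 3).

    Accepts an (n, 3) array of Euler triples, an (n,) array of single-axis
    tilt angles theta (phi = psi = 0), or a list of ``EulerAngles`` /
    3-tuples.
    """
    arr = np.asarray(angles, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.ndim == 1:
        out = np.zeros((arr.shape[0], 3))
        out[:, 1] = arr
        arr = out
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"angles must have shape (n,), (n, 3) or be Euler triples; got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("angles must be finite")
    return arr


def is_single_axis(angles) -> bool:
    """True if every orientation is a pure tilt about y (phi = psi = 0)."""
    arr = as_angle_array(angles)
    return bool(np.all(arr[:, 0] == 0.0) and np.all(arr[:, 2] == 0.0))


def euler_to_matrix(angles) -> np.ndarray:
    """Rotation matrix ``Z_phi @ Y_theta @ X_psi`` for Euler angles in degrees.

    Parameters
    ----------
    angles
        ``EulerAngles``, a 3-sequence ``(phi, theta, psi)`` in degrees, or a
        scalar ``theta`` (single-axis shorthand).

    Returns
    -------
    numpy.ndarray
        Orthogonal 3x3 matrix with determinant +1.
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim == 0:
        a = np.array([0.0, float(a), 0.0])
    if a.shape != (3,):
        raise ValueError(f"expected a single Euler triple, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("Euler angles must be finite")
    phi, theta, psi = np.deg2rad(a)

    cz, sz = np.cos(phi), np.sin(phi)
    cy, sy = np.cos(theta), np.sin(theta)
    cx, sx = np.cos(psi), np.sin(psi)

    Z = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    Y = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    X = np.array([[1.0, 0.0, 0.0], [0.0, cx, -sx], [0.0, sx, cx]])
    return Z @ Y @ X


def slice_transform(R: np.ndarray, w: float) -> tuple[np.ndarray, np.ndarray]:
    """In-plane affine map taking object-slice coordinates to detector
    coordinates.

    For a voxel at center-relative coordinates ``(u, v, w)`` the detector
    coordinates are ``[x; y] = A @ [u; v] + s`` where ``A`` collects the
    upper-left transpose block of ``R`` and the shift ``s`` is linear in the
    slice index ``w``:

    ``A = [[R11, R21], [R12, R22]]`` and ``s = w * [R31, R32]``
    (1-based element indices).  Every ``w != 0`` slice therefore sees the
    same linear map as the ``w = 0`` slice followed by a translation.

    Parameters
    ----------
    R
        3x3 rotation matrix (orthogonal within ``ROTATION_TOL``).
    w
        Plane index along the beam axis, relative to the rotation center.

    Returns
    -------
    (A, s)
        2x2 linear map and length-2 shift vector.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("R must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
        raise ValueError("R must be orthogonal")
    A = np.array([[R[0, 0], R[1, 0]], [R[0, 1], R[1, 1]]])
    s = float(w) * np.array([R[2, 0], R[2, 1]])
    return A, s
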
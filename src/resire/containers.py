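"""Tilt-series container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import as_angle_array

__all__ = ["ProjectionStack"]


@dataclass
class ProjectionStack:
    """An ordered tilt series: n projection images paired 1:1 with Euler
    angle triples.

    Attributes
    ----------
    images : numpy.ndarray
        Shape ``(n, Nx, Ny)``, real-valued.
    angles : numpy.ndarray
        Shape ``(n, 3)`` Euler angles ``(phi, theta, psi)`` in degrees.
        A 1D array of tilt angles theta is accepted and expanded.
    """

    images: np.ndarray
    angles: np.ndarray = field(default=None)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError(f"images must have shape (n, Nx, Ny), got {self.images.shape}")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("projection images contain non-finite values")
        if self.angles is None:
            raise ValueError("a tilt series requires one Euler triple per image")
        self.angles = as_angle_array(self.angles)
        if len(self.angles) != len(self.images):
            raise ValueError(
                f"{len(self.images)} images but {len(self.angles)} angle rows"
            )
        if len(self.images) < 1:
            raise ValueError("a tilt series needs at least one projection")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    def with_angles(self, angles) -> "ProjectionStack":
        """Same images, new angles (used by angular refinement)."""
        return ProjectionStack(self.images.copy(), angles)
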
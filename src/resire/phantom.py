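"""Synthetic tilt-series generation.

The generator emulates a missing-wedge electron-tomography experiment on
a vesicle-like object: a 64^3 volume of nested ellipsoidal membrane
shells with interior blobs, projected over a single y tilt axis
(+-70 degrees, 3.5 degree increment -> 41 projections), with optional
Poisson counting noise and Gaussian perturbation of the nominal tilt
angles (used by the angular-refinement tests).

All randomness flows from explicit integer seeds; fixed seeds give
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import ProjectionStack
from .geometry import as_angle_array
from .projectors import make_radon_operator

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "make_vesicle_phantom",
    "simulate_tilt_series",
    "tilt_angles",
    "perturb_angles",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Solid ellipsoid feature: center offset (voxels, relative to the
    grid center), semi-axes, density added inside."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    density: float

    def analytic_volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class Shell:
    """Ellipsoidal shell (membrane): density added between the outer
    ellipsoid and the one shrunk by ``thickness`` on every semi-axis."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    thickness: float
    density: float

    def analytic_volume(self) -> float:
        a, b, c = self.semi_axes
        t = self.thickness
        inner = max(a - t, 0.0) * max(b - t, 0.0) * max(c - t, 0.0)
        return 4.0 / 3.0 * np.pi * (a * b * c - inner)


def _default_shells() -> list[Shell]:
    # outer membrane slightly off-center + a nested inner vesicle:
    # the offsets break every rotational symmetry so projections at
    # distinct tilt angles differ (required by angular refinement).
    return [
        Shell(center=(1.5, -1.0, 0.5), semi_axes=(24.0, 21.0, 18.0), thickness=2.5, density=1.0),
        Shell(center=(-5.0, 4.0, -3.0), semi_axes=(9.0, 8.0, 7.0), thickness=2.0, density=0.8),
    ]


@dataclass
class PhantomSpec:
    """Parameters of the vesicle-like phantom.

    All features must fit inside a centered ball of diameter
    ``0.9 * size`` so that any rotation keeps the object on the detector.
    """

    size: int = 64
    shells: Sequence[Shell] = field(default_factory=_default_shells)
    n_blobs: int = 6
    blob_radius: tuple[float, float] = (2.0, 3.5)
    blob_density: tuple[float, float] = (0.6, 1.4)
    seed: int = 7

    def scaled(self, size: int) -> "PhantomSpec":
        """Same morphology on a different grid size (features scale
        proportionally)."""
        f = size / self.size
        shells = [
            Shell(tuple(np.array(s.center) * f), tuple(np.array(s.semi_axes) * f),
                  s.thickness * f, s.density)
            for s in self.shells
        ]
        return PhantomSpec(size=size, shells=shells, n_blobs=self.n_blobs,
                           blob_radius=(self.blob_radius[0] * f, self.blob_radius[1] * f),
                           blob_density=self.blob_density, seed=self.seed)


@dataclass
class NoiseSpec:
    """Poisson counting-noise parameters.

    ``mean_counts`` is the expected count at the brightest pixel of each
    projection: the image is scaled so its maximum equals ``mean_counts``,
    Poisson sampled, then rescaled back.
    """

    mean_counts: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if not self.mean_counts > 0:
            raise ValueError(f"mean_counts must be positive, got {self.mean_counts}")


def _check_inside(center, reach, size):
    safe = 0.45 * size  # radius of the 0.9*size ball
    if np.linalg.norm(center) + reach > safe:
        raise ValueError(
            f"feature at {tuple(center)} with extent {reach:.1f} leaves the safe "
            f"ball of radius {safe:.1f} (rotations would fall off the detector)"
        )


def _ellipsoid_field(size, center, semi_axes, supersample=2):
    """Anti-aliased indicator of an ellipsoid, evaluated on a supersampled
    grid and averaged (reduces voxelization error on the surface)."""
    ss = supersample
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    c = size // 2
    base = np.arange(size) - c
    out = np.zeros((size, size, size))
    for du in offs:
        for dv in offs:
            for dw in offs:
                xu = (base + du - center[0]) / semi_axes[0]
                xv = (base + dv - center[1]) / semi_axes[1]
                xw = (base + dw - center[2]) / semi_axes[2]
                q = (xu**2)[:, None, None] + (xv**2)[None, :, None] + (xw**2)[None, None, :]
                out += q <= 1.0
    return out / ss**3


def make_vesicle_phantom(spec: Optional[PhantomSpec] = None, supersample: int = 2) -> np.ndarray:
    """Build the vesicle-like phantom volume (nonnegative, deterministic
    given ``spec.seed``).

    Feature densities are additive; the total mass is the sum of analytic
    feature volumes times densities, up to voxelization error.
    """
    if spec is None:
        spec = PhantomSpec()
    size = int(spec.size)
    vol = np.zeros((size, size, size))
    for sh in spec.shells:
        _check_inside(sh.center, max(sh.semi_axes), size)
        outer = _ellipsoid_field(size, sh.center, sh.semi_axes, supersample)
        inner_axes = tuple(max(a - sh.thickness, 0.0) for a in sh.semi_axes)
        if min(inner_axes) > 0:
            inner = _ellipsoid_field(size, sh.center, inner_axes, supersample)
        else:
            inner = 0.0
        vol += sh.density * (outer - inner)

    rng = np.random.default_rng(spec.seed)
    r_lo, r_hi = spec.blob_radius
    d_lo, d_hi = spec.blob_density
    placed = 0
    while placed < spec.n_blobs:
        center = rng.uniform(-0.18 * size, 0.18 * size, size=3)
        radius = rng.uniform(r_lo, r_hi)
        density = rng.uniform(d_lo, d_hi)
        _check_inside(center, radius, size)
        vol += density * _ellipsoid_field(size, center, (radius,) * 3, supersample)
        placed += 1
    return np.clip(vol, 0.0, None)


def phantom_analytic_mass(spec: Optional[PhantomSpec] = None) -> float:
    """Sum of analytic feature volumes times densities (oracle for the
    voxelized mass; blob contributions require the matching seed)."""
    if spec is None:
        spec = PhantomSpec()
    total = sum(sh.density * sh.analytic_volume() for sh in spec.shells)
    rng = np.random.default_rng(spec.seed)
    r_lo, r_hi = spec.blob_radius
    d_lo, d_hi = spec.blob_density
    for _ in range(spec.n_blobs):
        rng.uniform(-0.18 * spec.size, 0.18 * spec.size, size=3)
        radius = rng.uniform(r_lo, r_hi)
        density = rng.uniform(d_lo, d_hi)
        total += density * 4.0 / 3.0 * np.pi * radius**3
    return float(total)


def tilt_angles(tilt_range: tuple[float, float], increment: float) -> np.ndarray:
    """Single-axis tilt angles from min to max inclusive at the given
    increment, as (n, 3) Euler triples (phi = psi = 0)."""
    lo, hi = (float(t) for t in tilt_range)
    if not increment > 0:
        raise ValueError(f"angular increment must be positive, got {increment}")
    if hi < lo:
        lo, hi = hi, lo
    thetas = lo + increment * np.arange(int(np.floor((hi - lo) / increment + 0.5)) + 1)
    thetas = thetas[thetas <= hi + 1e-9]
    if len(thetas) == 0:
        raise ValueError("empty tilt-angle list")
    return as_angle_array(thetas)


def simulate_tilt_series(volume, tilt_range=(-70.0, 70.0), increment: float = 3.5,
                         noise: Optional[NoiseSpec] = None,
                         subdivision: int = 4) -> ProjectionStack:
    """Simulate a single-tilt-axis series of a volume.

    Projections are computed with the Radon projector at high sub-voxel
    subdivision (default 4 per axis).  If ``noise`` is given, each image
    is scaled so its maximum equals ``noise.mean_counts``, Poisson
    sampled, and rescaled (bright projections are less noisy, as in a
    dose-limited experiment).
    """
    vol = np.asarray(volume, dtype=float)
    angles = tilt_angles(tilt_range, increment)
    images = np.stack(
        [make_radon_operator(vol.shape, a, subdivision).forward(vol) for a in angles]
    )
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        noisy = np.empty_like(images)
        for i, img in enumerate(images):
            peak = img.max()
            if peak <= 0:
                noisy[i] = img
                continue
            scale = noise.mean_counts / peak
            noisy[i] = rng.poisson(np.clip(img, 0.0, None) * scale) / scale
        images = noisy
    return ProjectionStack(images, angles)


def perturb_angles(angles, sigma: float, seed: int = 0) -> np.ndarray:
    """Add independent Gaussian errors (sd ``sigma`` degrees) to the theta
    component of every orientation; phi and psi are untouched."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    arr = as_angle_array(angles).copy()
    rng = np.random.default_rng(seed)
    arr[:, 1] += rng.normal(0.0, sigma, size=len(arr)) if sigma > 0 else 0.0
    return arr
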
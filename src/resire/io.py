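"""File I/O: MRC volumes/stacks, plain-text angle tables, FSC curves and
run manifests.

Angle files are whitespace-separated text, one row per projection: either
one column (the tilt angle theta; phi = psi = 0) or three columns
(phi theta psi), all in degrees.  Volumes and stacks are MRC2014.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .containers import ProjectionStack
from .geometry import as_angle_array
from .metrics import FscCurve
from .mrc import read_mrc, write_mrc

__all__ = [
    "read_angles",
    "write_angles",
    "read_volume",
    "write_volume",
    "read_projection_stack",
    "write_projection_stack",
    "write_fsc",
    "read_fsc",
    "RunManifest",
]


def read_angles(path) -> np.ndarray:
    """Parse an angle table into (n, 3) Euler triples in degrees."""
    rows = np.atleast_1d(np.loadtxt(path, dtype=float, ndmin=2))
    if rows.shape[1] == 1:
        return as_angle_array(rows[:, 0])
    if rows.shape[1] == 3:
        return as_angle_array(rows)
    raise ValueError(
        f"{path}: angle files need 1 column (theta) or 3 (phi theta psi); found {rows.shape[1]}"
    )


def write_angles(path, angles) -> None:
    """Write Euler angles as a 3-column text table (degrees)."""
    arr = as_angle_array(angles)
    np.savetxt(path, arr, fmt="%.6f", header="phi theta psi (degrees)")


def write_volume(volume, path, voxel_size: float = 1.0) -> None:
    """Write a 3D volume as MRC2014 (refuses non-finite data)."""
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {vol.shape}")
    write_mrc(path, vol, voxel_size)


def read_volume(path) -> np.ndarray:
    """Read an MRC2014 volume as (nx, ny, nz)."""
    return read_mrc(path)


def write_projection_stack(stack: ProjectionStack, path, angle_path=None) -> None:
    """Write a tilt series as an MRC stack (sections = images); optionally
    write the paired angle table."""
    # images are (n, Nx, Ny); on disk sections are the slow axis, with
    # (rows, columns) = (Ny, Nx), so feed write_mrc an (x, y, n) array
    write_mrc(path, np.transpose(stack.images, (1, 2, 0)))
    if angle_path is not None:
        write_angles(angle_path, stack.angles)


def read_projection_stack(path, angle_path) -> ProjectionStack:
    """Read an MRC image stack plus its angle table into a validated
    :class:`ProjectionStack`.

    Raises a format error when the image count and the angle-row count
    disagree.
    """
    data = read_mrc(path)  # (nx, ny, n)
    images = np.transpose(data, (2, 0, 1)).astype(float)
    angles = read_angles(angle_path)
    if len(angles) != images.shape[0]:
        raise ValueError(
            f"{path} holds {images.shape[0]} images but {angle_path} has "
            f"{len(angles)} angle rows"
        )
    return ProjectionStack(images, angles)


def write_fsc(curve: FscCurve, path) -> None:
    """Write an FSC curve as 2-column text (frequency, correlation)."""
    np.savetxt(
        path,
        np.column_stack([curve.shell_frequency, curve.correlation]),
        fmt="%.6f",
        header="spatial_frequency(cycles/voxel) correlation",
    )


def read_fsc(path) -> FscCurve:
    data = np.loadtxt(path, ndmin=2)
    return FscCurve(data[:, 0], data[:, 1])


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output: the full
    configuration, input digests, seeds and convergence trace."""

    command: str
    config: dict
    inputs: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    axis_convention: str = (
        "volume (x, y, z) with z the beam axis at zero tilt; MRC sections are z; "
        "rotation center index N//2; Euler angles (phi, theta, psi) about z, y, x, degrees"
    )
    sse_trace: Optional[list] = None
    r_factor_trace: Optional[list] = None
    final_r_factor: Optional[float] = None
    wall_clock_s: Optional[float] = None

    def add_input(self, label, path) -> None:
        self.inputs[label] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
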
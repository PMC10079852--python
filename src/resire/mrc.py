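"""Minimal MRC2014 volume/stack I/O.

Implements the subset of the MRC2014 format needed for tomography
exchange: a 1024-byte header followed by the data block, little-endian,
modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16).  Data are stored
section-by-section (z slowest), so a volume indexed ``(x, y, z)`` in this
package maps to a file array of shape ``(nz, ny, nx)``.
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["read_mrc", "write_mrc"]

_MODE_DTYPES = {
    0: np.dtype("<i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}
_DTYPE_MODES = {v: k for k, v in _MODE_DTYPES.items()}

_HEADER_SIZE = 1024
# little-endian machine stamp per MRC2014
_MACHST = b"\x44\x44\x00\x00"


def write_mrc(path, data: np.ndarray, voxel_size: float = 1.0) -> None:
    """Write a 2D image, 3D volume or image stack as MRC2014.

    3D input is interpreted as ``(x, y, z)`` ((image, x, y) for stacks is
    the caller's convention — the axes written are (sections, rows,
    columns) either way).  float64 input is stored as float32 (mode 2).
    """
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError(f"MRC data must be 2D or 3D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("refusing to write non-finite data to MRC")

    if arr.dtype in _DTYPE_MODES:
        out = arr
    else:
        out = arr.astype(np.float32)
    mode = _DTYPE_MODES[np.dtype(out.dtype.str.replace(">", "<"))]
    out = out.astype(out.dtype.newbyteorder("<"))

    nx, ny, nz = out.shape  # (columns, rows, sections) in file terms
    file_arr = np.ascontiguousarray(np.transpose(out, (2, 1, 0)))

    fdata = out.astype(np.float64)
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)           # nxstart..
    struct.pack_into("<3i", header, 28, nx, ny, nz)        # mx, my, mz
    struct.pack_into("<3f", header, 40, *(voxel_size * n for n in (nx, ny, nz)))
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)           # mapc, mapr, maps
    struct.pack_into("<3f", header, 76, float(fdata.min()), float(fdata.max()), float(fdata.mean()))
    struct.pack_into("<i", header, 88, 1)                  # ispg: volume
    struct.pack_into("<i", header, 92, 0)                  # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = _MACHST
    struct.pack_into("<f", header, 216, float(fdata.std()))
    struct.pack_into("<i", header, 220, 0)                 # nlabl

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(file_arr.tobytes())


def read_mrc(path) -> np.ndarray:
    """Read an MRC2014 file; returns an array of shape (nx, ny, nz)
    (the transpose of the on-disk section order)."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header ({len(header)} bytes)")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise ValueError(f"{path}: missing MAP identifier; not an MRC2014 file")
        if mode not in _MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        if min(nx, ny, nz) < 1:
            raise ValueError(f"{path}: invalid dimensions ({nx}, {ny}, {nz})")
        fh.seek(_HEADER_SIZE + max(nsymbt, 0))
        dtype = _MODE_DTYPES[mode]
        count = nx * ny * nz
        raw = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype, count=count)
        if raw.size != count:
            raise ValueError(f"{path}: data block shorter than header promises")
    return np.transpose(raw.reshape(nz, ny, nx), (2, 1, 0))
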
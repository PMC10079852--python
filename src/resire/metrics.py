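"""Error and resolution metrics: R-factor, Fourier shell correlation,
angle RMSE."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["r_factor", "r_factor_images", "fsc", "FscCurve", "angle_rmse"]


def _image_arrays(stack):
    from .containers import ProjectionStack

    if isinstance(stack, ProjectionStack):
        return stack.images
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a stack of 2D images, got shape {arr.shape}")
    return arr


def r_factor_images(calculated: np.ndarray, measured: np.ndarray, strict: bool = False) -> float:
    """R-factor of paired image arrays: per projection
    ``sum|calc - meas| / sum|meas|``, averaged over projections.

    With ``strict=False`` (solver-internal use), projections whose
    measured mass is zero contribute 0 when the residual is also zero
    (the degenerate all-zero series has a well-defined fixed point).
    """
    num = np.abs(calculated - measured).sum(axis=(1, 2))
    den = np.abs(measured).sum(axis=(1, 2))
    if np.any(den == 0):
        if strict:
            raise ValueError("R-factor undefined: a measured projection has zero absolute sum")
        ratios = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.where(num > 0, np.inf, 0.0))
    else:
        ratios = num / den
    return float(ratios.mean())


def r_factor(calculated, measured) -> float:
    """R-factor between calculated and measured tilt series.

    .. math::

        R_F = \\frac{1}{n} \\sum_\\theta
            \\frac{\\sum_{x,y} |\\Pi_\\theta(O)\\{x,y\\} - b_\\theta\\{x,y\\}|}
                 {\\sum_{x,y} |b_\\theta\\{x,y\\}|}

    Accepts ``ProjectionStack`` objects or image arrays of matching
    shape.  Raises if any measured projection has zero absolute sum
    (undefined normalization).
    """
    c = _image_arrays(calculated)
    m = _image_arrays(measured)
    if c.shape != m.shape:
        raise ValueError(f"stacks are not conformable: {c.shape} vs {m.shape}")
    return r_factor_images(c, m, strict=True)


@dataclass
class FscCurve:
    """Fourier shell correlation curve.

    Attributes
    ----------
    shell_frequency : numpy.ndarray
        Spatial frequency at each shell center, cycles/voxel (shell width
        is one Fourier voxel, DC to Nyquist).
    correlation : numpy.ndarray
        Normalized cross-correlation per shell, in [-1, 1]; NaN for empty
        shells.
    """

    shell_frequency: np.ndarray
    correlation: np.ndarray

    def __len__(self) -> int:
        return len(self.correlation)


def fsc(volume_a, volume_b) -> FscCurve:
    """Fourier shell correlation between two equally shaped volumes.

    Per radial shell k (width one Fourier voxel):
    ``Re(sum F_a conj(F_b)) / sqrt(sum|F_a|^2 * sum|F_b|^2)``.
    """
    a = np.asarray(volume_a, dtype=float)
    b = np.asarray(volume_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"volumes differ in shape: {a.shape} vs {b.shape}")
    Fa = np.fft.fftn(a)
    Fb = np.fft.fftn(b)

    grids = np.meshgrid(*(np.fft.fftfreq(n) * n for n in a.shape), indexing="ij")
    radius = np.sqrt(sum(g**2 for g in grids))
    nyquist = min(a.shape) // 2
    shell = np.rint(radius).astype(int)

    cross = np.real(Fa * np.conj(Fb))
    pa = np.abs(Fa) ** 2
    pb = np.abs(Fb) ** 2

    keep = shell <= nyquist
    idx = shell[keep].ravel()
    num = np.bincount(idx, weights=cross[keep].ravel(), minlength=nyquist + 1)
    da = np.bincount(idx, weights=pa[keep].ravel(), minlength=nyquist + 1)
    db = np.bincount(idx, weights=pb[keep].ravel(), minlength=nyquist + 1)

    denom = np.sqrt(da * db)
    corr = np.full(nyquist + 1, np.nan)
    ok = denom > 0
    corr[ok] = num[ok] / denom[ok]
    freq = np.arange(nyquist + 1) / min(a.shape)
    return FscCurve(freq, corr)


def angle_rmse(true_angles, estimated) -> float:
    """Root-mean-square angle residual in degrees.

    For 1D inputs (single-axis tilt angles theta) this is
    ``sqrt(mean((theta_true - theta_est)^2))``; for (n, 3) Euler triples
    the RMS runs over all three angle residuals.
    """
    t = np.asarray(true_angles, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if t.shape != e.shape:
        raise ValueError(f"angle lists differ in shape: {t.shape} vs {e.shape}")
    if t.ndim not in (1, 2):
        raise ValueError("angles must be a 1D theta list or an (n, 3) triple list")
    return float(np.sqrt(np.mean((t - e) ** 2)))
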
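"""Gradient-descent least-squares reconstruction.

The reconstruction minimizes the sum of squared errors

    eps(O) = 1/2 * sum_theta || Pi_theta(O) - b_theta ||_F^2

over the volume ``O``, where ``Pi_theta`` is the forward projector and
``b_theta`` the measured projections.  The gradient of each per-angle term
is the back projection of the projection residual, and the accumulated
gradient is ``nN_z``-Lipschitz (``n`` projections, ``N_z`` voxels along
the beam axis), so the update

    O <- O - t/(n*N_z) * sum_theta grad eps_theta(O)

converges at rate O(1/k) for normalized step ``t <= 1``; in practice
``t = 2`` is stable and is the default.  Optional positivity and support
constraints are applied after each update (projected gradient descent).

The model/results split follows the usual statsmodels pattern::

    model = Resire(stack, iterations=150, positivity=True)
    res = model.fit()
    res.volume, res.r_factor, res.summary()
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import ProjectionStack
from .metrics import r_factor_images
from .projectors import make_radon_operator, project_fst

__all__ = [
    "ReconstructionConfig",
    "ConvergenceRecord",
    "Resire",
    "ResireResults",
    "resire_reconstruct",
    "step_size",
    "compute_gradient",
    "apply_constraints",
]


@dataclass
class ReconstructionConfig:
    """Reconstruction parameters.

    Attributes
    ----------
    t : float
        Normalized gradient-descent step; the actual step is
        ``t / (n * N_z)``.  ``t <= 1`` guarantees monotone convergence;
        the default 2 is empirically stable and faster.
    iterations : int
        Fixed iteration count (default 150).
    projector : str
        ``"radon"`` (real-space, exact adjoint pair; default) or
        ``"fst"`` (Fourier-slice forward, Radon-adjoint back projection).
    oversampling : float
        Zero-padding ratio for the FST projector (default 3).
    subdivision : int
        Sub-voxels per axis for the Radon projector (default 2).
    positivity : bool
        Clip negative voxels after each update (default True).
    support : numpy.ndarray or None
        Optional binary mask; voxels outside it are zeroed after each
        update.
    tol : float or None
        Optional early stop: halt when ``|R_F[k] - R_F[k-10]| < tol``.
        Off by default (fixed iteration count).
    """

    t: float = 2.0
    iterations: int = 150
    projector: str = "radon"
    oversampling: float = 3.0
    subdivision: int = 2
    positivity: bool = True
    support: Optional[np.ndarray] = None
    tol: Optional[float] = None

    def __post_init__(self):
        if not self.t > 0:
            raise ValueError(f"normalized step t must be positive, got {self.t}")
        if int(self.iterations) < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        self.iterations = int(self.iterations)
        if self.projector not in ("radon", "fst"):
            raise ValueError(f"projector must be 'radon' or 'fst', got {self.projector!r}")
        if not self.oversampling >= 1:
            raise ValueError(f"oversampling ratio must be >= 1, got {self.oversampling}")
        if int(self.subdivision) < 1:
            raise ValueError(f"subdivision must be >= 1, got {self.subdivision}")
        self.subdivision = int(self.subdivision)
        if self.support is not None:
            self.support = np.asarray(self.support).astype(bool)


@dataclass
class ConvergenceRecord:
    """Per-iteration objective trace.

    ``sse[k]`` and ``r_factor[k]`` are evaluated from the projections of
    the (constraint-projected) iterate after ``k + 1`` updates.
    """

    sse: np.ndarray
    r_factor: np.ndarray

    def __len__(self) -> int:
        return len(self.sse)


def step_size(t: float, n: int, n_z: int) -> float:
    """Gradient-descent step ``t / (n * N_z)`` for ``n`` projections and a
    beam-axis extent of ``N_z`` voxels (the accumulated Lipschitz bound of
    the gradient is ``n * N_z``)."""
    if not (t > 0 and n > 0 and n_z > 0):
        raise ValueError(f"step_size arguments must be positive, got {(t, n, n_z)}")
    return float(t) / (float(n) * float(n_z))


def apply_constraints(volume: np.ndarray, config: ReconstructionConfig) -> np.ndarray:
    """Real-space constraints: support mask first, then positivity."""
    out = np.asarray(volume, dtype=float)
    if config.support is not None:
        if config.support.shape != out.shape:
            raise ValueError(
                f"support mask shape {config.support.shape} does not match volume {out.shape}"
            )
        out = np.where(config.support, out, 0.0)
    if config.positivity:
        out = np.maximum(out, 0.0)
    return out


def _forward_stack(volume, stack, config, ops):
    """Forward projections of ``volume`` at every stack angle."""
    if config.projector == "fst":
        return np.stack([project_fst(volume, a, config.oversampling) for a in stack.angles])
    return np.stack([op.forward(volume) for op in ops])


def _make_ops(shape, stack, config):
    return [make_radon_operator(shape, a, config.subdivision) for a in stack.angles]


def compute_gradient(volume, stack: ProjectionStack, config: ReconstructionConfig) -> np.ndarray:
    """Accumulated gradient ``sum_theta Pi^T(Pi(volume) - b_theta)``."""
    vol = np.asarray(volume, dtype=float)
    if len(stack) < 1:
        raise ValueError("projection stack is empty")
    if stack.image_shape != vol.shape[:2]:
        raise ValueError(
            f"stack in-plane shape {stack.image_shape} does not match volume {vol.shape[:2]}"
        )
    ops = _make_ops(vol.shape, stack, config)
    calc = _forward_stack(vol, stack, config, ops)
    grad = np.zeros_like(vol)
    for op, c, b in zip(ops, calc, stack.images):
        grad += op.adjoint(c - b)
    return grad


class Resire:
    """Least-squares tomographic reconstruction model for one tilt series.

    Parameters
    ----------
    stack : ProjectionStack or numpy.ndarray
        Measured projections; if an array, ``angles`` must be given.
    angles : array-like, optional
        Euler angles in degrees, one row per image ((n,) tilt angles or
        (n, 3) triples).
    n_z : int, optional
        Beam-axis extent of the reconstruction grid; defaults to the
        in-plane x-extent (cubic grid).
    config : ReconstructionConfig, optional
        Full parameter set; keyword arguments override individual fields.
    """

    def __init__(self, stack, angles=None, *, n_z: Optional[int] = None,
                 config: Optional[ReconstructionConfig] = None, **kwargs):
        if not isinstance(stack, ProjectionStack):
            stack = ProjectionStack(stack, angles)
        elif angles is not None:
            stack = stack.with_angles(angles)
        self.stack = stack
        if config is None:
            config = ReconstructionConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either config or keyword overrides, not both")
        self.config = config
        nx, ny = stack.image_shape
        self.shape = (nx, ny, int(n_z) if n_z is not None else nx)
        if config.support is not None and config.support.shape != self.shape:
            raise ValueError(
                f"support mask shape {config.support.shape} does not match volume {self.shape}"
            )

    @property
    def n(self) -> int:
        return len(self.stack)

    @property
    def step(self) -> float:
        return step_size(self.config.t, self.n, self.shape[2])

    def fit(self, initial=None, callback=None) -> "ResireResults":
        """Run the gradient-descent iteration.

        Parameters
        ----------
        initial : numpy.ndarray, optional
            Warm-start volume (default: zeros — an empty object).
        callback : callable, optional
            ``callback(k, volume, sse, r_factor)`` after each iteration.

        Raises
        ------
        RuntimeError
            If the objective becomes non-finite (divergence), naming the
            iteration at which it happened.
        """
        cfg = self.config
        b = self.stack.images
        if initial is None:
            vol = np.zeros(self.shape)
        else:
            vol = np.array(initial, dtype=float)
            if vol.shape != self.shape:
                raise ValueError(f"initial volume shape {vol.shape} != {self.shape}")
        ops = _make_ops(self.shape, self.stack, cfg)
        s = self.step

        sse_trace, rf_trace = [], []
        t0 = time.perf_counter()
        calc = _forward_stack(vol, self.stack, cfg, ops)
        for k in range(cfg.iterations):
            resid = calc - b
            grad = np.zeros_like(vol)
            for op, r in zip(ops, resid):
                grad += op.adjoint(r)
            vol = apply_constraints(vol - s * grad, cfg)

            calc = _forward_stack(vol, self.stack, cfg, ops)
            sse = 0.5 * float(np.sum((calc - b) ** 2))
            rf = r_factor_images(calc, b)
            if not np.isfinite(sse):
                raise RuntimeError(f"reconstruction diverged (non-finite SSE) at iteration {k + 1}")
            sse_trace.append(sse)
            rf_trace.append(rf)
            if callback is not None:
                callback(k, vol, sse, rf)
            if cfg.tol is not None and k >= 10 and abs(rf_trace[-11] - rf) < cfg.tol:
                break
        elapsed = time.perf_counter() - t0
        record = ConvergenceRecord(np.asarray(sse_trace), np.asarray(rf_trace))
        return ResireResults(self, vol, record, elapsed)


class ResireResults:
    """Fitted reconstruction: the volume, its convergence trace and
    fidelity diagnostics."""

    def __init__(self, model: Resire, volume: np.ndarray,
                 record: ConvergenceRecord, elapsed: float = float("nan")):
        self.model = model
        self.volume = volume
        self.record = record
        self.elapsed = elapsed

    @property
    def sse(self) -> float:
        """Final sum of squared errors (1/2 * sum of squared residuals)."""
        return float(self.record.sse[-1])

    @property
    def r_factor(self) -> float:
        """Final R-factor (mean per-projection normalized absolute residual)."""
        return float(self.record.r_factor[-1])

    def project(self, angles=None) -> np.ndarray:
        """Forward projections of the reconstruction (defaults to the
        measured tilt angles)."""
        cfg = self.model.config
        from .geometry import as_angle_array

        ang = self.model.stack.angles if angles is None else as_angle_array(angles)
        if cfg.projector == "fst":
            return np.stack([project_fst(self.volume, a, cfg.oversampling) for a in ang])
        return np.stack(
            [make_radon_operator(self.volume.shape, a, cfg.subdivision).forward(self.volume)
             for a in ang]
        )

    def summary(self) -> str:
        m, cfg = self.model, self.model.config
        lines = [
            "RESIRE reconstruction results",
            "=============================",
            f"projections (n):      {m.n}",
            f"volume shape:         {m.shape}",
            f"projector:            {cfg.projector}"
            + (f" (OR={cfg.oversampling:g})" if cfg.projector == "fst"
               else f" (subdivision={cfg.subdivision})"),
            f"iterations run:       {len(self.record)} (of {cfg.iterations})",
            f"normalized step t:    {cfg.t:g}  (step = t/(n*N_z) = {m.step:.4e})",
            f"positivity:           {cfg.positivity}",
            f"support mask:         {'yes' if cfg.support is not None else 'no'}",
            f"final SSE:            {self.sse:.6e}",
            f"final R-factor:       {self.r_factor:.4%}",
        ]
        if np.isfinite(self.elapsed):
            lines.append(f"wall-clock:           {self.elapsed:.1f} s")
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Plot the R-factor and SSE traces against iteration number."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = np.arange(1, len(self.record) + 1)
        ax.plot(k, self.record.r_factor, label="R-factor")
        ax.set_xlabel("iteration")
        ax.set_ylabel("R-factor", color="C0")
        ax2 = ax.twinx()
        ax2.semilogy(k, self.record.sse, color="C1", label="SSE")
        ax2.set_ylabel("SSE", color="C1")
        return ax


def resire_reconstruct(stack: ProjectionStack, config: ReconstructionConfig,
                       initial=None, n_z: Optional[int] = None):
    """Functional entry point: returns ``(volume, ConvergenceRecord)``."""
    res = Resire(stack, config=config, n_z=n_z).fit(initial=initial)
    return res.volume, res.record
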
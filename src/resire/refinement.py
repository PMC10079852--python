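"""Brute-force projection-matching angular refinement.

Measured tilt angles carry errors (stage drift, motor slip, beam-induced
motion).  The refinement loop alternates between reconstructing with the
current angles and, for each projection independently, evaluating a fixed
grid of candidate Euler angles centered on that projection's *initial*
angles; the candidate whose calculated projection best matches the
measured one (smallest single-projection R-factor) is kept.  Rounds
repeat until no angle changes or the round budget is exhausted.

Identifiability: for a single-axis series, tilt-angle errors that vary
smoothly with tilt index are nearly indistinguishable from a consistent
reorientation or warp of the reconstructed object.  A common offset added
to every theta is an exact gauge direction (it merely rotates the
reconstruction), and low-order polynomial drifts are close to one.
Projection matching cannot determine those components, and left free they
accumulate per-round matching noise as a random walk.  The refinement
therefore projects the theta corrections onto the complement of the
low-order polynomial subspace (order ``gauge_order``, default quadratic),
keeping the smooth components at their initially calibrated values and
refining only the rapidly varying per-projection components the data
constrain.

For a single-axis series the phi/psi search ranges default to zero, which
cuts the candidate grid from cubic to linear size; set ``delta_phi`` /
``delta_psi`` to search all three angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import ProjectionStack
from .geometry import as_angle_array
from .metrics import angle_rmse
from .model import ReconstructionConfig, Resire
from .projectors import make_radon_operator, project_fst

__all__ = [
    "RefinementConfig",
    "score_candidate",
    "refine_angles",
    "refine_angles_full",
    "RefinementResult",
]


@dataclass
class RefinementConfig:
    """Angular refinement parameters.

    Search half-ranges (degrees) define the fixed candidate window around
    each projection's initial angles; the suggested window is +-3 degrees
    (brute force is only affordable on a small window).  ``grid_step`` is
    the search grid spacing; ``rounds`` caps the outer reconstruct/search
    loop.  ``gauge_order`` is the polynomial order of the smooth
    (quasi-gauge) theta-correction components withheld from refinement;
    set it to ``None`` to disable the filter.
    """

    delta_phi: float = 0.0
    delta_theta: float = 3.0
    delta_psi: float = 0.0
    grid_step: float = 0.5
    rounds: int = 5
    gauge_order: Optional[int] = 2
    solver_config: ReconstructionConfig = field(default_factory=ReconstructionConfig)

    def __post_init__(self):
        for name in ("delta_phi", "delta_theta", "delta_psi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.grid_step > 0:
            raise ValueError(f"grid_step must be positive, got {self.grid_step}")
        if int(self.rounds) < 1:
            raise ValueError(f"rounds must be >= 1, got {self.rounds}")
        self.rounds = int(self.rounds)
        if self.gauge_order is not None and int(self.gauge_order) < 0:
            raise ValueError(f"gauge_order must be >= 0 or None, got {self.gauge_order}")

    def offsets(self, half_range: float) -> np.ndarray:
        """Symmetric grid offsets covering [-half_range, +half_range];
        always includes 0 so the initial angle stays in the grid."""
        if half_range == 0:
            return np.array([0.0])
        if self.grid_step > 2 * half_range:
            raise ValueError(
                f"grid_step {self.grid_step} exceeds the search window of half-range {half_range}"
            )
        k = int(np.floor(half_range / self.grid_step + 1e-9))
        return self.grid_step * np.arange(-k, k + 1)


def _project_at(volume, angles, config: ReconstructionConfig) -> np.ndarray:
    if config.projector == "fst":
        return project_fst(volume, angles, config.oversampling)
    return make_radon_operator(volume.shape, angles, config.subdivision).forward(volume)


def score_candidate(volume, measured, angles,
                    config: Optional[ReconstructionConfig] = None) -> float:
    """Single-projection R-factor of a candidate orientation:
    ``sum|Pi_angles(volume) - measured| / sum|measured|``."""
    if config is None:
        config = ReconstructionConfig()
    meas = np.asarray(measured, dtype=float)
    den = np.abs(meas).sum()
    if den == 0:
        raise ValueError("measured projection has zero absolute sum; score undefined")
    calc = _project_at(np.asarray(volume, dtype=float), np.asarray(angles, dtype=float), config)
    return float(np.abs(calc - meas).sum() / den)


def _gauge_basis(n: int, order: int) -> np.ndarray:
    """Orthonormal basis of polynomials up to ``order`` over the tilt
    index (the quasi-gauge subspace of theta errors)."""
    t = np.linspace(-1.0, 1.0, n)
    V = np.vander(t, order + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return Q


@dataclass
class RefinementResult:
    """Outcome of the refinement loop."""

    angles: np.ndarray
    volume: np.ndarray
    rounds_run: int
    score_trace: list
    rmse_trace: Optional[list] = None


def refine_angles(stack: ProjectionStack, initial=None,
                  config: Optional[RefinementConfig] = None,
                  true_angles=None, verbose: bool = False):
    """Refine per-projection Euler angles by projection matching.

    Parameters
    ----------
    stack : ProjectionStack
        Measured projections (the stack's own angles are the initial
        guess unless ``initial`` is given).
    initial : array-like, optional
        Starting angles; defaults to the stack's angles.
    config : RefinementConfig, optional
    true_angles : array-like, optional
        If given, a theta-RMSE trace against these is recorded (testing /
        simulation convenience; never used by the search).
    verbose : bool
        Print per-round progress.

    Returns
    -------
    (angles, volume)
        Refined (n, 3) Euler angles and the final reconstruction volume.
        Use :func:`refine_angles_full` for the full result object.
    """
    result = refine_angles_full(stack, initial, config, true_angles, verbose)
    return result.angles, result.volume


def refine_angles_full(stack: ProjectionStack, initial=None,
                       config: Optional[RefinementConfig] = None,
                       true_angles=None, verbose: bool = False) -> RefinementResult:
    if config is None:
        config = RefinementConfig()
    initial_arr = as_angle_array(stack.angles if initial is None else initial).copy()
    n = len(stack)
    offsets = [config.offsets(h) for h in
               (config.delta_phi, config.delta_theta, config.delta_psi)]
    Q = (_gauge_basis(n, config.gauge_order)
         if (config.gauge_order is not None and n > config.gauge_order) else None)

    scfg = config.solver_config
    current = initial_arr.copy()
    score_trace: list[float] = []
    rmse_trace: list[float] = [] if true_angles is not None else None
    results = None
    rounds_run = 0
    for rnd in range(config.rounds):
        results = Resire(stack.with_angles(current), config=scfg).fit()
        vol = results.volume

        picks = current.copy()
        best_scores = np.empty(n)
        for j in range(n):
            meas = stack.images[j]
            best = None
            for dphi in offsets[0]:
                for dth in offsets[1]:
                    for dpsi in offsets[2]:
                        # the grid stays anchored at the initial angles
                        cand = initial_arr[j] + np.array([dphi, dth, dpsi])
                        sc = score_candidate(vol, meas, cand, scfg)
                        dist = float(np.sum((cand - current[j]) ** 2))
                        # tie-break: smaller score, then smaller move from
                        # the current angles, then scan order
                        key = (sc, dist)
                        if best is None or key < best[0]:
                            best = (key, cand)
            picks[j] = best[1]
            best_scores[j] = best[0][0]

        new_angles = picks
        if Q is not None:
            corr = picks[:, 1] - initial_arr[:, 1]
            corr -= Q @ (Q.T @ corr)  # withhold quasi-gauge components
            new_angles = picks.copy()
            new_angles[:, 1] = initial_arr[:, 1] + corr

        rounds_run = rnd + 1
        score_trace.append(float(best_scores.mean()))
        if rmse_trace is not None:
            rmse_trace.append(
                angle_rmse(as_angle_array(true_angles)[:, 1], new_angles[:, 1])
            )
        if verbose:
            msg = f"round {rounds_run}: mean score {score_trace[-1]:.4f}"
            if rmse_trace is not None:
                msg += f", theta RMSE {rmse_trace[-1]:.3f} deg"
            print(msg)
        if np.allclose(new_angles, current, atol=1e-12):
            # converged: the last reconstruction already used these angles
            return RefinementResult(current, results.volume, rounds_run,
                                    score_trace, rmse_trace)
        current = new_angles

    # final reconstruction with the refined angles
    results = Resire(stack.with_angles(current), config=scfg).fit()
    return RefinementResult(current, results.volume, rounds_run, score_trace, rmse_trace)
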
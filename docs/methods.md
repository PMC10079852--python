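# Methods

## Model

The reconstruction target is a real, nonnegative density volume
`O ∈ R^{Nx×Ny×Nz}` observed through `n` linear projections
`b_θ = Π_θ(O) + noise`, one per orientation. The estimate minimizes the sum
of squared errors `ε(O) = ½ Σ_θ ‖Π_θ(O) − b_θ‖²_F` by projected gradient
descent from a zero initial volume. The model assumes the projection
approximation holds (no curvilinear/Ewald-sphere effects, no contrast
transfer function, projections already aligned translationally), that the
orientation of every projection is known up to the small errors the
refinement module addresses, and that noise is independent across pixels.

## Conventions

- Volume axes are `(x, y, z) = (u, v, w)` with `z` the beam axis at zero
  tilt; projection images are `(x, y)`. In MRC files, sections are `z`.
- Euler angles `(φ, θ, ψ)` in degrees, composed extrinsically as
  `R = Z_φ Y_θ X_ψ`. A single-axis tilt series about `y` is `(0, θ, 0)`.
  Positive `θ` rotates the object's `+x` axis toward `+z`. The same
  composition and sign are used by the forward projector, the back
  projector and the refinement, so the convention cancels internally.
- The rotation center along an axis of length `N` is the voxel at index
  `N // 2` (0-based), matching the FFT-centering convention, so the
  Fourier "slice through the origin" is the literal central plane.
- Detector coordinates of a voxel `(u, v, w)` (center-relative) are
  `[x; y] = A [u; v] + w · [R31, R32]` with
  `A = [[R11, R21], [R12, R22]]`; the `w ≠ 0` slice map is the `w = 0`
  map followed by a translation.

## Projectors

**Radon (default).** Each voxel is split into `subdivision³` equal
sub-voxels (default 2 per axis, i.e. 8); each sub-voxel center is mapped to
the detector and deposited with bilinear weights (scatter). Samples falling
off the detector are dropped, keeping the operator linear and modelling a
finite detector. The back projector gathers with the same coordinates,
weights and boundary mask, which makes it the exact adjoint of the forward
operator — verified to 1e-6 relative in the inner-product identity, which
is what the analytic gradient requires. Mass is conserved to 1e-10 relative
whenever the rotated support stays on-detector. For pure `y` tilts the
operator factorizes exactly into a sparse matrix on the `(u, w)` plane and
a 3-tap convolution along `y`; the factorization is cached per angle, which
is what makes 150-iteration runs on 64³ volumes take seconds.

**Fourier slice theorem.** The volume is zero-padded to `OR×` its size
(default OR = 3; beyond ~4 the returns vanish), 3D-FFT'd with centered
conventions, and the central plane spanned by the first two columns of `R`
is extracted by trilinear interpolation of the complex grid; the inverse 2D
FFT of the slice is the projection, whose imaginary residue is checked to
be small and discarded. At `θ = 0` and integer OR the slice lands on grid
points and the projection equals the column sum exactly. The FST projection
is smoother than the Radon one; the two agree to ≲1.5% relative L2 on
band-limited content across the tilt range. When `projector="fst"`, the
back projection (gradient) still uses the Radon-adjoint linear
transformation.

**Interpolation caveat.** The explicit 2D rotation operator built from
bilinear gather weights has entries in [0, 1] and row sums ≤ 1, but its
spectral norm can exceed 1 by a few percent on a finite grid (weight
interference); it is *nearly*, not exactly, non-expansive. The bound that
the step size rests on — `σ_max(S·P_θ) ≤ √N_z` — holds on the explicit
operator matrices across the tested angles, and the monotone-decrease
property at `t = 1` holds empirically throughout.

## Step size, convergence and bookkeeping

The update is `O ← O − t/(n·N_z) · Σ_θ Π_θᵀ(Π_θ(O) − b_θ)` with normalized
step `t` (default 2, guaranteed-monotone regime `t ≤ 1`), followed by the
support mask (if any) and positivity clipping (projected gradient descent;
positivity is on by default, support off). The iteration count is fixed
(default 150); an optional early stop halts when the R-factor changes by
less than `tol` over 10 iterations (off by default). When `N_z < N_x` the
same normalization is kept. A non-finite SSE raises an error naming the
iteration. Per iteration, one forward pass of the constrained iterate
provides both recorded diagnostics — SSE of the objective and R-factor of
the fit — so the trace costs nothing extra; both therefore describe the
post-constraint iterate.

## Metrics

- **R-factor**: `R_F = (1/n) Σ_θ [ Σ|Π_θ(O) − b_θ| / Σ|b_θ| ]`, the mean
  per-projection normalized absolute residual. Undefined (rejected) when a
  measured projection has zero absolute sum.
- **FSC**: per radial shell of width one Fourier voxel from DC to Nyquist,
  `Re(Σ F_a F_b*) / sqrt(Σ|F_a|² Σ|F_b|²)`; empty shells report NaN.
- **Angle RMSE**: root-mean-square residual over a 1D tilt-angle list, or
  over all 3n entries for Euler-triple lists.

## Synthetic data

The phantom emulates a vesicle-like biological object on a 64³ grid: an
off-center ellipsoidal membrane shell, a nested inner vesicle and six
randomly placed interior blobs (seeded), all anti-aliased by 2× supersampled
voxelization and confined to a centered ball of diameter 0.9·N so every
rotation stays on-detector. The off-center shells and blobs make
projections at distinct tilts differ, which the refinement experiment
requires. The default tilt series is 41 projections over ±70° at 3.5°
(single `y` axis); simulation uses the Radon projector at subdivision 4.
Poisson noise scales each image so its brightest pixel has an expectation
of `mean_counts` (default 1000 — a moderately dosed acquisition; the level
is a free parameter), samples counts, and rescales.

What the generator does *not* emulate: detector point-spread, beam damage,
translational misalignment, contrast transfer, or structured background.
Tests passing on this phantom therefore demonstrate the solver and
refinement mechanics under missing-wedge and counting-noise conditions, not
robustness to those unmodelled effects.

## Angular refinement

Per round: reconstruct with the current angles; for every projection,
score a fixed grid of candidate orientations — anchored at the *initial*
angles, half-ranges (φ, θ, ψ) = (0°, 3°, 0°) by default, step 0.5° — by the
single-projection R-factor against the measured image; keep the best
(ties: smallest move from the current angles, then scan order); stop when
nothing changes or after `rounds` (default 5).

Identifiability shapes two design choices. For a single-axis series, a
common offset added to every tilt angle merely rotates the reconstruction:
the data cannot determine it at all, and tilt errors that vary smoothly
with tilt index are close to that gauge (measured: a 0.5° common offset
survives refinement unchanged; a linear ramp retains ~0.8 of its amplitude
per round). Consequently (a) the candidate grid stays anchored at the
initial angles rather than drifting with the current estimate, and (b) the
θ corrections are projected onto the complement of the low-order polynomial
subspace (`gauge_order`, default 2), keeping the quasi-gauge components at
their initially calibrated values instead of letting per-round matching
noise random-walk in directions the data cannot see. The achievable
refined RMSE is therefore bounded below by the quasi-gauge content of the
actual angle errors (for iid Gaussian errors of sd σ over n projections,
roughly σ·√(k+1)/√n for k+1 withheld modes) plus a matching residual of
~0.1–0.2° on the 64³ phantom. For the sd-1.0°, n = 41 replicate this gives
typical refined values of 0.2–0.35°; a draw with, say, a 2.4σ common-mode
offset cannot be refined below that offset by any projection-matching
scheme. A 0.25° grid step is used in the replicate experiment (a 0.5° step
alone contributes 0.14° of quantization RMSE); the 0.5° default favors
speed.

## Problem sizes and tolerances

The bundled tests and the acceptance script run the full study geometry
(64³, 41 projections, 150 iterations) for the convergence, noise and
refinement experiments, and smaller grids (16³–32³) for operator-level
identities: adjointness at 1e-6 relative, gradient vs central difference at
1e-4 relative (h = 1e-4), rotation-matrix orthogonality at 1e-10, mass
conservation at 1e-10 relative. Explicit operator matrices are capped at
64×64 grids (oracle use). Degenerate inputs — empty stacks, zero-mass
measured projections, non-finite volumes, mismatched shapes or counts,
sub-unit oversampling/subdivision — are rejected with explicit errors; an
all-zero tilt series is a valid fixed point (zero volume, zero SSE).

## Known limitations

- No translational (shift) alignment of projections; angles only.
- No regularizers (sparsity, Tikhonov, TV) — the only priors are
  positivity and a support mask.
- The FST path uses trilinear interpolation in reciprocal space; kernels
  with better sidelobe behavior (Kaiser–Bessel) are not implemented.
- Gradient updates use dense volumes; memory is O(OR³·N³) for the FST
  forward pass.
- Multi-axis (φ, ψ ≠ 0) geometries run through the generic scatter/gather
  path, which is correct but considerably slower than the single-axis
  fast path, and the quasi-gauge analysis behind the refinement's
  smoothing filter was validated for single-axis series only.
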
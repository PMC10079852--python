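# resire

Real-space iterative reconstruction (RESIRE) for tomography: least-squares
reconstruction of a 3D density volume from a tilt series of 2D projections,
for electron tomography and related modalities where the data are few, noisy
and missing a wedge of orientations.

## The problem and the method

A tilt series measures projections *b<sub>θ</sub>* of an unknown volume *O*
at tilt angles *θ* (more generally, Euler triples (φ, θ, ψ) about z, y, x).
Limited dose and stage geometry leave the series sparse (tens of
projections) and truncated (|θ| ≲ 70°, the *missing wedge*), so direct
inversion is inaccurate. RESIRE instead minimizes the sum of squared errors

> ε(O) = ½ Σ<sub>θ</sub> ‖Π<sub>θ</sub>(O) − b<sub>θ</sub>‖²<sub>F</sub>

by gradient descent, where Π<sub>θ</sub> is the forward projector — either
the Fourier slice theorem (zero-pad by the oversampling ratio, FFT, extract
the central slice perpendicular to the rotated beam axis) or the Radon
transform (sub-voxel splitting with bilinear deposition). The gradient of
each per-angle term is the back projection Π<sup>T</sup><sub>θ</sub> of the
projection residual, a pure linear transformation: each (u, v) slice of the
gradient samples the residual at [x; y] = A[u; v] + w·[R₃₁, R₃₂] with A the
upper-left transpose block of the rotation matrix. The accumulated gradient
is n·N_z-Lipschitz (n projections, N_z voxels along the beam axis), so the
update

> O ← O − t/(n·N_z) · Σ<sub>θ</sub> Π<sup>T</sup><sub>θ</sub>(Π<sub>θ</sub>(O) − b<sub>θ</sub>)

converges at rate O(1/k) for normalized step t ≤ 1; t = 2 is stable in
practice and is the default. Optional positivity and support constraints are
applied after each update. Fidelity is tracked with the R-factor
R_F = (1/n) Σ<sub>θ</sub> Σ|Π<sub>θ</sub>(O) − b<sub>θ</sub>| / Σ|b<sub>θ</sub>|.

The package also provides brute-force projection-matching refinement of the
per-projection Euler angles (grid search in a ±3° window), Fourier shell
correlation and angle-RMSE metrics, a synthetic vesicle-phantom tilt-series
generator with Poisson noise, MRC2014 and plain-text angle-table I/O, and a
CLI (`resire simulate | reconstruct | refine | metrics`).

## Worked example

```python
import numpy as np
from resire import Resire, NoiseSpec, make_vesicle_phantom, simulate_tilt_series, fsc

phantom = make_vesicle_phantom()                      # 64^3 vesicle model
stack = simulate_tilt_series(phantom, (-70, 70), 3.5, # 41-projection tilt series
                             noise=NoiseSpec(mean_counts=1000, seed=0))

model = Resire(stack, iterations=150)                 # t=2, Radon projector, positivity
res = model.fit()
print(res.summary())
```

```
RESIRE reconstruction results
=============================
projections (n):      41
volume shape:         (64, 64, 64)
projector:            radon (subdivision=2)
iterations run:       150 (of 150)
normalized step t:    2  (step = t/(n*N_z) = 7.6220e-04)
positivity:           True
support mask:         no
final SSE:            4.552083e+03
final R-factor:       3.9221%
wall-clock:           8.8 s
```

The final R-factor says the reconstruction's calculated projections differ
from the measured (Poisson-noisy) ones by ~3.9% in mean normalized absolute
residual. Comparing to the known ground truth:

```python
corr = np.corrcoef(res.volume.ravel(), phantom.ravel())[0, 1]
curve = fsc(phantom, res.volume)
print(f"correlation with truth: {corr:.3f}")   # 0.951
print(f"FSC at 1/4 Nyquist:     {curve.correlation[8]:.3f}")   # 0.950
```

Despite the missing wedge (|θ| ≤ 70°) the real-space correlation with the
truth is 0.95. The same pipeline runs from the shell:

```sh
resire simulate --output stack.mrc --angles-out angles.txt --noise --seed 0
resire reconstruct --projections stack.mrc --angles angles.txt --output recon.mrc
resire metrics rfactor --volume recon.mrc --projections stack.mrc --angles angles.txt
```

Tilt-angle refinement (when the nominal angles carry errors):

```python
from resire import RefinementConfig, refine_angles

refined, volume = refine_angles(stack, config=RefinementConfig(grid_step=0.25, rounds=3))
```

## Layout

- `resire.geometry` — Euler-angle conventions, rotation matrices, the
  per-slice affine projection map
- `resire.projectors` — FST and Radon forward projectors, the exact-adjoint
  back projector, explicit small-grid operator matrices
- `resire.model` — `Resire` / `ResireResults` (the gradient-descent solver)
- `resire.metrics` — R-factor, FSC, angle RMSE
- `resire.refinement` — projection-matching angular refinement
- `resire.phantom` — vesicle phantom, tilt-series simulation, noise and
  angle perturbation
- `resire.io`, `resire.mrc`, `resire.cli` — MRC2014/text I/O, run
  manifests, command-line interface

See `docs/methods.md` for the numerical conventions, parameter defaults and
known limitations.
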
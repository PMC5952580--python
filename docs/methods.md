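# Methods

This note documents the models, numerical choices and limitations of
`tvtomo` in the way the package itself defines them. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not compute.

## Geometry and conventions

A circular trajectory in a right-handed frame: rotation axis `z`,
isocenter at the origin, source at
`(sid·cosθ, sid·sinθ, 0)`, flat detector centered on the
source–isocenter line at distance `sdd` from the source, detector `u`
axis in the rotation plane and `v` axis along `z`. Voxels are sampled
at centers; a grid of `n` voxels of size `s` spans `[-ns/2, ns/2]`.
One fixed convention is shared by the projector, the backprojector and
FDK, which removes the usual half-voxel mismatch bugs between
operators.

Angles are uniform: a full turn excludes the endpoint (step
`span/num_proj`, so 0° and 360° are not duplicated), a partial span
includes both endpoints (step `span/(num_proj−1)`). Fan-beam 2D is a
first-class mode (single detector row, single-slice volume) because
every piece of the mathematics is identical to the 3D case and tests
run much faster at that scale.

The field of view `Ω` is the cylinder through the outermost voxel
centers of the shorter transaxial axis (radius `(min(nx,ny)−1)/2`
voxels). Using voxel centers rather than the full extent makes corner
voxels of small grids fall outside the mask, which is the behaviour
wanted of a support constraint.

The simulator's default geometry uses magnification 2
(`sid = 2·extent`, `sdd = 4·extent`) with a detector covering 1.25×
the volume extent at the isocenter and `DimProj = 1.5·n` pixels
(≈ 0.83 voxel sampling at the isocenter). These are package choices
for a generic small-animal-like bench geometry; nothing downstream
depends on the absolute distances, only on the volume fitting the FOV.

## Operators

**Forward projector** `A`: incremental Siddon traversal — each
detector pixel receives the exact length-weighted line integral of the
volume along the source–pixel ray. Rays that miss the volume
contribute exactly 0.

**Backprojectors**: the default is the classical *voxel-driven*
backprojector (each voxel is projected onto the detector, the detector
value bilinearly interpolated, voxels projecting off the detector
receive nothing). This pair is *unmatched* — the standard production
choice — so a matched-adjoint backprojector (the exact Siddon
transpose) is provided behind a flag for adjoint tests and for a
provably symmetric normal operator. The voxel-driven output is scaled
by the voxel size so that its magnitude agrees with the true adjoint,
whose weights are per-voxel path lengths of order one voxel; without
this factor the effective data weight `μ` would depend on resolution.

**Chunking**: both operators can run under a byte budget. The forward
projector partitions the projection (angle) axis and the voxel-driven
backprojector the volume z axis, mirroring how the input and output
data of each operator grow; the matched adjoint partitions angles and
sums partial volumes (its rays cross every slab). Per-element
arithmetic is identical in chunked and unchunked evaluation, so
results agree to round-off — this invariance is what makes memory
partitioning safe for large volumes.

**Gradients**: forward differences with a replicate (Neumann)
boundary — the last difference along an axis is zero. The adjoint is
the exact algebraic transpose, so the inner-product identity holds to
machine precision and `∇ᵀ∇` is symmetric positive semidefinite. The
TV axes default to `(x, y)` applied per slice, with `z` available by
flag: the split variables of the method are defined in-plane, and an
out-of-plane gradient is a natural but distinct extension.

## Split Bregman loop

Per outer iteration: (1) BiCGStab solve of
`(μAᵀA + λ∇ᵀ∇ + βI) u = μAᵀfᵏ + λΣ∇ᵀ(d−b)`, warm-started from the
previous `u`; (2) projection onto the constraints (`u ≥ 0`, FOV mask);
(3) isotropic shrinkage of `∇u + b` at threshold `α/λ`; (4) Bregman
updates of `fᵏ` and `b`. Both quadratic blocks of the inner operator
are positive semidefinite by construction (the TV block is written as
a composition of the difference operator with its exact adjoint), so
the system is well posed; `β` adds a small identity shift that keeps
it definite even where `AᵀA` and `∇ᵀ∇` share a null direction.

Choices that were genuinely open:

* **Shrinkage coupling**: the threshold is `α/λ` — `α` weights the TV
  term, `λ` the splitting. It is exposed as a parameter pair rather
  than a single knob so either convention can be recovered.
* **Shrinkage form**: isotropic over the enabled axes (soft-threshold
  of the pointwise gradient magnitude); the anisotropic variant
  differs only in coupling and was not needed.
* **Fidelity data**: the inner solve uses the *augmented* data `fᵏ`,
  consistent with the Bregman update that defines it.
* **Constraint enforcement**: projection (clip + mask) after each
  inner solve, the simplest scheme that keeps every iterate feasible.
* **Initialization**: `u⁰ = 0`, `d⁰ = b⁰ = 0`, `f⁰ = f`; an FDK warm
  start is available by flag.
* **Stopping**: fixed cap of 35 outer iterations plus early stop when
  the relative L2 change of `u` falls below 1% (`stop_rel_change =
  0.01`). The noise bound σ² of the constrained formulation has no
  operational role in the unconstrained splitting; its effect is
  absorbed into the iteration count (see limitations).

Default weights `α = 0.003`, `μ = 20`, `λ = 2`, `β = 3` are the
working point of the limited-data CBCT studies this implementation
follows. They are scale-dependent (they weight `AᵀA`, whose norm
grows with object size in mm), so other acquisition scales may need
retuning.

**BiCGStab** is implemented matrix-free with the operator as a
callback (defaults: relative tolerance 1e-4, 30 iterations per outer
iteration, no preconditioner). Breakdown of the recurrences triggers
one restart from the current iterate with a fresh shadow residual;
a second breakdown returns the current iterate flagged unconverged.
The solver tolerates the mildly nonsymmetric operator produced by the
default unmatched pair.

## FDK baseline

Cosine weighting `sdd/√(sdd² + u² + v²)`, row-wise ramp filtering with
the band-limited Ram-Lak kernel sampled at the virtual-detector pitch
(optional Hann apodization), voxel-driven backprojection with the
`(sid/L)²` distance weight, scaled by half the angular step. The
half-step scale corresponds to full-turn redundancy; partial spans use
the same formula without Parker weighting, which is the plain FDK
behaviour whose limited-data artifacts the iterative method is
designed to remove. On a 64² uniform disc with 180 projections the
baseline recovers the interior mean within about 1% (asserted as
RMSE < 10% of the amplitude in the tests).

## Simulator

Phantoms are piecewise constant (Shepp-Logan ellipse table, seeded
random ellipses, seeded discs), fully contained in the FOV, and
reproducible from their seed. Acquisitions are projections by the
package's own forward model; Poisson noise draws transmitted counts
`Poisson(I0·e^{−p})` per pixel and converts back to line integrals,
clamping zero counts to one count. By default simulation and
reconstruction share the projector (the *inverse crime*), which is the
right setting for verifying the algorithm; a `supersample` factor
projects a 2×-refined copy of the phantom to break the exact match
for honest experiment-style comparisons.

What the simulator does **not** emulate: polychromatic spectra, beam
hardening, scatter, detector blur and gain nonuniformity, motion.
Passing tests therefore demonstrate algorithmic correctness and the
expected limited-data behaviour, not performance on physical scans.

## Problem sizes

All shipped experiments run at 64×64 single-slice scale with a
96-pixel detector row (3D paths are exercised on small multi-slice
grids). This scale keeps every experiment to seconds while preserving
the regimes of interest — the limited-span ordering (135° ≥ 150° ≥
360° in RMSE at 45 projections), the RMSE-vs-iteration decay, and the
TV-vs-FDK gap are all clearly resolved at this size. Absolute RMSE
values are intensity-scale-dependent and are not comparable across
phantoms or to other systems.

## Known limitations

* With Poisson noise and the default 35-iteration cap the Bregman
  data update keeps feeding the noise residual back into `fᵏ`, so
  over-iterating fits noise: on noisy data the iteration count (or a
  residual-based stop at the noise level) is the effective
  regularization, consistent with σ² having no explicit role in the
  unconstrained splitting. The shipped SNR experiment is therefore
  run noise-free, where the homogeneous-ROI "noise" is limited-data
  streaking — the artifact the method targets.
* The unmatched default pair makes the inner operator slightly
  nonsymmetric; BiCGStab handles this, but convergence guarantees
  exist only for the matched mode.
* Very small angular spans (≲ 90°) leave a genuinely unrecoverable
  null space; TV shrinks but does not eliminate the resulting
  distortion.
* FDK is implemented without short-scan weighting and is inexact for
  large cone angles.
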
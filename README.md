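# tvtomo

Split Bregman total-variation (TV) reconstruction for **limited-data
fan-beam and cone-beam CT**, with a matrix-free projector pair, an FDK
filtered-backprojection baseline, a synthetic acquisition simulator and
RMSE/SNR evaluation.

## The problem

Standard cone-beam CT acquires hundreds of projections over a full
360° rotation. In intraoperative imaging, respiratory-gated CT and
dose-limited protocols only a few projections are available, sometimes
covering well under 180°. Analytic reconstruction (FDK) of such data
produces severe streaks and edge distortion. Iterative reconstruction
can compensate by adding prior information — here the assumption of
local smoothness, imposed by minimizing the L1 norm of the image
gradient (total variation), which favors piecewise-constant images.

## The algorithm

The reconstruction solves

```
min ‖∇u‖₁   s.t.   ‖Au − f‖₂² ≤ σ²,   u ≥ 0,   u ∈ Ω
```

where `u` is the attenuation volume, `A` the system matrix (ray-driven
projector), `f` the measured line integrals and `Ω` the cylindrical
field of view. Because the TV term is not differentiable, the problem
is handled with the **split Bregman** formulation: surrogate gradient
fields `d ≈ ∇u` are introduced and each outer iteration `k` alternates

1. an L2 subproblem for `u`,
   `(μAᵀA + λ∇ᵀ∇ + βI) u = μAᵀfᵏ + λ∇ᵀ(dᵏ − bᵏ)`,
   solved matrix-free with BiCGStab (`A`/`Aᵀ` are never formed; they
   are a ray-driven Siddon projector and a voxel-driven backprojector,
   applied chunk-wise under a memory budget),
2. closed-form isotropic **shrinkage** of `∇u + b` with threshold
   `α/λ`, giving `d`,
3. **Bregman updates** `f^{k+1} = fᵏ + f − Au` and
   `b^{k+1} = b + ∇u − d`,

with non-negativity and the field of view enforced by projection. The
loop runs a fixed number of outer iterations (default 35) with early
stopping once the relative change of `u` drops below 1%. Default
weights are `α = 0.003`, `μ = 20`, `λ = 2`, `β = 3`.

## Worked example

```python
import tvtomo as tt

# piecewise-constant phantom, 64x64 voxels of 0.5 mm
truth = tt.make_phantom(tt.PhantomSpec(
    kind="random_ellipsoids", dims=(64, 64, 1), voxel_size=0.5, n_objects=4, seed=1))

# 45 projections over a 150-degree span: a limited-data acquisition
geom = tt.default_geometry(truth.grid, num_proj=45, span=150.0)
data = tt.simulate_acquisition(truth, geom)

fdk = tt.reconstruct_fdk(data, truth.grid)
vol, trace = tt.reconstruct_tv(data, truth.grid, tt.ReconParams(), reference=truth)

print(f"FDK RMSE:            {tt.rmse(fdk, truth):.4f}")
print(f"Split Bregman RMSE:  {tt.rmse(vol, truth):.4f}")
print(f"outer iterations:    {len(trace)}")
print(f"RMSE per iteration:  {[round(r, 4) for r in trace.rmse[:5]]} ...")
```

prints

```
FDK RMSE:            0.1365
Split Bregman RMSE:  0.0073
outer iterations:    9
RMSE per iteration:  [0.0326, 0.0232, 0.0176, 0.0141, 0.0117] ...
```

The TV reconstruction cuts the error of the FDK baseline by roughly a
factor of 20 on this 45-projection, 150°-span case; the per-iteration
RMSE trace decays monotonically, and the loop stops on its own once
the solution changes by less than 1% between iterations.

The same pipeline is available from the shell:

```bash
tvtomo simulate --phantom shepp_logan --size 64 --numproj 45 --span 150 \
    --out proj.tif --truth truth.mhd
tvtomo recon-fdk --input proj.tif --out fdk.mhd --size 64
tvtomo recon-tv  --input proj.tif --out tv.mhd  --size 64 \
    --reference truth.mhd --trace trace.csv
tvtomo evaluate  --input tv.mhd --reference truth.mhd \
    --roi 31.5,31.5,6,0 --compare fdk.mhd
```

Each command writes a provenance JSON (options, seed, version) next to
its output and logs the share of wall time spent in projection and
backprojection.

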
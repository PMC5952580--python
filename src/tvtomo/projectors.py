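"""Matrix-free system operators A and A^T for circular-trajectory CT.

The forward model ``A`` is a ray-driven Siddon projector: the value at
each detector pixel is the exact length-weighted line integral of the
volume along the source-pixel ray.  Two backprojectors are provided:

``method="voxel"`` (default)
    Voxel-driven backprojection with bilinear detector interpolation —
    the classical unmatched transpose used in production iterative
    reconstruction.  Its output is scaled by the voxel size so that it
    approximates ``A^T`` (whose weights are per-voxel path lengths of
    order one voxel).

``method="matched"``
    The exact adjoint of the ray-driven projector (Siddon scatter).
    This pair satisfies the adjoint identity to machine precision and
    makes the normal-equation operator symmetric.

Both operators support chunked evaluation under a memory budget: the
forward projector partitions the projection (angle) axis, the
backprojectors partition the volume z axis (angle axis for the matched
adjoint, whose rays span all slices).  Chunked and unchunked evaluation
agree to floating-point round-off.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import _kernels
from .geometry import GeometryError, ScanGeometry, Volume, VolumeGrid

__all__ = [
    "ProjectionStack",
    "ChunkPlan",
    "ChunkBudgetError",
    "plan_chunks",
    "forward_project",
    "back_project",
    "dense_system_matrix",
    "dense_backprojection_matrix",
    "op_timers",
    "reset_op_timers",
]

# cumulative wall time (s) spent in the two heavy operators; the CLI
# reports the projection/backprojection share of each run from these
op_timers = {"forward": 0.0, "back": 0.0}


def reset_op_timers() -> None:
    op_timers["forward"] = 0.0
    op_timers["back"] = 0.0


class ChunkBudgetError(ValueError):
    """Raised when the memory budget cannot hold a single slab."""


@dataclass
class ProjectionStack:
    """Line-integral data for one acquisition.

    ``values`` has shape ``(det_pixels_u, det_pixels_v, num_proj)`` and
    holds dimensionless attenuation path integrals (mm of attenuation
    path).
    """

    geometry: ScanGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        g = self.geometry
        expected = (g.det_pixels_u, g.det_pixels_v, g.num_proj)
        if self.values.shape != expected:
            raise GeometryError(
                f"projection shape {self.values.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("projections contain non-finite values")

    def copy(self) -> "ProjectionStack":
        return ProjectionStack(self.geometry, self.values.copy())

    @classmethod
    def zeros(cls, geometry: ScanGeometry) -> "ProjectionStack":
        shape = (geometry.det_pixels_u, geometry.det_pixels_v, geometry.num_proj)
        return cls(geometry, np.zeros(shape))


@dataclass(frozen=True)
class ChunkPlan:
    """Partition of one array axis into contiguous chunks.

    ``chunk_sizes`` sum to the partitioned dimension; each chunk's
    float64 slab fits within ``memory_budget`` bytes.
    """

    axis: str  # "proj" or "z"
    chunk_sizes: tuple
    memory_budget: int

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.chunk_sizes):
            raise ChunkBudgetError("chunk sizes must be positive")

    def slices(self):
        start = 0
        for size in self.chunk_sizes:
            yield slice(start, start + size)
            start += size


def plan_chunks(shape: tuple, budget: int, axis_index: int = -1, axis: str = "proj") -> ChunkPlan:
    """Fewest contiguous chunks along one axis fitting a byte budget.

    ``shape`` is the full float64 array shape; the axis at
    ``axis_index`` is partitioned.  Deterministic: chunk sizes are as
    equal as possible, larger chunks first.
    """
    shape = tuple(int(s) for s in shape)
    n = shape[axis_index]
    slab_bytes = 8 * int(np.prod(shape)) // n
    if budget < slab_bytes:
        raise ChunkBudgetError(
            f"budget {budget} B below one slab ({slab_bytes} B) for shape {shape}"
        )
    max_slabs = budget // slab_bytes
    n_chunks = -(-n // max_slabs)  # ceil
    base, rem = divmod(n, n_chunks)
    sizes = tuple(base + 1 if i < rem else base for i in range(n_chunks))
    return ChunkPlan(axis=axis, chunk_sizes=sizes, memory_budget=int(budget))


def _pose_arrays(geom: ScanGeometry):
    """Per-angle source position, detector center and detector axes."""
    th = geom.angles_rad
    c, s = np.cos(th), np.sin(th)
    sid, sdd = geom.source_to_isocenter, geom.source_to_detector
    src = np.stack([sid * c, sid * s, np.zeros_like(th)], axis=1)
    w = np.stack([-c, -s, np.zeros_like(th)], axis=1)  # unit source->detector
    detc = src + sdd * w
    eu = np.stack([-s, c, np.zeros_like(th)], axis=1)
    ev = np.stack([np.zeros_like(th), np.zeros_like(th), np.ones_like(th)], axis=1)
    return (
        np.ascontiguousarray(src),
        np.ascontiguousarray(detc),
        np.ascontiguousarray(eu),
        np.ascontiguousarray(ev),
    )


def _resolve_plan(plan, shape, axis_index, axis):
    if plan is None or plan == "auto":
        return ChunkPlan(axis=axis, chunk_sizes=(shape[axis_index],), memory_budget=8 * int(np.prod(shape)))
    if isinstance(plan, int):
        return plan_chunks(shape, plan, axis_index=axis_index, axis=axis)
    if isinstance(plan, ChunkPlan):
        if sum(plan.chunk_sizes) != shape[axis_index]:
            raise ChunkBudgetError(
                f"chunk sizes {plan.chunk_sizes} do not cover dimension {shape[axis_index]}"
            )
        return plan
    raise TypeError(f"plan must be None, 'auto', an int budget or a ChunkPlan, got {plan!r}")


def forward_project(
    vol: Volume,
    geom: ScanGeometry,
    plan: Union[None, str, int, ChunkPlan] = None,
) -> ProjectionStack:
    """Apply the ray-driven projector A to a volume.

    ``plan`` may be ``None``/"auto" (single chunk), an integer byte
    budget, or an explicit :class:`ChunkPlan` over the projection axis.
    The result is independent of the chunking.
    """
    t_start = time.perf_counter()
    g = geom
    out_shape = (g.det_pixels_u, g.det_pixels_v, g.num_proj)
    cplan = _resolve_plan(plan, out_shape, axis_index=2, axis="proj")
    src, detc, eu, ev = _pose_arrays(g)
    out = np.zeros(out_shape)
    values = np.ascontiguousarray(vol.values)
    for sl in cplan.slices():
        chunk = np.zeros((g.det_pixels_u, g.det_pixels_v, sl.stop - sl.start))
        _kernels.forward_kernel(
            values,
            vol.grid.voxel_size,
            src[sl],
            detc[sl],
            eu[sl],
            ev[sl],
            g.det_pitch_u,
            g.det_pitch_v,
            chunk,
        )
        out[:, :, sl] = chunk
    op_timers["forward"] += time.perf_counter() - t_start
    return ProjectionStack(g, out)


def back_project(
    proj: ProjectionStack,
    grid: VolumeGrid,
    plan: Union[None, str, int, ChunkPlan] = None,
    method: str = "voxel",
) -> Volume:
    """Backproject a stack onto a grid.

    ``method="voxel"``: voxel-driven with bilinear detector
    interpolation, scaled by the voxel size (unmatched transpose,
    default).  ``method="matched"``: exact adjoint of the ray-driven
    projector.
    """
    t_start = time.perf_counter()
    g = proj.geometry
    src, detc, eu, ev = _pose_arrays(g)
    values = np.ascontiguousarray(proj.values)
    if method == "matched":
        # rays cross every z-slab, so partition the angle axis instead
        cplan = _resolve_plan(plan, values.shape, axis_index=2, axis="proj")
        out = np.zeros(grid.shape)
        for sl in cplan.slices():
            part = np.zeros(grid.shape)
            _kernels.adjoint_kernel(
                np.ascontiguousarray(values[:, :, sl]),
                grid.voxel_size,
                src[sl],
                detc[sl],
                eu[sl],
                ev[sl],
                g.det_pitch_u,
                g.det_pitch_v,
                part,
            )
            out += part
    elif method == "voxel":
        cplan = _resolve_plan(plan, grid.shape, axis_index=2, axis="z")
        out = np.zeros(grid.shape)
        z0 = 0
        for sl in cplan.slices():
            nzc = sl.stop - sl.start
            slab = np.zeros((grid.nx, grid.ny, nzc))
            _kernels.backproject_kernel(
                values,
                grid.voxel_size,
                grid.nx,
                grid.ny,
                grid.nz,
                z0,
                src,
                detc,
                eu,
                ev,
                g.det_pitch_u,
                g.det_pitch_v,
                g.source_to_isocenter,
                g.source_to_detector,
                False,
                slab,
            )
            out[:, :, sl] = slab * grid.voxel_size
            z0 = sl.stop
    else:
        raise ValueError(f"unknown backprojection method {method!r}")
    op_timers["back"] += time.perf_counter() - t_start
    return Volume(grid, out)


def dense_system_matrix(
    geom: ScanGeometry, grid: VolumeGrid, max_voxels: int = 32768
) -> np.ndarray:
    """Explicit dense A for small problems (test oracle).

    Column ``j`` is the forward projection of a unit impulse at voxel
    ``j`` (C-order flattening of ``(nx, ny, nz)``).  Refuses grids
    larger than ``max_voxels`` voxels.
    """
    if grid.num_voxels > max_voxels:
        raise ValueError(
            f"dense oracle limited to {max_voxels} voxels, grid has {grid.num_voxels}"
        )
    nray = geom.det_pixels_u * geom.det_pixels_v * geom.num_proj
    A = np.zeros((nray, grid.num_voxels))
    impulse = Volume.zeros(grid)
    flat = impulse.values.reshape(-1)
    for j in range(grid.num_voxels):
        flat[j] = 1.0
        A[:, j] = forward_project(impulse, geom).values.reshape(-1)
        flat[j] = 0.0
    return A


def dense_backprojection_matrix(
    geom: ScanGeometry,
    grid: VolumeGrid,
    method: str = "voxel",
    max_voxels: int = 32768,
) -> np.ndarray:
    """Explicit dense backprojection operator (test oracle).

    Column ``i`` is the backprojection of a unit impulse in detector
    bin ``i`` (C-order flattening of ``(nu, nv, na)``).
    """
    if grid.num_voxels > max_voxels:
        raise ValueError(
            f"dense oracle limited to {max_voxels} voxels, grid has {grid.num_voxels}"
        )
    nray = geom.det_pixels_u * geom.det_pixels_v * geom.num_proj
    B = np.zeros((grid.num_voxels, nray))
    stack = ProjectionStack.zeros(geom)
    flat = stack.values.reshape(-1)
    for i in range(nray):
        flat[i] = 1.0
        B[:, i] = back_project(stack, grid, method=method).values.reshape(-1)
        flat[i] = 0.0
    return B
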
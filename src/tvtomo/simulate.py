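"""Synthetic phantoms and limited-data acquisition simulation.

This module stands in for a real cone-beam scanner: piecewise-constant
phantoms (Shepp-Logan, random ellipsoids, discs) are projected with the
package's ray-driven forward model, optionally with Poisson counting
noise on the transmitted intensities.  Limited-data acquisitions are
expressed through the geometry: few projections (NumProj) and/or a
reduced angular span.

By default the simulator uses the same projector as the reconstruction
(the "inverse crime" setting, useful for algorithmic verification); a
``supersample`` factor projects a finer-grained copy of the phantom
instead, which breaks the exact data match and is the honest setting
for experiment-like comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .geometry import ScanGeometry, Volume, VolumeGrid, make_circular_geometry
from .projectors import ProjectionStack, forward_project

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "simulate_acquisition",
    "default_geometry",
    "SHEPP_LOGAN_2D",
]

# Modified Shepp-Logan ellipses: (value added, a, b, x0, y0, angle_deg)
# in the unit square [-1, 1]^2; intensities give a [0, 1] image.
SHEPP_LOGAN_2D = (
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.874, 0.0, -0.0184, 0.0),
    (-0.2, 0.11, 0.31, 0.22, 0.0, -18.0),
    (-0.2, 0.16, 0.41, -0.22, 0.0, 18.0),
    (0.1, 0.21, 0.25, 0.0, 0.35, 0.0),
    (0.1, 0.046, 0.046, 0.0, 0.1, 0.0),
    (0.1, 0.046, 0.046, 0.0, -0.1, 0.0),
    (0.1, 0.046, 0.023, -0.08, -0.605, 0.0),
    (0.1, 0.023, 0.023, 0.0, -0.606, 0.0),
    (0.1, 0.023, 0.046, 0.06, -0.605, 0.0),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Description of a reproducible piecewise-constant phantom.

    ``kind`` is one of ``shepp_logan``, ``random_ellipsoids`` or
    ``discs``; ``dims`` the voxel counts, ``voxel_size`` in mm.  The
    same spec (same seed) always yields an identical volume.
    """

    kind: str
    dims: Tuple[int, int, int]
    voxel_size: float = 0.5
    n_objects: int = 5
    amplitude_range: Tuple[float, float] = (0.2, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("shepp_logan", "random_ellipsoids", "discs"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if any(d <= 0 for d in self.dims):
            raise ValueError("phantom dims must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")


def _unit_coords(grid: VolumeGrid):
    """Voxel-center coordinates scaled to [-1, 1] per transaxial axis."""
    nx, ny = grid.nx, grid.ny
    x = (np.arange(nx) - (nx - 1) / 2.0) / (nx / 2.0)
    y = (np.arange(ny) - (ny - 1) / 2.0) / (ny / 2.0)
    return x[:, None], y[None, :]


def _paint_ellipse(img, x, y, value, a, b, x0, y0, angle_deg, additive):
    th = np.deg2rad(angle_deg)
    ct, st = np.cos(th), np.sin(th)
    xr = (x - x0) * ct + (y - y0) * st
    yr = -(x - x0) * st + (y - y0) * ct
    inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    if additive:
        img[inside] += value
    else:
        img[inside] = value


def make_phantom(spec: PhantomSpec) -> Volume:
    """Rasterize a phantom volume; all structures lie inside the FOV."""
    nx, ny, nz = spec.dims
    grid = VolumeGrid(nx, ny, nz, spec.voxel_size)
    x, y = _unit_coords(grid)
    rng = np.random.default_rng(spec.seed)
    slice_img = np.zeros((nx, ny))

    if spec.kind == "shepp_logan":
        for value, a, b, x0, y0, ang in SHEPP_LOGAN_2D:
            _paint_ellipse(slice_img, x, y, value, a, b, x0, y0, ang, additive=True)
        slice_img = np.clip(slice_img, 0.0, None)
        vol2d = slice_img
    elif spec.kind == "random_ellipsoids":
        lo, hi = spec.amplitude_range
        for _ in range(spec.n_objects):
            a = rng.uniform(0.08, 0.35)
            b = rng.uniform(0.08, 0.35)
            rmax = max(a, b)
            r0 = rng.uniform(0.0, max(0.9 - rmax, 0.0))
            phi = rng.uniform(0.0, 2 * np.pi)
            ang = rng.uniform(0.0, 180.0)
            value = rng.uniform(lo, hi)
            # paint (overwrite) keeps the image piecewise constant with
            # at most n_objects + 1 plateaus
            _paint_ellipse(
                slice_img, x, y, value, a, b, r0 * np.cos(phi), r0 * np.sin(phi), ang, additive=False
            )
        vol2d = slice_img
    else:  # discs
        lo, hi = spec.amplitude_range
        for _ in range(spec.n_objects):
            radius = rng.uniform(0.08, 0.3)
            r0 = rng.uniform(0.0, max(0.9 - radius, 0.0))
            phi = rng.uniform(0.0, 2 * np.pi)
            value = rng.uniform(lo, hi)
            _paint_ellipse(
                slice_img, x, y, value, radius, radius, r0 * np.cos(phi), r0 * np.sin(phi), 0.0, additive=False
            )
        vol2d = slice_img

    values = np.repeat(vol2d[:, :, None], nz, axis=2)
    if nz > 1:
        # taper the end slices so structures stay inside the cone
        z = (np.arange(nz) - (nz - 1) / 2.0) / max(nz / 2.0, 1.0)
        values = values * (np.abs(z)[None, None, :] <= 0.85)
    return Volume(grid, values)


def default_geometry(
    grid: VolumeGrid,
    num_proj: int,
    span: float = 360.0,
    dim_proj: Optional[int] = None,
    mode: Optional[str] = None,
) -> ScanGeometry:
    """Scanner geometry sized to keep ``grid`` inside the field of view.

    Magnification 2 (``sdd = 2 sid``) with ``sid`` twice the transaxial
    extent, and a detector covering 1.25x the extent at the isocenter;
    the default DimProj is ``1.5 * max(nx, ny)`` pixels.
    """
    n = max(grid.nx, grid.ny)
    extent = n * grid.voxel_size
    sid = 2.0 * extent
    sdd = 4.0 * extent
    if dim_proj is None:
        dim_proj = int(np.ceil(1.5 * n))
    pitch = 2.5 * extent / dim_proj
    if mode is None:
        mode = "fanbeam2d" if grid.nz == 1 else "conebeam3d"
    return make_circular_geometry(num_proj, span, dim_proj, pitch, sid, sdd, mode)


def simulate_acquisition(
    vol: Volume,
    geom: ScanGeometry,
    noise: str = "none",
    i0: float = 1e5,
    seed: int = 0,
    supersample: int = 1,
) -> ProjectionStack:
    """Simulate an acquisition of ``vol`` under ``geom``.

    ``noise="poisson"`` draws transmitted counts from
    ``Poisson(i0 * exp(-p))`` per detector pixel and converts back to
    line integrals ``-log(counts / i0)``; zero counts are clamped to
    one count.  ``supersample > 1`` projects a ``supersample``-times
    finer replication of the volume (identical in the continuum) to
    avoid committing the inverse crime.
    """
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")

    if supersample > 1:
        ss = supersample
        fine_values = vol.values
        for ax in range(3):
            if vol.values.shape[ax] > 1:
                fine_values = np.repeat(fine_values, ss, axis=ax)
        fine_grid = VolumeGrid(
            fine_values.shape[0],
            fine_values.shape[1],
            fine_values.shape[2],
            vol.grid.voxel_size / ss,
        )
        # z stays physically centered even when nz == 1 is not refined:
        # a single slice keeps its size, matching a fan-beam midplane
        proj = forward_project(Volume(fine_grid, fine_values), geom)
    else:
        proj = forward_project(vol, geom)

    if noise == "none":
        return proj
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(i0 * np.exp(-proj.values)).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    noisy = -np.log(counts / i0)
    return ProjectionStack(geom, noisy)
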
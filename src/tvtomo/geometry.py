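"""Scan geometry and volume containers for circular-trajectory CT.

Coordinate conventions shared by every operator in the package
(projector, backprojector, filtered backprojection):

* Right-handed world frame, rotation axis along ``z``, isocenter at the
  origin.
* The X-ray source at gantry angle ``theta`` (degrees) sits at
  ``(sid*cos(theta), sid*sin(theta), 0)`` where ``sid`` is the
  source-to-isocenter distance.  The flat detector is centered on the
  source-isocenter line at distance ``sdd`` (source-to-detector) behind
  the isocenter.
* The detector ``u`` axis lies in the rotation plane with direction
  ``(-sin(theta), cos(theta), 0)``; the ``v`` axis is parallel to ``z``.
  Pixel (0, 0) is the most negative corner; pixel centers are offset by
  integer multiples of the pitch from the detector center.
* A volume of ``n`` voxels of size ``s`` along an axis spans the
  interval ``[-n*s/2, n*s/2]``; voxel values are samples at voxel
  centers.

Fan-beam 2D acquisitions are represented as cone-beam geometries with a
single detector row (``det_pixels_v == 1``) and single-slice volumes
(``nz == 1``); all operators treat this case uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "GeometryError",
    "ScanGeometry",
    "VolumeGrid",
    "Volume",
    "make_circular_geometry",
    "fov_mask",
]

_MODES = ("fanbeam2d", "conebeam3d")


class GeometryError(ValueError):
    """Raised for inconsistent or non-physical scan geometries."""


@dataclass(frozen=True)
class ScanGeometry:
    """Circular-trajectory cone-beam (or fan-beam) scan description.

    Parameters
    ----------
    source_to_isocenter, source_to_detector:
        Distances in mm; ``source_to_detector > source_to_isocenter > 0``.
    det_pixels_u, det_pixels_v:
        Detector grid size; fan-beam mode uses a single row
        (``det_pixels_v == 1``).
    det_pitch_u, det_pitch_v:
        Detector pixel pitch in mm.
    angles:
        Gantry angles in degrees, strictly increasing.
    mode:
        ``"fanbeam2d"`` or ``"conebeam3d"``.
    """

    source_to_isocenter: float
    source_to_detector: float
    det_pixels_u: int
    det_pixels_v: int
    det_pitch_u: float
    det_pitch_v: float
    angles: tuple = field(default=())
    mode: str = "conebeam3d"

    def __post_init__(self) -> None:
        if not (self.source_to_detector > self.source_to_isocenter > 0):
            raise GeometryError(
                "require source_to_detector > source_to_isocenter > 0, got "
                f"sdd={self.source_to_detector}, sid={self.source_to_isocenter}"
            )
        if self.det_pitch_u <= 0 or self.det_pitch_v <= 0:
            raise GeometryError("detector pitch must be positive")
        if self.det_pixels_u < 1 or self.det_pixels_v < 1:
            raise GeometryError("detector pixel counts must be >= 1")
        if self.mode not in _MODES:
            raise GeometryError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode == "fanbeam2d" and self.det_pixels_v != 1:
            raise GeometryError("fanbeam2d mode requires det_pixels_v == 1")
        ang = np.asarray(self.angles, dtype=float)
        if ang.size == 0:
            raise GeometryError("at least one projection angle is required")
        if ang.size > 1 and not np.all(np.diff(ang) > 0):
            raise GeometryError("angles must be strictly increasing")
        object.__setattr__(self, "angles", tuple(float(a) for a in ang))

    @property
    def num_proj(self) -> int:
        """Number of projections (NumProj)."""
        return len(self.angles)

    @property
    def dim_proj(self) -> int:
        """Detector size along u (DimProj)."""
        return self.det_pixels_u

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(np.asarray(self.angles, dtype=float))

    def to_dict(self) -> dict:
        return {
            "source_to_isocenter": self.source_to_isocenter,
            "source_to_detector": self.source_to_detector,
            "det_pixels_u": self.det_pixels_u,
            "det_pixels_v": self.det_pixels_v,
            "det_pitch_u": self.det_pitch_u,
            "det_pitch_v": self.det_pitch_v,
            "angles": list(self.angles),
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScanGeometry":
        try:
            return cls(
                source_to_isocenter=float(d["source_to_isocenter"]),
                source_to_detector=float(d["source_to_detector"]),
                det_pixels_u=int(d["det_pixels_u"]),
                det_pixels_v=int(d["det_pixels_v"]),
                det_pitch_u=float(d["det_pitch_u"]),
                det_pitch_v=float(d["det_pitch_v"]),
                angles=tuple(float(a) for a in d["angles"]),
                mode=str(d.get("mode", "conebeam3d")),
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise GeometryError(f"missing geometry key: {exc}") from exc


@dataclass(frozen=True)
class VolumeGrid:
    """Isotropic voxel grid centered on the isocenter.

    ``nx, ny, nz`` voxel counts and the voxel edge length in mm.  The
    physical extent along each axis is ``n * voxel_size``, centered on
    the origin.
    """

    nx: int
    ny: int
    nz: int
    voxel_size: float

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.nz < 1:
            raise GeometryError("grid dimensions must be >= 1")
        if self.voxel_size <= 0:
            raise GeometryError("voxel_size must be positive")

    @property
    def shape(self) -> tuple:
        return (self.nx, self.ny, self.nz)

    @property
    def num_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    def axis_coords(self, axis: str) -> np.ndarray:
        """Physical coordinates of voxel centers along ``axis`` (mm)."""
        n = {"x": self.nx, "y": self.ny, "z": self.nz}[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size

    def to_dict(self) -> dict:
        return {"nx": self.nx, "ny": self.ny, "nz": self.nz, "voxel_size": self.voxel_size}

    @classmethod
    def from_dict(cls, d: Mapping) -> "VolumeGrid":
        return cls(int(d["nx"]), int(d["ny"]), int(d["nz"]), float(d["voxel_size"]))


@dataclass
class Volume:
    """A voxel grid of linear attenuation values (1/mm).

    ``values`` is a float64 array of shape ``(nx, ny, nz)`` indexed
    ``[ix, iy, iz]``.
    """

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise GeometryError(
                f"volume shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("volume contains non-finite values")

    def copy(self) -> "Volume":
        return Volume(self.grid, self.values.copy())

    @classmethod
    def zeros(cls, grid: VolumeGrid) -> "Volume":
        return cls(grid, np.zeros(grid.shape))


def make_circular_geometry(
    num_proj: int,
    span: float,
    dim_proj: int,
    pitch: float,
    sid: float,
    sdd: float,
    mode: str = "conebeam3d",
) -> ScanGeometry:
    """Build a uniformly sampled circular trajectory.

    ``num_proj`` angles uniformly distributed in an angular span of
    ``span`` degrees.  For a full turn (``span == 360``) the endpoint is
    excluded (step ``span/num_proj``), so e.g. 4 projections give
    0/90/180/270 degrees.  For a partial span both endpoints are
    included (step ``span/(num_proj-1)``); a single projection sits at 0.
    The detector is a square ``dim_proj x dim_proj`` grid (one row in
    fan-beam mode) of pixels with edge ``pitch`` mm.
    """
    if num_proj < 1:
        raise GeometryError("num_proj must be >= 1")
    if not (0 < span <= 360):
        raise GeometryError("span must lie in (0, 360] degrees")
    if dim_proj < 2:
        raise GeometryError("dim_proj must be >= 2")
    if pitch <= 0 or sid <= 0 or sdd <= 0:
        raise GeometryError("pitch and distances must be positive")

    if span == 360.0:
        step = span / num_proj
        angles = tuple(i * step for i in range(num_proj))
    elif num_proj == 1:
        angles = (0.0,)
    else:
        step = span / (num_proj - 1)
        angles = tuple(i * step for i in range(num_proj))

    det_v = 1 if mode == "fanbeam2d" else dim_proj
    return ScanGeometry(
        source_to_isocenter=sid,
        source_to_detector=sdd,
        det_pixels_u=dim_proj,
        det_pixels_v=det_v,
        det_pitch_u=pitch,
        det_pitch_v=pitch,
        angles=angles,
        mode=mode,
    )


def fov_mask(grid: VolumeGrid) -> Volume:
    """Binary field-of-view mask: the inscribed cylinder around ``z``.

    A voxel belongs to the FOV when its center lies within the circle
    through the outermost voxel centers of the shorter transaxial axis,
    i.e. radius ``(min(nx, ny) - 1)/2`` voxels.  Reapplying the mask is
    idempotent.
    """
    x = grid.axis_coords("x")[:, None]
    y = grid.axis_coords("y")[None, :]
    radius = (min(grid.nx, grid.ny) - 1) / 2.0 * grid.voxel_size
    disc = (x * x + y * y) <= radius * radius + 1e-12
    values = np.repeat(disc[:, :, None], grid.nz, axis=2).astype(np.float64)
    return Volume(grid, values)
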
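"""Readers and writers for volumes, projection stacks and configs.

Volumes: MetaImage (``.mhd``/``.mha``, via SimpleITK) and NIfTI
(``.nii``/``.nii.gz``, via nibabel), with the voxel size carried in the
image spacing.  Projection stacks: multi-page TIFF (page = projection,
via tifffile) or HDF5, each with the scan geometry stored alongside
(a ``<stem>.geometry.yaml`` sidecar for TIFF, attributes/datasets for
HDF5).  Round-trips are lossless for float64 data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import h5py
import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile
import yaml

from .geometry import ScanGeometry, Volume, VolumeGrid
from .projectors import ProjectionStack

__all__ = [
    "FormatError",
    "read_volume",
    "write_volume",
    "read_projections",
    "write_projections",
    "read_geometry",
    "write_geometry",
    "write_provenance",
]


class FormatError(ValueError):
    """Raised for unsupported formats or malformed files."""


_VOLUME_EXTS = (".mhd", ".mha", ".nii", ".nii.gz")


def _ext(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def write_volume(vol: Volume, path: Union[str, Path]) -> None:
    """Write a volume as MetaImage or NIfTI (chosen by extension)."""
    path = Path(path)
    ext = _ext(path)
    vs = vol.grid.voxel_size
    if ext in (".mhd", ".mha"):
        # SimpleITK uses (z, y, x) array order
        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))
        img.SetSpacing((vs, vs, vs))
        sitk.WriteImage(img, str(path))
    elif ext in (".nii", ".nii.gz"):
        affine = np.diag([vs, vs, vs, 1.0])
        nib.save(nib.Nifti1Image(vol.values, affine), str(path))
    else:
        raise FormatError(f"unsupported volume format {ext!r} (use {_VOLUME_EXTS})")


def read_volume(path: Union[str, Path]) -> Volume:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    ext = _ext(path)
    if ext in (".mhd", ".mha"):
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:
            raise FormatError(f"cannot parse MetaImage {path}: {exc}") from exc
        values = sitk.GetArrayFromImage(img).T.astype(np.float64)
        spacing = img.GetSpacing()
    elif ext in (".nii", ".nii.gz"):
        try:
            img = nib.load(str(path))
        except Exception as exc:
            raise FormatError(f"cannot parse NIfTI {path}: {exc}") from exc
        values = np.asarray(img.dataobj, dtype=np.float64)
        spacing = img.header.get_zooms()[:3]
    else:
        raise FormatError(f"unsupported volume format {ext!r} (use {_VOLUME_EXTS})")
    if values.ndim == 2:
        values = values[:, :, None]
    if abs(spacing[0] - spacing[1]) > 1e-9 or abs(spacing[0] - spacing[2]) > 1e-9:
        raise FormatError(f"anisotropic spacing {spacing} is not supported")
    grid = VolumeGrid(values.shape[0], values.shape[1], values.shape[2], float(spacing[0]))
    return Volume(grid, values)


def write_geometry(geom: ScanGeometry, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(geom.to_dict(), fh, sort_keys=True)


def read_geometry(path: Union[str, Path]) -> ScanGeometry:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"geometry file not found: {path}")
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise FormatError(f"geometry file {path} does not contain a mapping")
    return ScanGeometry.from_dict(d)


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".tif", ".tiff"):
        if name.lower().endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".geometry.yaml")
    return path.with_suffix(".geometry.yaml")


def write_projections(stack: ProjectionStack, path: Union[str, Path]) -> None:
    """Write a projection stack as multi-page TIFF or HDF5.

    TIFF pages are per-projection ``(v, u)`` images; the geometry goes
    to a ``<stem>.geometry.yaml`` sidecar.  HDF5 files carry datasets
    ``projections`` (u, v, angle) and ``angles`` plus the remaining
    geometry fields as attributes.
    """
    path = Path(path)
    ext = _ext(path)
    if ext in (".tif", ".tiff"):
        # pages along the angle axis
        pages = np.ascontiguousarray(np.moveaxis(stack.values, 2, 0))
        tifffile.imwrite(str(path), pages)
        write_geometry(stack.geometry, _sidecar(path))
    elif ext in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("projections", data=stack.values)
            fh.create_dataset("angles", data=np.asarray(stack.geometry.angles))
            meta = stack.geometry.to_dict()
            meta.pop("angles")
            for key, val in meta.items():
                fh.attrs[key] = val
    else:
        raise FormatError(f"unsupported projection format {ext!r} (use .tif/.tiff/.h5/.hdf5)")


def read_projections(path: Union[str, Path]) -> ProjectionStack:
    """Read a projection stack written by :func:`write_projections`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"projection file not found: {path}")
    ext = _ext(path)
    if ext in (".tif", ".tiff"):
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise FormatError(
                f"missing geometry sidecar {sidecar} for projection stack {path}"
            )
        geom = read_geometry(sidecar)
        pages = tifffile.imread(str(path))
        if pages.ndim == 2:
            pages = pages[None, :, :]
        values = np.moveaxis(pages, 0, 2).astype(np.float64)
        if values.shape[2] != geom.num_proj:
            raise FormatError(
                f"{path}: {values.shape[2]} pages but geometry lists {geom.num_proj} angles"
            )
        return ProjectionStack(geom, values)
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            if "projections" not in fh:
                raise FormatError(f"{path}: missing 'projections' dataset")
            values = np.asarray(fh["projections"], dtype=np.float64)
            angles = [float(a) for a in np.asarray(fh["angles"])]
            meta = {key: fh.attrs[key] for key in fh.attrs}
        meta["angles"] = angles
        geom = ScanGeometry.from_dict(meta)
        if values.shape[2] != geom.num_proj:
            raise FormatError(
                f"{path}: {values.shape[2]} projections but geometry lists {geom.num_proj} angles"
            )
        return ProjectionStack(geom, values)
    raise FormatError(f"unsupported projection format {ext!r} (use .tif/.tiff/.h5/.hdf5)")


def write_provenance(path: Union[str, Path], config: dict) -> None:
    """Record the run configuration (options, seed, version) as JSON."""
    from . import __version__

    record = {"tvtomo_version": __version__, **config}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
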
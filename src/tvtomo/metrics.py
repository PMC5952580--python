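"""Image-quality metrics: RMSE against a reference and ROI-based SNR.

RMSE is computed on the raw attenuation scale (no normalization).  SNR
is ``20*log10(mean/std)`` over a circular region of interest placed in
a homogeneous area; the improvement of an iterative reconstruction
over filtered backprojection is the difference of the two SNRs in dB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import Volume

__all__ = ["ROISpec", "rmse", "snr_db", "snr_difference_db"]


@dataclass(frozen=True)
class ROISpec:
    """Circular ROI on one transaxial slice (voxel units).

    ``center`` is ``(cx, cy)`` in voxel indices, ``radius`` in voxels,
    ``slice_index`` the z slice.
    """

    center: tuple
    radius: float
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")

    def mask(self, shape) -> np.ndarray:
        nx, ny, nz = shape
        cx, cy = self.center
        if not (0 <= self.slice_index < nz):
            raise ValueError(f"slice {self.slice_index} outside volume with nz={nz}")
        if (
            cx - self.radius < -0.5
            or cy - self.radius < -0.5
            or cx + self.radius > nx - 0.5
            or cy + self.radius > ny - 0.5
        ):
            raise ValueError("ROI extends outside the grid")
        x = np.arange(nx)[:, None] - cx
        y = np.arange(ny)[None, :] - cy
        return (x * x + y * y) <= self.radius**2


def rmse(u: Volume, ref: Volume, mask: Optional[Volume] = None) -> float:
    """Root mean square error between two volumes, optionally masked."""
    if u.values.shape != ref.values.shape:
        raise ValueError(
            f"shape mismatch: {u.values.shape} vs {ref.values.shape}"
        )
    diff = u.values - ref.values
    if mask is not None:
        sel = mask.values > 0
        if not np.any(sel):
            raise ValueError("mask selects no voxels")
        diff = diff[sel]
    return float(np.sqrt(np.mean(diff**2)))


def snr_db(vol: Volume, roi: ROISpec) -> float:
    """SNR in dB over a circular ROI: ``20*log10(mean/std)``.

    A perfectly homogeneous ROI (zero standard deviation) has infinite
    SNR; ``inf`` is returned with a warning rather than raising.
    """
    sel = roi.mask(vol.values.shape)
    vals = vol.values[:, :, roi.slice_index][sel]
    mean = float(np.mean(vals))
    std = float(np.std(vals))
    if std == 0.0:
        warnings.warn("ROI has zero standard deviation; SNR is infinite", RuntimeWarning)
        return np.inf
    return 20.0 * np.log10(abs(mean) / std)


def snr_difference_db(iterative: Volume, fdk: Volume, roi: ROISpec) -> float:
    """SNR improvement of an iterative reconstruction over FDK (dB)."""
    return snr_db(iterative, roi) - snr_db(fdk, roi)
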
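"""Forward-difference gradients and their exact discrete adjoints.

The gradient along an axis is the forward difference
``g[i] = u[i+1] - u[i]`` with a replicate (Neumann) boundary: the last
difference along the axis is zero.  ``gradient_adjoint`` is the exact
algebraic transpose of that linear map, so the inner-product identity
``<grad u, v> == <u, grad_adjoint v>`` holds to round-off; the composed
operator ``grad_adjoint(grad(.))`` is the (negated-boundary) discrete
Laplacian, symmetric positive semidefinite with constant images in its
null space.
"""

from __future__ import annotations

import numpy as np

from .geometry import Volume

__all__ = ["AXES", "gradient", "gradient_adjoint", "gradient_array", "gradient_adjoint_array"]

AXES = {"x": 0, "y": 1, "z": 2}


class AxisError(ValueError):
    """Raised when a difference axis is disabled or unknown."""


def _check_axis(shape, axis: str) -> int:
    if axis not in AXES:
        raise AxisError(f"unknown axis {axis!r}; expected one of {sorted(AXES)}")
    ax = AXES[axis]
    if shape[ax] == 1:
        raise AxisError(f"axis {axis!r} is disabled on a grid with size 1 along it")
    return ax


def gradient_array(values: np.ndarray, axis: str) -> np.ndarray:
    """Forward difference of a raw (nx, ny, nz) array along ``axis``."""
    ax = _check_axis(values.shape, axis)
    out = np.empty_like(values)
    src = [slice(None)] * values.ndim
    dst = [slice(None)] * values.ndim
    src[ax] = slice(1, None)
    dst[ax] = slice(0, -1)
    out[tuple(dst)] = values[tuple(src)] - values[tuple(dst)]
    last = [slice(None)] * values.ndim
    last[ax] = slice(-1, None)
    out[tuple(last)] = 0.0
    return out


def gradient_adjoint_array(values: np.ndarray, axis: str) -> np.ndarray:
    """Exact transpose of :func:`gradient_array` along ``axis``.

    ``(D^T v)[j] = v[j-1] - v[j]`` in the interior, ``-v[0]`` at the
    first index and ``v[n-2]`` at the last (the zeroed final difference
    contributes nothing).
    """
    ax = _check_axis(values.shape, axis)
    n = values.shape[ax]
    out = np.zeros_like(values)

    def sl(a, b):
        idx = [slice(None)] * values.ndim
        idx[ax] = slice(a, b)
        return tuple(idx)

    out[sl(0, n - 1)] = -values[sl(0, n - 1)]
    out[sl(1, n)] += values[sl(0, n - 1)]
    return out


def gradient(vol: Volume, axis: str) -> Volume:
    """Forward-difference gradient of a volume along ``axis``."""
    return Volume(vol.grid, gradient_array(vol.values, axis))


def gradient_adjoint(vol: Volume, axis: str) -> Volume:
    """Exact adjoint of :func:`gradient` along ``axis``."""
    return Volume(vol.grid, gradient_adjoint_array(vol.values, axis))
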
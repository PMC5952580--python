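"""Matrix-free BiCGStab solver.

The biconjugate gradient stabilized method solves ``K x = rhs`` for a
general (possibly nonsymmetric) linear operator given only as a
callback ``apply_op(x) -> K x``.  This is the inner solver of the split
Bregman loop, where the operator chains a forward projection, a
backprojection and difference operators and is never formed as a
matrix.

Breakdown (a vanishing denominator in the recurrences) is handled by a
single restart from the current iterate with a fresh shadow residual;
a second breakdown terminates with ``converged=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = ["KrylovReport", "bicgstab"]


@dataclass
class KrylovReport:
    """Outcome of one BiCGStab solve."""

    iterations: int
    final_relative_residual: float
    converged: bool


def _norm(x: np.ndarray) -> float:
    return float(np.linalg.norm(x.ravel()))


def _dot(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.dot(a.ravel(), b.ravel()))


def bicgstab(
    apply_op: Callable[[np.ndarray], np.ndarray],
    rhs: np.ndarray,
    x0: Optional[np.ndarray] = None,
    tol: float = 1e-4,
    max_iter: int = 30,
):
    """Solve ``apply_op(x) = rhs`` to relative residual ``tol``.

    Returns ``(x, KrylovReport)``.  Deterministic for given inputs; the
    operator is touched only through the callback.  Raises
    ``FloatingPointError`` if the operator returns non-finite values.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    rhs = np.asarray(rhs, dtype=np.float64)
    rhs_norm = _norm(rhs)
    if rhs_norm == 0.0:
        return np.zeros_like(rhs), KrylovReport(0, 0.0, True)

    def op(v):
        out = np.asarray(apply_op(v), dtype=np.float64)
        if out.shape != rhs.shape:
            raise ValueError("operator is not shape-preserving")
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("operator returned non-finite values")
        return out

    x = np.zeros_like(rhs) if x0 is None else np.array(x0, dtype=np.float64, copy=True)
    r = rhs - op(x)
    r_hat = r.copy()
    rho = alpha = omega = 1.0
    v = np.zeros_like(rhs)
    p = np.zeros_like(rhs)
    restarted = False
    breakdown_tol = 1e-30

    iterations = 0
    rel_res = _norm(r) / rhs_norm
    while iterations < max_iter and rel_res > tol:
        rho_new = _dot(r_hat, r)
        if abs(rho_new) < breakdown_tol:
            if restarted:
                break
            # restart from the current iterate with a new shadow residual
            restarted = True
            r = rhs - op(x)
            r_hat = r.copy()
            rho = alpha = omega = 1.0
            v[:] = 0.0
            p[:] = 0.0
            rel_res = _norm(r) / rhs_norm
            continue
        beta = (rho_new / rho) * (alpha / omega)
        rho = rho_new
        p = r + beta * (p - omega * v)
        v = op(p)
        denom = _dot(r_hat, v)
        if abs(denom) < breakdown_tol:
            if restarted:
                break
            restarted = True
            r = rhs - op(x)
            r_hat = r.copy()
            rho = alpha = omega = 1.0
            v[:] = 0.0
            p[:] = 0.0
            rel_res = _norm(r) / rhs_norm
            continue
        alpha = rho / denom
        s = r - alpha * v
        iterations += 1
        if _norm(s) / rhs_norm <= tol:
            x = x + alpha * p
            rel_res = _norm(rhs - op(x)) / rhs_norm
            break
        t = op(s)
        tt = _dot(t, t)
        if tt < breakdown_tol:
            x = x + alpha * p
            rel_res = _norm(rhs - op(x)) / rhs_norm
            if rel_res <= tol:
                break
            if restarted:
                break
            restarted = True
            r = rhs - op(x)
            r_hat = r.copy()
            rho = alpha = omega = 1.0
            v[:] = 0.0
            p[:] = 0.0
            continue
        omega = _dot(t, s) / tt
        x = x + alpha * p + omega * s
        r = s - omega * t
        rel_res = _norm(r) / rhs_norm

    converged = rel_res <= tol
    return x, KrylovReport(iterations, rel_res, converged)
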
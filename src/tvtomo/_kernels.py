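"""Numba kernels for ray-driven projection and voxel-driven backprojection.

All kernels operate in the world frame of :mod:`tvtomo.geometry` on
float64 arrays.  The ray tracer is an incremental Siddon traversal:
each ray accumulates voxel values weighted by the exact intersection
length of the ray with each voxel (mm), so projections are radiological
path integrals.  The same traversal, run in scatter mode, yields the
exact adjoint of the projector.
"""

import numpy as np
from numba import njit

_EPS = 1e-12
_BIG = 1e30


@njit(cache=False)
def _traverse(vol_in, vol_out, scatter, val, vs, sx, sy, sz, dx, dy, dz):
    """Trace one ray from (sx,sy,sz) along (dx,dy,dz) for t in [0, 1].

    Gather mode (``scatter`` false): return the line integral of
    ``vol_in``.  Scatter mode: add ``val * segment_length`` into
    ``vol_out`` for every traversed voxel and return 0.
    """
    nx, ny, nz = vol_out.shape
    xmin = -0.5 * nx * vs
    ymin = -0.5 * ny * vs
    zmin = -0.5 * nz * vs

    t0 = 0.0
    t1 = 1.0
    # clip against the three slabs of the volume bounding box
    if dx > _EPS or dx < -_EPS:
        ta = (xmin - sx) / dx
        tb = (-xmin - sx) / dx
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    elif sx <= xmin or sx >= -xmin:
        return 0.0
    if dy > _EPS or dy < -_EPS:
        ta = (ymin - sy) / dy
        tb = (-ymin - sy) / dy
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    elif sy <= ymin or sy >= -ymin:
        return 0.0
    if dz > _EPS or dz < -_EPS:
        ta = (zmin - sz) / dz
        tb = (-zmin - sz) / dz
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    elif sz <= zmin or sz >= -zmin:
        return 0.0
    if t1 - t0 <= _EPS:
        return 0.0

    dnorm = np.sqrt(dx * dx + dy * dy + dz * dz)

    # entry voxel
    px = sx + t0 * dx
    py = sy + t0 * dy
    pz = sz + t0 * dz
    ix = int(np.floor((px - xmin) / vs))
    iy = int(np.floor((py - ymin) / vs))
    iz = int(np.floor((pz - zmin) / vs))
    if ix < 0:
        ix = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    if iy > ny - 1:
        iy = ny - 1
    if iz < 0:
        iz = 0
    if iz > nz - 1:
        iz = nz - 1

    # parametric distance to the next voxel boundary along each axis
    if dx > _EPS:
        stepx = 1
        tnx = (xmin + (ix + 1) * vs - sx) / dx
        dtx = vs / dx
    elif dx < -_EPS:
        stepx = -1
        tnx = (xmin + ix * vs - sx) / dx
        dtx = -vs / dx
    else:
        stepx = 0
        tnx = _BIG
        dtx = _BIG
    if dy > _EPS:
        stepy = 1
        tny = (ymin + (iy + 1) * vs - sy) / dy
        dty = vs / dy
    elif dy < -_EPS:
        stepy = -1
        tny = (ymin + iy * vs - sy) / dy
        dty = -vs / dy
    else:
        stepy = 0
        tny = _BIG
        dty = _BIG
    if dz > _EPS:
        stepz = 1
        tnz = (zmin + (iz + 1) * vs - sz) / dz
        dtz = vs / dz
    elif dz < -_EPS:
        stepz = -1
        tnz = (zmin + iz * vs - sz) / dz
        dtz = -vs / dz
    else:
        stepz = 0
        tnz = _BIG
        dtz = _BIG

    total = 0.0
    t = t0
    while t < t1 - _EPS:
        if tnx <= tny and tnx <= tnz:
            tn = tnx
            axis = 0
        elif tny <= tnz:
            tn = tny
            axis = 1
        else:
            tn = tnz
            axis = 2
        if tn > t1:
            tn = t1
        seg = (tn - t) * dnorm
        if seg > 0.0:
            if scatter:
                vol_out[ix, iy, iz] += val * seg
            else:
                total += vol_in[ix, iy, iz] * seg
        t = tn
        if axis == 0:
            ix += stepx
            tnx += dtx
            if ix < 0 or ix > nx - 1:
                break
        elif axis == 1:
            iy += stepy
            tny += dty
            if iy < 0 or iy > ny - 1:
                break
        else:
            iz += stepz
            tnz += dtz
            if iz < 0 or iz > nz - 1:
                break
    return total


@njit(cache=False)
def forward_kernel(vol, vs, src, detc, eu, ev, pitch_u, pitch_v, out):
    """Ray-driven projection of ``vol`` into ``out`` (nu, nv, na)."""
    nu, nv, na = out.shape
    for a in range(na):
        sx = src[a, 0]
        sy = src[a, 1]
        sz = src[a, 2]
        for iu in range(nu):
            uo = (iu - 0.5 * (nu - 1)) * pitch_u
            for iv in range(nv):
                vo = (iv - 0.5 * (nv - 1)) * pitch_v
                px = detc[a, 0] + uo * eu[a, 0] + vo * ev[a, 0]
                py = detc[a, 1] + uo * eu[a, 1] + vo * ev[a, 1]
                pz = detc[a, 2] + uo * eu[a, 2] + vo * ev[a, 2]
                out[iu, iv, a] = _traverse(
                    vol, vol, False, 0.0, vs, sx, sy, sz, px - sx, py - sy, pz - sz
                )


@njit(cache=False)
def adjoint_kernel(proj, vs, src, detc, eu, ev, pitch_u, pitch_v, out_vol):
    """Exact transpose of :func:`forward_kernel` (Siddon scatter)."""
    nu, nv, na = proj.shape
    for a in range(na):
        sx = src[a, 0]
        sy = src[a, 1]
        sz = src[a, 2]
        for iu in range(nu):
            uo = (iu - 0.5 * (nu - 1)) * pitch_u
            for iv in range(nv):
                val = proj[iu, iv, a]
                if val == 0.0:
                    continue
                vo = (iv - 0.5 * (nv - 1)) * pitch_v
                px = detc[a, 0] + uo * eu[a, 0] + vo * ev[a, 0]
                py = detc[a, 1] + uo * eu[a, 1] + vo * ev[a, 1]
                pz = detc[a, 2] + uo * eu[a, 2] + vo * ev[a, 2]
                _traverse(
                    out_vol, out_vol, True, val, vs, sx, sy, sz, px - sx, py - sy, pz - sz
                )


@njit(cache=False)
def backproject_kernel(
    proj,
    vs,
    nx,
    ny,
    nz_full,
    z0,
    src,
    detc,
    eu,
    ev,
    pitch_u,
    pitch_v,
    sid,
    sdd,
    fdk_weight,
    out,
):
    """Voxel-driven backprojection into the z-slab ``out``.

    Each voxel center is projected through the source onto the detector
    plane and the detector value is bilinearly interpolated.  Voxels
    projecting outside the detector receive no contribution.  With
    ``fdk_weight`` the contribution is scaled by ``(sid/L)**2`` where
    ``L`` is the voxel distance from the source along the central-ray
    direction (the FDK distance weight); otherwise the weight is 1.

    ``out`` has shape ``(nx, ny, nzc)`` and covers global z indices
    ``z0 .. z0+nzc-1`` of an ``nz_full``-slice volume.
    """
    nu, nv, na = proj.shape
    nzc = out.shape[2]
    xmin = -0.5 * nx * vs
    ymin = -0.5 * ny * vs
    zmin = -0.5 * nz_full * vs
    for a in range(na):
        sx = src[a, 0]
        sy = src[a, 1]
        sz = src[a, 2]
        wx = (detc[a, 0] - sx) / sdd
        wy = (detc[a, 1] - sy) / sdd
        wz = (detc[a, 2] - sz) / sdd
        for ix in range(nx):
            x = xmin + (ix + 0.5) * vs
            for iy in range(ny):
                y = ymin + (iy + 0.5) * vs
                for izc in range(nzc):
                    z = zmin + (z0 + izc + 0.5) * vs
                    rx = x - sx
                    ry = y - sy
                    rz = z - sz
                    L = rx * wx + ry * wy + rz * wz
                    if L < 1e-9:
                        continue
                    sc = sdd / L
                    hx = sx + sc * rx - detc[a, 0]
                    hy = sy + sc * ry - detc[a, 1]
                    hz = sz + sc * rz - detc[a, 2]
                    u = hx * eu[a, 0] + hy * eu[a, 1] + hz * eu[a, 2]
                    v = hx * ev[a, 0] + hy * ev[a, 1] + hz * ev[a, 2]
                    puf = u / pitch_u + 0.5 * (nu - 1)
                    pvf = v / pitch_v + 0.5 * (nv - 1)
                    if nu == 1:
                        if puf < -0.5 or puf > 0.5:
                            continue
                        iu0 = 0
                        iu1 = 0
                        fu = 0.0
                    else:
                        if puf < 0.0 or puf > nu - 1:
                            continue
                        iu0 = int(puf)
                        if iu0 > nu - 2:
                            iu0 = nu - 2
                        iu1 = iu0 + 1
                        fu = puf - iu0
                    if nv == 1:
                        if pvf < -0.5 or pvf > 0.5:
                            continue
                        iv0 = 0
                        iv1 = 0
                        fv = 0.0
                    else:
                        if pvf < 0.0 or pvf > nv - 1:
                            continue
                        iv0 = int(pvf)
                        if iv0 > nv - 2:
                            iv0 = nv - 2
                        iv1 = iv0 + 1
                        fv = pvf - iv0
                    val = (
                        (1.0 - fu) * (1.0 - fv) * proj[iu0, iv0, a]
                        + fu * (1.0 - fv) * proj[iu1, iv0, a]
                        + (1.0 - fu) * fv * proj[iu0, iv1, a]
                        + fu * fv * proj[iu1, iv1, a]
                    )
                    if fdk_weight:
                        w = sid / L
                        out[ix, iy, izc] += w * w * val
                    else:
                        out[ix, iy, izc] += val
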
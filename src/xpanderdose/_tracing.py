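"""Numba-compiled Siddon-style voxel traversal.

Exact line integrals of density along a segment through a regular grid:
each voxel the segment crosses contributes density x intersection length.
Two integrals are accumulated per ray: the radiological path (mm . g/cm^3)
and the geometric path length spent in "material" (density >= threshold),
which defines the depth below the phantom surface.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INF = 1e300


@njit(cache=True)
def trace_segment(vals, bx, by, bz, sx, sy, sz, x0, y0, z0, x1, y1, z1, thresh):
    """Integrate along the segment p0 -> p1.

    ``b*`` is the lower grid boundary (voxel (0,0,0) lower corner), ``s*``
    the spacing.  Returns (radiological mm.g/cm^3, geometric mm in
    material).  Segments outside the grid contribute zero.
    """
    nx, ny, nz = vals.shape
    dx = x1 - x0
    dy = y1 - y0
    dz = z1 - z0
    length = np.sqrt(dx * dx + dy * dy + dz * dz)
    if length < 1e-12:
        return 0.0, 0.0
    # clip parameter range to the grid box (slab test, unrolled per axis)
    t0 = 0.0
    t1 = 1.0
    lo = bx
    hi = bx + nx * sx
    if abs(dx) < 1e-300:
        if x0 < lo or x0 > hi:
            return 0.0, 0.0
    else:
        ta = (lo - x0) / dx
        tb = (hi - x0) / dx
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    lo = by
    hi = by + ny * sy
    if abs(dy) < 1e-300:
        if y0 < lo or y0 > hi:
            return 0.0, 0.0
    else:
        ta = (lo - y0) / dy
        tb = (hi - y0) / dy
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    lo = bz
    hi = bz + nz * sz
    if abs(dz) < 1e-300:
        if z0 < lo or z0 > hi:
            return 0.0, 0.0
    else:
        ta = (lo - z0) / dz
        tb = (hi - z0) / dz
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    if t0 >= t1:
        return 0.0, 0.0
    eps = 1e-12
    tmid = t0 + eps
    ix = int(np.floor((x0 + tmid * dx - bx) / sx))
    iy = int(np.floor((y0 + tmid * dy - by) / sy))
    iz = int(np.floor((z0 + tmid * dz - bz) / sz))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1
    # parametric distance to the next boundary crossing per axis
    if abs(dx) > 1e-300:
        step_x = 1 if dx > 0 else -1
        t_delta_x = sx / abs(dx)
        nb = bx + (ix + (1 if dx > 0 else 0)) * sx
        t_max_x = (nb - x0) / dx
    else:
        step_x = 0
        t_delta_x = _INF
        t_max_x = _INF
    if abs(dy) > 1e-300:
        step_y = 1 if dy > 0 else -1
        t_delta_y = sy / abs(dy)
        nb = by + (iy + (1 if dy > 0 else 0)) * sy
        t_max_y = (nb - y0) / dy
    else:
        step_y = 0
        t_delta_y = _INF
        t_max_y = _INF
    if abs(dz) > 1e-300:
        step_z = 1 if dz > 0 else -1
        t_delta_z = sz / abs(dz)
        nb = bz + (iz + (1 if dz > 0 else 0)) * sz
        t_max_z = (nb - z0) / dz
    else:
        step_z = 0
        t_delta_z = _INF
        t_max_z = _INF

    rad = 0.0
    geom = 0.0
    t = t0
    while t < t1 - 1e-14:
        t_next = t_max_x
        if t_max_y < t_next:
            t_next = t_max_y
        if t_max_z < t_next:
            t_next = t_max_z
        if t_next > t1:
            t_next = t1
        seg = (t_next - t) * length
        if seg > 0 and 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            rho = vals[ix, iy, iz]
            rad += rho * seg
            if rho >= thresh:
                geom += seg
        t = t_next
        if t_next == t_max_x:
            ix += step_x
            t_max_x += t_delta_x
        elif t_next == t_max_y:
            iy += step_y
            t_max_y += t_delta_y
        elif t_next == t_max_z:
            iz += step_z
            t_max_z += t_delta_z
    return rad, geom


@njit(cache=True)
def trace_grid(vals, origin, spacing, source, thresh):
    """Trace from one source point to every voxel center.

    Returns (rad, geom) arrays with the same shape as ``vals``; see
    :func:`trace_segment` for units.
    """
    nx, ny, nz = vals.shape
    bx = origin[0] - spacing[0] / 2.0
    by = origin[1] - spacing[1] / 2.0
    bz = origin[2] - spacing[2] / 2.0
    rad = np.empty((nx, ny, nz))
    geom = np.empty((nx, ny, nz))
    for ix in range(nx):
        px = origin[0] + ix * spacing[0]
        for iy in range(ny):
            py = origin[1] + iy * spacing[1]
            for iz in range(nz):
                pz = origin[2] + iz * spacing[2]
                r, g = trace_segment(
                    vals,
                    bx,
                    by,
                    bz,
                    spacing[0],
                    spacing[1],
                    spacing[2],
                    source[0],
                    source[1],
                    source[2],
                    px,
                    py,
                    pz,
                    thresh,
                )
                rad[ix, iy, iz] = r
                geom[ix, iy, iz] = g
    return rad, geom
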
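"""Numba kernel for cone-beam line integrals.

Uniform-step ray marching with trilinear interpolation.  Each detector
pixel's value is the integral of attenuation along the ray from the point
source through the pixel centre, approximated by midpoint sampling at a
fixed step after clipping the ray to the volume bounding box.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def raymarch(vol, src, pts, step, origin, spacing, out):  # pragma: no cover - jitted
    nx, ny, nz = vol.shape
    sx, sy, sz = src[0], src[1], src[2]
    ox, oy, oz = origin[0], origin[1], origin[2]
    dx, dy, dz = spacing[0], spacing[1], spacing[2]
    npix = pts.shape[0]
    for i in range(npix):
        rx = pts[i, 0] - sx
        ry = pts[i, 1] - sy
        rz = pts[i, 2] - sz
        length = np.sqrt(rx * rx + ry * ry + rz * rz)
        rx /= length
        ry /= length
        rz /= length
        tmin = 0.0
        tmax = length
        # slab clipping against the voxel-edge bounding box
        lo = ox - 0.5 * dx
        hi = ox + (nx - 0.5) * dx
        if rx != 0.0:
            t1 = (lo - sx) / rx
            t2 = (hi - sx) / rx
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
        elif sx < lo or sx > hi:
            tmax = -1.0
        lo = oy - 0.5 * dy
        hi = oy + (ny - 0.5) * dy
        if ry != 0.0:
            t1 = (lo - sy) / ry
            t2 = (hi - sy) / ry
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
        elif sy < lo or sy > hi:
            tmax = -1.0
        lo = oz - 0.5 * dz
        hi = oz + (nz - 0.5) * dz
        if rz != 0.0:
            t1 = (lo - sz) / rz
            t2 = (hi - sz) / rz
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
        elif sz < lo or sz > hi:
            tmax = -1.0
        if tmax <= tmin:
            out[i] = 0.0
            continue
        # midpoint rule with a shortened final step so the quadrature
        # covers [tmin, tmax] exactly
        n = int(np.ceil((tmax - tmin) / step))
        acc = 0.0
        for k in range(n):
            t0 = tmin + k * step
            dt = tmax - t0
            if dt > step:
                dt = step
            if dt <= 0.0:
                break
            t = t0 + 0.5 * dt
            x = (sx + t * rx - ox) / dx
            y = (sy + t * ry - oy) / dy
            z = (sz + t * rz - oz) / dz
            x0 = int(np.floor(x))
            y0 = int(np.floor(y))
            z0 = int(np.floor(z))
            fx = x - x0
            fy = y - y0
            fz = z - z0
            v = 0.0
            for a in range(2):
                xa = x0 + a
                if xa < 0 or xa >= nx:
                    continue
                wa = fx if a == 1 else 1.0 - fx
                for b in range(2):
                    yb = y0 + b
                    if yb < 0 or yb >= ny:
                        continue
                    wb = fy if b == 1 else 1.0 - fy
                    for c in range(2):
                        zc = z0 + c
                        if zc < 0 or zc >= nz:
                            continue
                        wc = fz if c == 1 else 1.0 - fz
                        v += wa * wb * wc * vol[xa, yb, zc]
            acc += v * dt
        out[i] = acc
    return out
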
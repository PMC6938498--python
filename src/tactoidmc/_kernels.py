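"""Numba kernels for the hard-particle Monte Carlo core.

Everything here operates on plain float64/int64 arrays so the hot loop
(segment-segment distances, cell-list bookkeeping, the sweep driver) compiles
to machine code.  The Python-facing API lives in :mod:`tactoidmc.mc`.

Cell list: uniform grid over the lens bounding box with cell edge >= L + d,
one cell in z (the container is shallow).  Any two rods whose capsules overlap
have center distance < L + d, so checking the 3x3 neighborhood of the cell of
a trial center is exhaustive.
"""

from __future__ import annotations

import numpy as np
from numba import njit

CELL_CAP = 160  # max rods per cell; generous for eta <= 0.5 with edge ~ L + d


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def segment_dist2(ax, ay, az, bx, by, bz, cx, cy, cz, dx, dy, dz):
    """Squared minimum distance between segments A=(a,b) and B=(c,d).

    Closest-point parametrization clamped to [0,1] on both segments
    (Ericson, Real-Time Collision Detection, 5.1.9).
    """
    d1x = bx - ax
    d1y = by - ay
    d1z = bz - az
    d2x = dx - cx
    d2y = dy - cy
    d2z = dz - cz
    rx = ax - cx
    ry = ay - cy
    rz = az - cz
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    EPS = 1e-14
    if a <= EPS and e <= EPS:
        return rx * rx + ry * ry + rz * rz
    if a <= EPS:
        s = 0.0
        t = min(1.0, max(0.0, f / e))
    else:
        c_ = d1x * rx + d1y * ry + d1z * rz
        if e <= EPS:
            t = 0.0
            s = min(1.0, max(0.0, -c_ / a))
        else:
            b = d1x * d2x + d1y * d2y + d1z * d2z
            denom = a * e - b * b
            if denom > EPS:
                s = min(1.0, max(0.0, (b * f - c_ * e) / denom))
            else:
                s = 0.0
            t = b * s + f
            if t < 0.0:
                t = 0.0
                s = min(1.0, max(0.0, -c_ / a))
            elif t > e:
                t = 1.0
                s = min(1.0, max(0.0, (b - c_) / a))
            else:
                t = t / e
    px = ax + d1x * s - (cx + d2x * t)
    py = ay + d1y * s - (cy + d2y * t)
    pz = az + d1z * s - (cz + d2z * t)
    return px * px + py * py + pz * pz


@njit(cache=True)
def endpoints_inside(x, y, z, ux, uy, uz, halfL, margin, R, c, h):
    """Hard-wall test: both capsule endpoints in the margin-eroded lens."""
    r_eff = R - margin
    r2 = r_eff * r_eff
    for sgn in (-1.0, 1.0):
        ex = x + sgn * halfL * ux
        ey = y + sgn * halfL * uy
        ez = z + sgn * halfL * uz
        if ez < margin or ez > h - margin:
            return False
        if (ex - c) ** 2 + ey * ey > r2:
            return False
        if (ex + c) ** 2 + ey * ey > r2:
            return False
    return True


@njit(cache=True)
def cell_index(x, y, x0, y0, inv_cell, nx, ny):
    ix = int((x - x0) * inv_cell)
    iy = int((y - y0) * inv_cell)
    if ix < 0:
        ix = 0
    elif ix >= nx:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy >= ny:
        iy = ny - 1
    return iy * nx + ix


@njit(cache=True)
def build_cells(pos, x0, y0, inv_cell, nx, ny, cell_count, cell_items, cell_of):
    cell_count[:] = 0
    n = pos.shape[0]
    for i in range(n):
        k = cell_index(pos[i, 0], pos[i, 1], x0, y0, inv_cell, nx, ny)
        cell_of[i] = k
        m = cell_count[k]
        if m >= CELL_CAP:
            return False
        cell_items[k, m] = i
        cell_count[k] = m + 1
    return True


@njit(cache=True, fastmath=True)
def overlaps_any(i, x, y, z, ux, uy, uz, halfL, d2min, pos, ort, halfLs,
                 x0, y0, inv_cell, nx, ny, cell_count, cell_items):
    """True if the trial capsule of rod i at (x,y,z,u) overlaps any other rod."""
    ax = x - halfL * ux
    ay = y - halfL * uy
    az = z - halfL * uz
    bx = x + halfL * ux
    by = y + halfL * uy
    bz = z + halfL * uz
    ix = int((x - x0) * inv_cell)
    iy = int((y - y0) * inv_cell)
    for jy in range(max(0, iy - 1), min(ny, iy + 2)):
        for jx in range(max(0, ix - 1), min(nx, ix + 2)):
            k = jy * nx + jx
            for m in range(cell_count[k]):
                j = cell_items[k, m]
                if j == i:
                    continue
                hj = halfLs[j]
                cx = pos[j, 0] - hj * ort[j, 0]
                cy = pos[j, 1] - hj * ort[j, 1]
                cz = pos[j, 2] - hj * ort[j, 2]
                dxx = pos[j, 0] + hj * ort[j, 0]
                dyy = pos[j, 1] + hj * ort[j, 1]
                dzz = pos[j, 2] + hj * ort[j, 2]
                if segment_dist2(ax, ay, az, bx, by, bz,
                                 cx, cy, cz, dxx, dyy, dzz) < d2min:
                    return True
    return False


@njit(cache=True)
def any_overlap_allpairs(pos, ort, halfLs, d):
    """All-pairs O(N^2) overlap oracle; returns (i, j) of first overlap or (-1, -1)."""
    n = pos.shape[0]
    d2 = d * d
    for i in range(n):
        hi = halfLs[i]
        ax = pos[i, 0] - hi * ort[i, 0]
        ay = pos[i, 1] - hi * ort[i, 1]
        az = pos[i, 2] - hi * ort[i, 2]
        bx = pos[i, 0] + hi * ort[i, 0]
        by = pos[i, 1] + hi * ort[i, 1]
        bz = pos[i, 2] + hi * ort[i, 2]
        for j in range(i + 1, n):
            hj = halfLs[j]
            cx = pos[j, 0] - hj * ort[j, 0]
            cy = pos[j, 1] - hj * ort[j, 1]
            cz = pos[j, 2] - hj * ort[j, 2]
            dx = pos[j, 0] + hj * ort[j, 0]
            dy = pos[j, 1] + hj * ort[j, 1]
            dz = pos[j, 2] + hj * ort[j, 2]
            if segment_dist2(ax, ay, az, bx, by, bz, cx, cy, cz, dx, dy, dz) < d2:
                return i, j
    return -1, -1


@njit(cache=True, fastmath=True)
def run_sweeps_kernel(pos, ort, halfLs, d, R, c, h,
                      x0, y0, inv_cell, nx, ny,
                      cell_count, cell_items, cell_of,
                      dr_max, dtheta_max, nsweeps):
    """Run ``nsweeps`` sweeps of N single-particle trial moves in place.

    One sweep = N attempts on uniformly random particles; each attempt
    proposes a joint translation (uniform in a cube of half-edge dr_max) and
    rotation (uniform angle in [0, dtheta_max] about a uniform random axis).
    Returns the number of accepted moves.
    """
    n = pos.shape[0]
    d2min = d * d
    margin = 0.5 * d
    accepted = 0
    for _s in range(nsweeps):
        for _t in range(n):
            i = np.random.randint(0, n)
            x = pos[i, 0] + (2.0 * np.random.random() - 1.0) * dr_max
            y = pos[i, 1] + (2.0 * np.random.random() - 1.0) * dr_max
            z = pos[i, 2] + (2.0 * np.random.random() - 1.0) * dr_max
            # random rotation axis (gaussian 3-vector, normalized)
            kx = np.random.normal()
            ky = np.random.normal()
            kz = np.random.normal()
            kn = np.sqrt(kx * kx + ky * ky + kz * kz)
            if kn < 1e-12:
                kx, ky, kz = 0.0, 0.0, 1.0
            else:
                kx /= kn
                ky /= kn
                kz /= kn
            ang = np.random.random() * dtheta_max
            ca = np.cos(ang)
            sa = np.sin(ang)
            ux0 = ort[i, 0]
            uy0 = ort[i, 1]
            uz0 = ort[i, 2]
            kdotu = kx * ux0 + ky * uy0 + kz * uz0
            ux = ux0 * ca + (ky * uz0 - kz * uy0) * sa + kx * kdotu * (1.0 - ca)
            uy = uy0 * ca + (kz * ux0 - kx * uz0) * sa + ky * kdotu * (1.0 - ca)
            uz = uz0 * ca + (kx * uy0 - ky * ux0) * sa + kz * kdotu * (1.0 - ca)
            un = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= un
            uy /= un
            uz /= un
            halfL = halfLs[i]
            if not endpoints_inside(x, y, z, ux, uy, uz, halfL, margin, R, c, h):
                continue
            if overlaps_any(i, x, y, z, ux, uy, uz, halfL, d2min, pos, ort,
                            halfLs, x0, y0, inv_cell, nx, ny,
                            cell_count, cell_items):
                continue
            # accept: update coordinates and cell membership
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            ort[i, 0] = ux
            ort[i, 1] = uy
            ort[i, 2] = uz
            knew = cell_index(x, y, x0, y0, inv_cell, nx, ny)
            kold = cell_of[i]
            if knew != kold:
                m = cell_count[kold]
                for q in range(m):
                    if cell_items[kold, q] == i:
                        cell_items[kold, q] = cell_items[kold, m - 1]
                        break
                cell_count[kold] = m - 1
                mm = cell_count[knew]
                cell_items[knew, mm] = i
                cell_count[knew] = mm + 1
                cell_of[i] = knew
            accepted += 1
    return accepted


@njit(cache=True)
def all_inside_walls(pos, ort, halfLs, d, R, c, h):
    """Index of first rod violating the hard wall, or -1."""
    margin = 0.5 * d
    for i in range(pos.shape[0]):
        if not endpoints_inside(pos[i, 0], pos[i, 1], pos[i, 2],
                                ort[i, 0], ort[i, 1], ort[i, 2],
                                halfLs[i], margin, R, c, h):
            return i
    return -1


@njit(cache=True, fastmath=True)
def accumulate_local_Q(pos, ort, halfL, x_edges, y_edges, M, occ):
    """Accumulate length-weighted orientation tensors on the cell grid.

    For each rod the centerline is clipped to every overlapped (x, y) cell
    column (cells span the full height); M[ix, iy] += l * (3/2 u u^T - I/2),
    occ[ix, iy] += l.  Clipping is exact parametric slab intersection.
    """
    n = pos.shape[0]
    nx = x_edges.shape[0] - 1
    ny = y_edges.shape[0] - 1
    for i in range(n):
        ux = ort[i, 0]
        uy = ort[i, 1]
        uz = ort[i, 2]
        p0x = pos[i, 0] - halfL * ux
        p0y = pos[i, 1] - halfL * uy
        p1x = pos[i, 0] + halfL * ux
        p1y = pos[i, 1] + halfL * uy
        seg_len = 2.0 * halfL
        dx = p1x - p0x
        dy = p1y - p0y
        xmin = min(p0x, p1x)
        xmax = max(p0x, p1x)
        ymin = min(p0y, p1y)
        ymax = max(p0y, p1y)
        ix0 = np.searchsorted(x_edges, xmin) - 1
        ix1 = np.searchsorted(x_edges, xmax)
        iy0 = np.searchsorted(y_edges, ymin) - 1
        iy1 = np.searchsorted(y_edges, ymax)
        if ix0 < 0:
            ix0 = 0
        if iy0 < 0:
            iy0 = 0
        if ix1 > nx - 1:
            ix1 = nx - 1
        if iy1 > ny - 1:
            iy1 = ny - 1
        for ix in range(ix0, ix1 + 1):
            for iy in range(iy0, iy1 + 1):
                t0 = 0.0
                t1 = 1.0
                ok = True
                # degenerate axes use half-open cells so a segment lying
                # exactly on a shared edge is counted once, not twice
                if abs(dx) < 1e-300:
                    if p0x < x_edges[ix] or p0x >= x_edges[ix + 1]:
                        ok = False
                else:
                    ta = (x_edges[ix] - p0x) / dx
                    tb = (x_edges[ix + 1] - p0x) / dx
                    if ta > tb:
                        ta, tb = tb, ta
                    if ta > t0:
                        t0 = ta
                    if tb < t1:
                        t1 = tb
                    if t0 >= t1:
                        ok = False
                if ok:
                    if abs(dy) < 1e-300:
                        if p0y < y_edges[iy] or p0y >= y_edges[iy + 1]:
                            ok = False
                    else:
                        ta = (y_edges[iy] - p0y) / dy
                        tb = (y_edges[iy + 1] - p0y) / dy
                        if ta > tb:
                            ta, tb = tb, ta
                        if ta > t0:
                            t0 = ta
                        if tb < t1:
                            t1 = tb
                        if t0 >= t1:
                            ok = False
                if not ok:
                    continue
                l = seg_len * (t1 - t0)
                if l <= 0.0:
                    continue
                occ[ix, iy] += l
                M[ix, iy, 0, 0] += l * (1.5 * ux * ux - 0.5)
                M[ix, iy, 0, 1] += l * 1.5 * ux * uy
                M[ix, iy, 0, 2] += l * 1.5 * ux * uz
                M[ix, iy, 1, 1] += l * (1.5 * uy * uy - 0.5)
                M[ix, iy, 1, 2] += l * 1.5 * uy * uz
                M[ix, iy, 2, 2] += l * (1.5 * uz * uz - 0.5)
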
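"""Compiled inner loops for Keys cubic interpolation.

The registration and operator-assembly hot paths evaluate millions of
4x4x4 Catmull-Rom stencils; the numba kernels below run them as tight
loops without temporaries.  Pure-numpy fallbacks keep the package
functional if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _cr4(t, w):
    t2 = t * t
    t3 = t2 * t
    w[0] = 0.5 * (-t3 + 2.0 * t2 - t)
    w[1] = 0.5 * (3.0 * t3 - 5.0 * t2 + 2.0)
    w[2] = 0.5 * (-3.0 * t3 + 4.0 * t2 + t)
    w[3] = 0.5 * (t3 - t2)


@njit(cache=False)
def _cr4d(t, d):
    t2 = t * t
    d[0] = 0.5 * (-3.0 * t2 + 4.0 * t - 1.0)
    d[1] = 0.5 * (9.0 * t2 - 10.0 * t)
    d[2] = 0.5 * (-9.0 * t2 + 8.0 * t + 1.0)
    d[3] = 0.5 * (3.0 * t2 - 2.0 * t)


@njit(cache=False)
def nb_interp(vol, coords, out):
    nx, ny, nz = vol.shape
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    for p in range(coords.shape[0]):
        bx = int(np.floor(coords[p, 0]))
        by = int(np.floor(coords[p, 1]))
        bz = int(np.floor(coords[p, 2]))
        _cr4(coords[p, 0] - bx, wx)
        _cr4(coords[p, 1] - by, wy)
        _cr4(coords[p, 2] - bz, wz)
        acc = 0.0
        for i in range(4):
            ix = bx + i - 1
            if ix < 0 or ix >= nx:
                continue
            for j in range(4):
                iy = by + j - 1
                if iy < 0 or iy >= ny:
                    continue
                wxy = wx[i] * wy[j]
                for k in range(4):
                    iz = bz + k - 1
                    if iz < 0 or iz >= nz:
                        continue
                    acc += wxy * wz[k] * vol[ix, iy, iz]
        out[p] = acc


@njit(cache=False)
def nb_interp_grad(vol, coords, out, grad):
    nx, ny, nz = vol.shape
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    dx = np.empty(4)
    dy = np.empty(4)
    dz = np.empty(4)
    for p in range(coords.shape[0]):
        bx = int(np.floor(coords[p, 0]))
        by = int(np.floor(coords[p, 1]))
        bz = int(np.floor(coords[p, 2]))
        tx = coords[p, 0] - bx
        ty = coords[p, 1] - by
        tz = coords[p, 2] - bz
        _cr4(tx, wx)
        _cr4(ty, wy)
        _cr4(tz, wz)
        _cr4d(tx, dx)
        _cr4d(ty, dy)
        _cr4d(tz, dz)
        acc = 0.0
        g0 = 0.0
        g1 = 0.0
        g2 = 0.0
        for i in range(4):
            ix = bx + i - 1
            if ix < 0 or ix >= nx:
                continue
            for j in range(4):
                iy = by + j - 1
                if iy < 0 or iy >= ny:
                    continue
                for k in range(4):
                    iz = bz + k - 1
                    if iz < 0 or iz >= nz:
                        continue
                    v = vol[ix, iy, iz]
                    acc += wx[i] * wy[j] * wz[k] * v
                    g0 += dx[i] * wy[j] * wz[k] * v
                    g1 += wx[i] * dy[j] * wz[k] * v
                    g2 += wx[i] * wy[j] * dz[k] * v
        out[p] = acc
        grad[p, 0] = g0
        grad[p, 1] = g1
        grad[p, 2] = g2


@njit(cache=False)
def nb_stencil(coords, nx, ny, nz, cols, w):
    """Flattened 64-neighbor column indices and weights per point."""
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    for p in range(coords.shape[0]):
        bx = int(np.floor(coords[p, 0]))
        by = int(np.floor(coords[p, 1]))
        bz = int(np.floor(coords[p, 2]))
        _cr4(coords[p, 0] - bx, wx)
        _cr4(coords[p, 1] - by, wy)
        _cr4(coords[p, 2] - bz, wz)
        q = 0
        for i in range(4):
            ix = bx + i - 1
            okx = 0 <= ix < nx
            for j in range(4):
                iy = by + j - 1
                oky = 0 <= iy < ny
                wxy = wx[i] * wy[j]
                for k in range(4):
                    iz = bz + k - 1
                    if okx and oky and 0 <= iz < nz:
                        cols[p, q] = (ix * ny + iy) * nz + iz
                        w[p, q] = wxy * wz[k]
                    else:
                        cols[p, q] = 0
                        w[p, q] = 0.0
                    q += 1
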
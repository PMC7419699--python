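"""Numba kernels for subset correlation.

The hot loop of local DVC is the zero-normalized cross-correlation (ZNCC)
of a cubic reference subset against every integer offset of a cubic search
window, repeated at every grid node. Windows that are fully finite take a
fast path using 3D integral images (window sums in O(1)); windows touching
NaN-masked voxels fall back to an explicitly masked accumulation over
jointly-finite voxels.

All loops are serial over nodes, so results are bit-identical regardless
of scheduling.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# node status codes (shared with dvc module)
STATUS_OK = 0
STATUS_LOW_CC = 1
STATUS_INSUFFICIENT_VALID = 2
STATUS_OUT_OF_BOUNDS = 3


@njit(cache=True)
def _integral(arr):
    """Inclusive 3D summed-area table padded with a leading zero plane."""
    nz, ny, nx = arr.shape
    out = np.zeros((nz + 1, ny + 1, nx + 1), dtype=np.float64)
    for k in range(nz):
        for j in range(ny):
            row = 0.0
            for i in range(nx):
                row += arr[k, j, i]
                out[k + 1, j + 1, i + 1] = out[k, j + 1, i + 1] + out[k + 1, j, i + 1] - out[k, j, i + 1] + row
    return out


@njit(cache=True, inline="always")
def _box_sum(P, z0, y0, x0, z1, y1, x1):
    """Sum of arr[z0:z1, y0:y1, x0:x1] from the integral table P."""
    return (
        P[z1, y1, x1] - P[z0, y1, x1] - P[z1, y0, x1] + P[z0, y0, x1]
        - P[z1, y1, x0] + P[z0, y1, x0] + P[z1, y0, x0] - P[z0, y0, x0]
    )


@njit(cache=True)
def _zncc_masked(ref, deff, cz, cy, cx, oz, oy, ox, half, min_valid_fraction):
    """Masked ZNCC between the ref subset at (cz,cy,cx) and the deformed
    subset at the integer offset (oz,oy,ox). NaN if the jointly-finite
    fraction is below threshold or either window has zero variance."""
    n = 0
    sr = 0.0
    sd = 0.0
    srr = 0.0
    sdd = 0.0
    srd = 0.0
    for dz in range(-half, half + 1):
        for dy in range(-half, half + 1):
            for dx in range(-half, half + 1):
                r = ref[cz + dz, cy + dy, cx + dx]
                d = deff[cz + oz + dz, cy + oy + dy, cx + ox + dx]
                if r == r and d == d:
                    n += 1
                    sr += r
                    sd += d
                    srr += r * r
                    sdd += d * d
                    srd += r * d
    side = 2 * half + 1
    total = side * side * side
    if n < min_valid_fraction * total or n < 2:
        return np.nan
    vr = srr - sr * sr / n
    vd = sdd - sd * sd / n
    if vr <= 0.0 or vd <= 0.0:
        return np.nan
    return (srd - sr * sd / n) / np.sqrt(vr * vd)


@njit(cache=True)
def dvc_at_nodes(ref, deff, nodes, half, search, min_valid_fraction, cc_min, subpixel):
    """Integer search + parabolic subpixel refinement at every node.

    Parameters
    ----------
    ref, deff : float64 3D arrays (NaN = masked)
    nodes : (N, 3) int64 node centers (z, y, x), guaranteed to keep
        subset+search windows in bounds
    half : (subset_side - 1) // 2
    search : integer search radius (voxels)

    Returns
    -------
    u : (N, 3) float64 displacements (z, y, x), NaN where failed
    cc : (N,) float64 best correlation score
    status : (N,) int8
    """
    nn = nodes.shape[0]
    u = np.full((nn, 3), np.nan)
    cc = np.full(nn, np.nan)
    status = np.full(nn, STATUS_INSUFFICIENT_VALID, dtype=np.int8)

    side = 2 * half + 1
    subset_n = side * side * side
    w = 2 * search + 1

    ref_fin = np.isfinite(ref).astype(np.float64)
    def_fin = np.isfinite(deff).astype(np.float64)
    Crf = _integral(ref_fin)
    Cdf = _integral(def_fin)
    # zero-filled copies so integral sums ignore NaNs on the fast path
    d0 = np.where(def_fin > 0, deff, 0.0)
    Pd = _integral(d0)
    Pdd = _integral(d0 * d0)

    scores = np.empty((w, w, w), dtype=np.float64)
    rbuf = np.empty(subset_n, dtype=np.float64)

    for inode in range(nn):
        cz, cy, cx = nodes[inode, 0], nodes[inode, 1], nodes[inode, 2]
        z0, y0, x0 = cz - half, cy - half, cx - half
        z1, y1, x1 = cz + half + 1, cy + half + 1, cx + half + 1

        ref_full = _box_sum(Crf, z0, y0, x0, z1, y1, x1) == subset_n
        sr = 0.0
        srr = 0.0
        if ref_full:
            k = 0
            for dz in range(-half, half + 1):
                for dy in range(-half, half + 1):
                    for dx in range(-half, half + 1):
                        v = ref[cz + dz, cy + dy, cx + dx]
                        rbuf[k] = v
                        k += 1
                        sr += v
                        srr += v * v
        ref_var = srr - sr * sr / subset_n

        best = -2.0
        best_norm = 1.0e30
        boz = 0
        boy = 0
        box = 0
        any_valid = False
        for oz in range(-search, search + 1):
            for oy in range(-search, search + 1):
                for ox in range(-search, search + 1):
                    dz0, dy0, dx0 = z0 + oz, y0 + oy, x0 + ox
                    dz1, dy1, dx1 = z1 + oz, y1 + oy, x1 + ox
                    if ref_full and _box_sum(Cdf, dz0, dy0, dx0, dz1, dy1, dx1) == subset_n:
                        if ref_var <= 0.0:
                            s = np.nan
                        else:
                            sd = _box_sum(Pd, dz0, dy0, dx0, dz1, dy1, dx1)
                            sdd = _box_sum(Pdd, dz0, dy0, dx0, dz1, dy1, dx1)
                            vd = sdd - sd * sd / subset_n
                            if vd <= 0.0:
                                s = np.nan
                            else:
                                srd = 0.0
                                k = 0
                                for dz in range(-half, half + 1):
                                    zz = cz + oz + dz
                                    for dy in range(-half, half + 1):
                                        yy = cy + oy + dy
                                        xx = cx + ox - half
                                        for dx in range(side):
                                            srd += rbuf[k] * deff[zz, yy, xx + dx]
                                            k += 1
                                s = (srd - sr * sd / subset_n) / np.sqrt(ref_var * vd)
                    else:
                        s = _zncc_masked(ref, deff, cz, cy, cx, oz, oy, ox, half, min_valid_fraction)
                    scores[oz + search, oy + search, ox + search] = s
                    if s == s:
                        any_valid = True
                        nrm = float(oz * oz + oy * oy + ox * ox)
                        if s > best or (s == best and nrm < best_norm):
                            best = s
                            best_norm = nrm
                            boz, boy, box = oz, oy, ox

        if not any_valid:
            status[inode] = STATUS_INSUFFICIENT_VALID
            continue
        cc[inode] = best
        if best < cc_min:
            status[inode] = STATUS_LOW_CC
            continue
        status[inode] = STATUS_OK
        uz = float(boz)
        uy = float(boy)
        ux = float(box)
        # subpixel: separable parabola through the optimum; skipped at the
        # window boundary and at numerically perfect (cc ~ 1) matches
        if subpixel and best < 1.0 - 1e-9:
            iz, iy, ix = boz + search, boy + search, box + search
            if 0 < iz < w - 1 and 0 < iy < w - 1 and 0 < ix < w - 1:
                ok3 = True
                for a in (-1, 1):
                    if not (scores[iz + a, iy, ix] == scores[iz + a, iy, ix]
                            and scores[iz, iy + a, ix] == scores[iz, iy + a, ix]
                            and scores[iz, iy, ix + a] == scores[iz, iy, ix + a]):
                        ok3 = False
                if ok3:
                    uz += _parabolic(scores[iz - 1, iy, ix], best, scores[iz + 1, iy, ix])
                    uy += _parabolic(scores[iz, iy - 1, ix], best, scores[iz, iy + 1, ix])
                    ux += _parabolic(scores[iz, iy, ix - 1], best, scores[iz, iy, ix + 1])
        u[inode, 0] = uz
        u[inode, 1] = uy
        u[inode, 2] = ux
    return u, cc, status


@njit(cache=True, inline="always")
def _parabolic(sm, s0, sp):
    denom = sm - 2.0 * s0 + sp
    if denom == 0.0:
        return 0.0
    d = (sm - sp) / (2.0 * denom)
    if d > 0.499:
        d = 0.499
    elif d < -0.499:
        d = -0.499
    return d
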
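"""Image preparation: median filtering, screw-axis alignment, IsoData
thresholding, and phase masking to NaN.

The preparation chain used before morphometry and DVC is
filter -> align -> threshold/mask. The median filter uses a spherical
neighborhood (radius in voxels) and excludes NaN voxels from each
neighborhood sample; phase masking replaces background and screw voxels
with NaN so they never enter correlation sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .volume import DegenerateInputError, ParameterError, Volume


@dataclass
class PhaseMasks:
    """Disjoint background / screw masks and the gray thresholds that
    produced them."""

    background_mask: np.ndarray
    screw_mask: np.ndarray
    thresholds: tuple[float, float]  # (t_background, t_screw)

    def __post_init__(self) -> None:
        if (self.background_mask & self.screw_mask).any():
            raise ParameterError("background and screw masks overlap")


def spherical_offsets(radius: int) -> np.ndarray:
    """Integer offsets (dz, dy, dx) with squared norm <= radius^2."""
    r = int(radius)
    g = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(g, g, g, indexing="ij")
    keep = dz ** 2 + dy ** 2 + dx ** 2 <= r * r
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1).astype(np.int64)


@njit(cache=True)
def _median_kernel(data, offsets):
    nz, ny, nx = data.shape
    out = np.empty_like(data)
    m = offsets.shape[0]
    buf = np.empty(m, dtype=np.float64)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                k = 0
                for i in range(m):
                    zz = z + offsets[i, 0]
                    yy = y + offsets[i, 1]
                    xx = x + offsets[i, 2]
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                        v = data[zz, yy, xx]
                        if v == v:
                            buf[k] = v
                            k += 1
                if k == 0:
                    out[z, y, x] = np.nan
                else:
                    vals = np.sort(buf[:k])
                    if k % 2 == 1:
                        out[z, y, x] = vals[k // 2]
                    else:
                        out[z, y, x] = 0.5 * (vals[k // 2 - 1] + vals[k // 2])
    return out


def median_filter3d(vol: Volume, radius_vox: int) -> Volume:
    """Median over the spherical neighborhood of the given radius; NaN
    voxels are excluded from each neighborhood sample. Radius 0 is the
    identity."""
    if radius_vox < 0:
        raise ParameterError(f"radius must be >= 0, got {radius_vox}")
    if radius_vox == 0:
        return vol.copy()
    out = vol.with_data(_median_kernel(np.ascontiguousarray(vol.data), spherical_offsets(radius_vox)))
    # filtering may fill isolated NaNs from neighbors; keep original mask
    out.data[~np.isfinite(vol.data)] = np.nan
    out.meta["median_radius_vox"] = radius_vox
    return out


def isodata_threshold(vol: Volume | np.ndarray, tol: float = 0.5, max_iter: int = 500) -> float:
    """IsoData automatic threshold: the fixed point
    t = (mean(values < t) + mean(values >= t)) / 2, iterated from the
    global mean until the step falls below ``tol`` gray levels."""
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol, dtype=np.float64)
    vals = data[np.isfinite(data)]
    if vals.size == 0 or np.unique(vals).size < 2:
        raise DegenerateInputError("IsoData needs at least two distinct finite values")
    t = float(vals.mean())
    for _ in range(max_iter):
        lo = vals[vals < t]
        hi = vals[vals >= t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = 0.5 * (float(lo.mean()) + float(hi.mean()))
        if abs(t_new - t) < tol:
            return t_new
        t = t_new
    return t


def align_screw_axis(vol: Volume, screw_mask: np.ndarray) -> tuple[Volume, np.ndarray]:
    """Rotate the volume so the screw's long axis maps onto +z.

    The axis is the principal component of the screw-mask voxel
    coordinates; the rotation (returned as a 3x3 matrix in (z, y, x) index
    order) is applied about the volume centre with trilinear resampling,
    out-of-domain voxels becoming NaN.
    """
    from scipy import ndimage

    coords = np.argwhere(screw_mask).astype(np.float64)
    if coords.shape[0] < 8:
        raise ParameterError("screw mask is empty or too small")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    if evals[1] <= 0 or np.sqrt(evals[0] / evals[1]) < 1.2:
        raise ParameterError("screw mask is not elongated enough for axis alignment")
    axis = evecs[:, order[0]]
    if axis[0] < 0:
        axis = -axis
    ez = np.array([1.0, 0.0, 0.0])  # +z in (z, y, x) order
    v = np.cross(axis, ez)
    s = np.linalg.norm(v)
    c = float(axis @ ez)
    if s < 1e-12:
        R = np.eye(3)
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s ** 2)
    center = (np.array(vol.shape, dtype=np.float64) - 1) / 2
    matrix = R.T  # output -> input mapping
    offset = center - matrix @ center
    rotated = ndimage.affine_transform(
        vol.data, matrix, offset=offset, order=1, mode="constant", cval=np.nan
    )
    out = vol.with_data(rotated)
    out.meta["alignment_rotation"] = R
    return out, R


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle of a 3x3 rotation matrix, degrees."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def mask_phases(vol: Volume, t_background: float, t_screw: float) -> tuple[Volume, PhaseMasks]:
    """NaN-out voxels below ``t_background`` (air/marrow) and at or above
    ``t_screw`` (metal). Unmasked intensities are never altered."""
    if not t_background < t_screw:
        raise ParameterError(f"need t_background < t_screw, got {t_background} >= {t_screw}")
    finite = np.isfinite(vol.data)
    bg = finite & (vol.data < t_background)
    screw = finite & (vol.data >= t_screw)
    out = vol.copy()
    out.data[bg | screw] = np.nan
    masks = PhaseMasks(background_mask=bg, screw_mask=screw, thresholds=(t_background, t_screw))
    out.meta["phase_thresholds"] = (t_background, t_screw)
    return out, masks


def default_phantom_thresholds(vol: Volume, bone_intensity: float, screw_intensity: float) -> tuple[float, float]:
    """Default masking thresholds for phantoms: IsoData between background
    and bone, midpoint between bone and screw. Real scans require
    explicitly configured thresholds."""
    below_screw = vol.data[np.isfinite(vol.data) & (vol.data < 0.5 * (bone_intensity + screw_intensity))]
    t_bg = isodata_threshold(below_screw)
    return t_bg, 0.5 * (bone_intensity + screw_intensity)
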
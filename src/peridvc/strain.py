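"""Green-Lagrange strain from a gridded displacement field.

The node grid is interpreted as a mesh of 8-node hexahedral finite
elements (one element per grid cell). Displacements are median-smoothed on
the grid, the deformation gradient F = I + du/dX is evaluated at each
element center from trilinear shape-function derivatives, and from F the
Green-Lagrange tensor E = (F^T F - I)/2, the volumetric strain det(F) - 1
and a scalar maximum shear strain

    gamma = (1/3) * sqrt( 2(exx - eyy)^2 + 2(exx - ezz)^2 + 2(eyy - ezz)^2
                          + 12 eyx^2 + 12 ezx^2 + 12 ezy^2 )

are derived. E is symmetric, so the six stored components are
(exx, eyy, ezz, eyx, ezx, ezy) with eyx = exy etc. Rigid translations and
rotations produce zero strain; fields linear in position reproduce their F
exactly in every element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dvc import STATUS_OK, DisplacementField
from .volume import ParameterError

#: storage order of the six independent components
COMPONENT_NAMES = ("exx", "eyy", "ezz", "eyx", "ezx", "ezy")

ELEMENT_OK = 0
ELEMENT_FAILED_CORNER = 1


@dataclass
class StrainField:
    """Per-element strain state at element centers.

    ``coords`` are element-center coordinates (voxels, reference frame)
    along (z, y, x); arrays are shaped by the element grid, which has one
    fewer entry per axis than the node grid. Elements with any failed
    corner node carry NaN and ``status != 0``.
    """

    coords: tuple[np.ndarray, np.ndarray, np.ndarray]
    F: np.ndarray            # (ez, ey, ex, 3, 3), index order (z, y, x)
    components: np.ndarray   # (ez, ey, ex, 6) in COMPONENT_NAMES order
    volumetric: np.ndarray   # (ez, ey, ex)
    max_shear: np.ndarray    # (ez, ey, ex)
    status: np.ndarray       # (ez, ey, ex) int8
    voxel_size_um: float = 25.0
    meta: dict = field(default_factory=dict)

    @property
    def ok(self) -> np.ndarray:
        return self.status == ELEMENT_OK

    def summary(self) -> dict:
        """Min/max/quantile summary per derived quantity over valid elements."""
        out: dict[str, dict[str, float]] = {}
        names = list(COMPONENT_NAMES) + ["volumetric", "max_shear"]
        arrays = [self.components[..., i] for i in range(6)] + [self.volumetric, self.max_shear]
        for name, arr in zip(names, arrays):
            vals = arr[self.ok]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                out[name] = {}
                continue
            q = np.quantile(vals, [0.25, 0.5, 0.75])
            out[name] = {
                "min": float(vals.min()), "q25": float(q[0]), "median": float(q[1]),
                "q75": float(q[2]), "max": float(vals.max()), "n": int(vals.size),
            }
        return out


def smooth_displacements(fld: DisplacementField, radius_nodes: int = 1) -> DisplacementField:
    """Componentwise median filter on the node grid (radius counted in
    nodes, cubic (2r+1)^3 neighborhood). Failed nodes are excluded from
    every neighborhood sample; statuses are preserved."""
    if radius_nodes < 0:
        raise ParameterError(f"radius must be >= 0, got {radius_nodes}")
    if radius_nodes == 0:
        return fld
    u = fld.u.copy()
    u[~fld.ok] = np.nan
    r = radius_nodes
    padded = np.pad(u, ((r, r), (r, r), (r, r), (0, 0)), constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (2 * r + 1,) * 3, axis=(0, 1, 2))
    # win shape: (nz, ny, nx, 3, 2r+1, 2r+1, 2r+1)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        smoothed = np.nanmedian(win.reshape(win.shape[:4] + (-1,)), axis=-1)
    out_u = fld.u.copy()
    ok = fld.ok & np.isfinite(smoothed).all(axis=-1)
    out_u[ok] = smoothed[ok]
    sm = DisplacementField(
        coords=fld.coords, u=out_u, cc=fld.cc, status=fld.status.copy(),
        voxel_size_um=fld.voxel_size_um, node_spacing_vox=fld.node_spacing_vox,
        meta=dict(fld.meta),
    )
    sm.meta["smoothing_radius_nodes"] = radius_nodes
    return sm


def deformation_gradient(fld: DisplacementField, element: tuple[int, int, int]) -> np.ndarray:
    """F = I + du/dX at the center of one element (grid-cell indices).

    Trilinear shape functions make the center gradient along each axis the
    mean of the four corner-pair differences, divided by the node spacing
    along that axis. Index order of F is (z, y, x). Raises if any corner
    displacement is missing.
    """
    iz, iy, ix = element
    corners_u = fld.u[iz:iz + 2, iy:iy + 2, ix:ix + 2]  # (2,2,2,3)
    corners_ok = fld.ok[iz:iz + 2, iy:iy + 2, ix:ix + 2]
    if corners_u.shape[:3] != (2, 2, 2):
        raise ParameterError(f"element {element} outside the grid")
    if not (corners_ok.all() and np.isfinite(corners_u).all()):
        raise ParameterError(f"element {element} has failed corner nodes")
    h = [float(c[i + 1] - c[i]) for c, i in zip(fld.coords, element)]
    du = np.empty((3, 3))
    du[:, 0] = (corners_u[1] - corners_u[0]).mean(axis=(0, 1)) / h[0]
    du[:, 1] = (corners_u[:, 1] - corners_u[:, 0]).mean(axis=(0, 1)) / h[1]
    du[:, 2] = (corners_u[:, :, 1] - corners_u[:, :, 0]).mean(axis=(0, 1)) / h[2]
    # du rows are (u_z, u_y, u_x) — already aligned with (z, y, x) indices
    return np.eye(3) + du


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """E = (F^T F - I)/2; returns the full symmetric 3x3 tensor in the
    same (z, y, x) index order as F."""
    F = np.asarray(F, dtype=np.float64)
    return 0.5 * (F.T @ F - np.eye(3))


def volumetric_strain(F: np.ndarray) -> float:
    """det(F) - 1: local relative volume change."""
    return float(np.linalg.det(np.asarray(F, dtype=np.float64)) - 1.0)


def tensor_components(E: np.ndarray) -> np.ndarray:
    """Extract (exx, eyy, ezz, eyx, ezx, ezy) from a (z, y, x)-ordered
    tensor: physical x is array axis 2, z is axis 0."""
    return np.array([E[2, 2], E[1, 1], E[0, 0], E[1, 2], E[0, 2], E[0, 1]])


def max_shear(E: np.ndarray) -> float:
    """Scalar maximum shear strain of a Green-Lagrange tensor.

    Zero for isotropic strain states; always >= 0.
    """
    exx, eyy, ezz, eyx, ezx, ezy = tensor_components(np.asarray(E, dtype=np.float64))
    return float(
        (1.0 / 3.0) * np.sqrt(
            2.0 * (exx - eyy) ** 2 + 2.0 * (exx - ezz) ** 2 + 2.0 * (eyy - ezz) ** 2
            + 12.0 * eyx ** 2 + 12.0 * ezx ** 2 + 12.0 * ezy ** 2
        )
    )


def run_strain(fld: DisplacementField, smoothing_radius_nodes: int = 1) -> StrainField:
    """Full chain: median smoothing (default radius 1 node) -> per-element
    F -> Green-Lagrange components, volumetric strain and max shear."""
    if int(fld.ok.sum()) < 8:
        raise ParameterError("need at least 8 valid nodes to form one element")
    sm = smooth_displacements(fld, smoothing_radius_nodes)
    gz, gy, gx = sm.grid_shape
    ez, ey, ex = gz - 1, gy - 1, gx - 1
    if min(ez, ey, ex) < 1:
        raise ParameterError("node grid too small to form elements")
    F = np.full((ez, ey, ex, 3, 3), np.nan)
    comps = np.full((ez, ey, ex, 6), np.nan)
    vols = np.full((ez, ey, ex), np.nan)
    shear = np.full((ez, ey, ex), np.nan)
    status = np.full((ez, ey, ex), ELEMENT_FAILED_CORNER, dtype=np.int8)

    ok = sm.ok & np.isfinite(sm.u).all(axis=-1)
    corner_ok = (
        ok[:-1, :-1, :-1] & ok[1:, :-1, :-1] & ok[:-1, 1:, :-1] & ok[:-1, :-1, 1:]
        & ok[1:, 1:, :-1] & ok[1:, :-1, 1:] & ok[:-1, 1:, 1:] & ok[1:, 1:, 1:]
    )
    # vectorized center gradients over all elements at once
    h = [np.diff(c).astype(np.float64) for c in sm.coords]
    u = np.where(ok[..., None], sm.u, np.nan)
    dz = (u[1:, :, :] - u[:-1, :, :])[:, :-1, :-1] + (u[1:, :, :] - u[:-1, :, :])[:, 1:, :-1] \
        + (u[1:, :, :] - u[:-1, :, :])[:, :-1, 1:] + (u[1:, :, :] - u[:-1, :, :])[:, 1:, 1:]
    dy = (u[:, 1:, :] - u[:, :-1, :])[:-1, :, :-1] + (u[:, 1:, :] - u[:, :-1, :])[1:, :, :-1] \
        + (u[:, 1:, :] - u[:, :-1, :])[:-1, :, 1:] + (u[:, 1:, :] - u[:, :-1, :])[1:, :, 1:]
    dx = (u[:, :, 1:] - u[:, :, :-1])[:-1, :-1, :] + (u[:, :, 1:] - u[:, :, :-1])[1:, :-1, :] \
        + (u[:, :, 1:] - u[:, :, :-1])[:-1, 1:, :] + (u[:, :, 1:] - u[:, :, :-1])[1:, 1:, :]
    grad = np.stack([
        dz / (4.0 * h[0][:, None, None, None]),
        dy / (4.0 * h[1][None, :, None, None]),
        dx / (4.0 * h[2][None, None, :, None]),
    ], axis=-1)  # (ez, ey, ex, 3 comp, 3 axis)
    Fall = np.eye(3) + grad
    valid = corner_ok & np.isfinite(Fall).all(axis=(-2, -1))
    F[valid] = Fall[valid]
    status[valid] = ELEMENT_OK

    if valid.any():
        Fv = Fall[valid]
        Ev = 0.5 * (np.swapaxes(Fv, -1, -2) @ Fv - np.eye(3))
        comps[valid] = np.stack(
            [Ev[:, 2, 2], Ev[:, 1, 1], Ev[:, 0, 0], Ev[:, 1, 2], Ev[:, 0, 2], Ev[:, 0, 1]],
            axis=1,
        )
        vols[valid] = np.linalg.det(Fv) - 1.0
        e = comps[valid]
        shear[valid] = (1.0 / 3.0) * np.sqrt(
            2.0 * (e[:, 0] - e[:, 1]) ** 2 + 2.0 * (e[:, 0] - e[:, 2]) ** 2
            + 2.0 * (e[:, 1] - e[:, 2]) ** 2
            + 12.0 * (e[:, 3] ** 2 + e[:, 4] ** 2 + e[:, 5] ** 2)
        )

    centers = tuple((c[:-1] + c[1:]) / 2.0 for c in sm.coords)
    sf = StrainField(
        coords=centers, F=F, components=comps, volumetric=vols, max_shear=shear,
        status=status, voxel_size_um=fld.voxel_size_um,
    )
    sf.meta.update(
        smoothing_radius_nodes=smoothing_radius_nodes,
        n_valid_elements=int(valid.sum()),
        summary=sf.summary(),
    )
    return sf
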
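"""Synthetic peri-implant tomogram generator.

Produces 3D gray-value volumes that emulate a micro-CT scan of trabecular
bone surrounding a threaded metal screw: a thresholded Gaussian random
field for the trabecular network (controllable solid fraction BV/TV and
feature size), a bright threaded cylinder along z for the screw, imposed
warp fields with analytic ground truth (rigid, affine, pullout envelope),
and additive Gaussian noise. Every output is a pure function of
(spec, seed).

The warp convention matches the tracking direction of subset DVC: the
displacement field u is defined on the reference frame and the deformed
image is resampled as ``deformed(x) = reference(x - u(x))``, so a DVC run
between the pair should recover u at the nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume import GeometryError, ParameterError, Volume

WARP_KINDS = ("rigid_translation", "rigid_rotation", "affine", "pullout_envelope")


@dataclass
class PhantomSpec:
    """Geometry, texture and intensity parameters of a synthetic scan.

    Defaults follow the imaging conditions of the rat-tibia screw model:
    25 μm voxels, peri-implant solid fraction 0.32, screw outer radius
    1300 μm (Ø 2.6 mm) with ~200 μm threads.
    """

    dims: tuple[int, int, int] = (96, 96, 96)  # (z, y, x) voxel counts
    voxel_size_um: float = 25.0
    target_bvtv: float = 0.32
    screw_radius_um: float = 1300.0
    thread_pitch_um: float = 400.0
    thread_depth_um: float = 150.0
    bone_texture_scale_um: float = 150.0
    psf_sigma_vox: float = 0.8  # scanner point-spread blur (voxels)
    intensities: tuple[float, float, float] = (50.0, 150.0, 250.0)  # bg, bone, screw
    seed: int = 0

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)  # type: ignore[assignment]
        if len(self.dims) != 3 or any(d < 32 for d in self.dims):
            raise ParameterError(f"dims must be 3 values all >= 32, got {self.dims}")
        if not (0.0 < self.target_bvtv <= 1.0):
            raise ParameterError(f"target_bvtv must lie in (0, 1], got {self.target_bvtv}")
        bg, bone, screw = self.intensities
        if not (bg < bone < screw):
            raise ParameterError(f"intensities must be strictly ordered bg < bone < screw, got {self.intensities}")
        if self.voxel_size_um <= 0:
            raise ParameterError("voxel_size_um must be > 0")
        if self.screw_radius_um < 0 or self.thread_depth_um < 0 or self.thread_pitch_um <= 0:
            raise ParameterError("screw geometry must be non-negative (pitch > 0)")
        if self.psf_sigma_vox < 0:
            raise ParameterError("psf_sigma_vox must be >= 0")

    @property
    def background_intensity(self) -> float:
        return self.intensities[0]

    @property
    def bone_intensity(self) -> float:
        return self.intensities[1]

    @property
    def screw_intensity(self) -> float:
        return self.intensities[2]


@dataclass
class WarpSpec:
    """An imposed ground-truth displacement field.

    kind selects the parameter set that must be provided:

    - ``rigid_translation``: translation_vox (3-vector, voxels, (z, y, x))
    - ``rigid_rotation``: rotation_axis (3-vector) + rotation_deg, about the
      volume centre
    - ``affine``: affine_matrix (3x3 deformation gradient F, positive
      determinant) applied about the volume centre, u(x) = (F - I)(x - c)
    - ``pullout_envelope``: axial (z) displacement of ``envelope_magnitude_vox``
      voxels for material within ``envelope_inner_um`` of the screw surface,
      cosine-tapering to zero over ``envelope_decay_um``; emulates the shell
      of displaced bone seen around a pulled screw.
    """

    kind: str = "rigid_translation"
    translation_vox: Optional[tuple[float, float, float]] = None
    rotation_axis: Optional[tuple[float, float, float]] = None
    rotation_deg: Optional[float] = None
    affine_matrix: Optional[np.ndarray] = None
    envelope_magnitude_vox: Optional[float] = None
    envelope_inner_um: float = 300.0
    envelope_decay_um: float = 400.0

    def __post_init__(self) -> None:
        if self.kind not in WARP_KINDS:
            raise ParameterError(f"unknown warp kind {self.kind!r}; choose from {WARP_KINDS}")
        required = {
            "rigid_translation": ("translation_vox",),
            "rigid_rotation": ("rotation_axis", "rotation_deg"),
            "affine": ("affine_matrix",),
            "pullout_envelope": ("envelope_magnitude_vox",),
        }[self.kind]
        for name in required:
            if getattr(self, name) is None:
                raise ParameterError(f"warp kind {self.kind!r} requires parameter {name!r}")
        extras = {
            "translation_vox", "rotation_axis", "rotation_deg", "affine_matrix",
            "envelope_magnitude_vox",
        } - set(required)
        for name in extras:
            if getattr(self, name) is not None:
                raise ParameterError(f"parameter {name!r} is not valid for warp kind {self.kind!r}")
        if self.kind == "affine":
            self.affine_matrix = np.asarray(self.affine_matrix, dtype=np.float64)
            if self.affine_matrix.shape != (3, 3):
                raise ParameterError("affine_matrix must be 3x3")
            if np.linalg.det(self.affine_matrix) <= 0:
                raise ParameterError("affine_matrix must have positive determinant")
        if self.envelope_decay_um <= 0 or self.envelope_inner_um < 0:
            raise ParameterError("envelope extents must be positive")


def make_trabecular_volume(spec: PhantomSpec) -> Volume:
    """Generate the trabecular texture: a smoothed Gaussian random field
    thresholded at the quantile that yields ``target_bvtv`` solid fraction.

    Solid voxels take the bone intensity, the rest the background
    intensity. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(spec.dims)
    # correlation length ~ texture scale; gaussian std of half the scale in voxels
    sigma_vox = 0.5 * spec.bone_texture_scale_um / spec.voxel_size_um
    fld = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    if spec.target_bvtv >= 1.0:
        solid = np.ones(spec.dims, dtype=bool)
    else:
        thr = np.quantile(fld, 1.0 - spec.target_bvtv)
        solid = fld > thr
    data = np.where(solid, spec.bone_intensity, spec.background_intensity).astype(np.float64)
    if spec.psf_sigma_vox > 0:
        # band-limit like a real scanner: without partial-volume blur the
        # correlation peak is triangular and subpixel interpolation locks
        # onto integer voxels
        data = ndimage.gaussian_filter(data, spec.psf_sigma_vox)
    vol = Volume(data, voxel_size_um=spec.voxel_size_um)
    vol.meta.update(
        kind="trabecular_phantom",
        seed=spec.seed,
        target_bvtv=spec.target_bvtv,
        bone_mask_fraction=float(solid.mean()),
    )
    return vol


def _screw_surface_radius_um(z_um: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Axisymmetric thread profile: outer radius minus a triangular-wave
    thread groove of depth ``thread_depth_um`` and period ``thread_pitch_um``.
    Maximal radius equals ``screw_radius_um`` (thread crests)."""
    phase = np.mod(z_um, spec.thread_pitch_um) / spec.thread_pitch_um
    tri = 2.0 * np.abs(phase - 0.5)  # 1 at crest, 0 at groove root
    return spec.screw_radius_um - spec.thread_depth_um * (1.0 - tri)


def insert_screw(vol: Volume, spec: PhantomSpec) -> Volume:
    """Overwrite a threaded cylinder along z at the screw intensity.

    The screw axis passes through the volume centre in (y, x) and spans the
    full z extent. The boolean screw mask and the screw geometry are stored
    in ``meta`` for downstream masking, warping and ROI definition.
    """
    if spec.screw_radius_um <= 0:
        out = vol.copy()
        out.meta.update(screw_radius_um=0.0)
        return out
    nz, ny, nx = vol.shape
    r_max_vox = spec.screw_radius_um / vol.voxel_size_um
    if r_max_vox > min(ny, nx) / 2.0 - 1.0:
        raise GeometryError(
            f"screw radius {spec.screw_radius_um} um ({r_max_vox:.1f} vox) does not fit "
            f"inside the {ny}x{nx} cross-section"
        )
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    z = np.arange(nz)[:, None, None]
    y = np.arange(ny)[None, :, None]
    x = np.arange(nx)[None, None, :]
    r_um = np.hypot(y - cy, x - cx) * vol.voxel_size_um
    surf = _screw_surface_radius_um((z - cz) * vol.voxel_size_um, spec)
    mask = r_um <= surf
    out = vol.copy()
    out.data[mask] = spec.screw_intensity
    out.meta.update(
        screw_mask=mask,
        screw_radius_um=spec.screw_radius_um,
        screw_center_yx=(cy, cx),
    )
    return out


def displacement_field(warp: WarpSpec, vol: Volume) -> np.ndarray:
    """Analytic ground-truth displacement u (voxels) on the full voxel grid.

    Returns an array of shape (3, nz, ny, nx) ordered (u_z, u_y, u_x).
    """
    nz, ny, nx = vol.shape
    c = (np.array(vol.shape, dtype=np.float64) - 1.0) / 2.0
    u = np.zeros((3, nz, ny, nx), dtype=np.float64)
    if warp.kind == "rigid_translation":
        t = np.asarray(warp.translation_vox, dtype=np.float64)
        u += t[:, None, None, None]
    elif warp.kind in ("rigid_rotation", "affine"):
        if warp.kind == "rigid_rotation":
            axis = np.asarray(warp.rotation_axis, dtype=np.float64)
            n = np.linalg.norm(axis)
            if n == 0:
                raise ParameterError("rotation_axis must be nonzero")
            axis = axis / n
            theta = np.deg2rad(warp.rotation_deg)
            K = np.array([
                [0.0, -axis[2], axis[1]],
                [axis[2], 0.0, -axis[0]],
                [-axis[1], axis[0], 0.0],
            ])
            F = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        else:
            F = warp.affine_matrix
        A = F - np.eye(3)
        zz = np.arange(nz, dtype=np.float64)[:, None, None] - c[0]
        yy = np.arange(ny, dtype=np.float64)[None, :, None] - c[1]
        xx = np.arange(nx, dtype=np.float64)[None, None, :] - c[2]
        for i in range(3):
            u[i] = A[i, 0] * zz + A[i, 1] * yy + A[i, 2] * xx
    elif warp.kind == "pullout_envelope":
        screw_r_um = float(vol.meta.get("screw_radius_um", 0.0))
        cy, cx = vol.meta.get("screw_center_yx", (c[1], c[2]))
        y = np.arange(ny, dtype=np.float64)[:, None] - cy
        x = np.arange(nx, dtype=np.float64)[None, :] - cx
        d_um = np.hypot(y, x) * vol.voxel_size_um - screw_r_um  # distance from surface
        inner, decay = warp.envelope_inner_um, warp.envelope_decay_um
        taper = np.where(
            d_um <= inner,
            1.0,
            np.where(
                d_um <= inner + decay,
                0.5 * (1.0 + np.cos(np.pi * (d_um - inner) / decay)),
                0.0,
            ),
        )
        u[0] = warp.envelope_magnitude_vox * taper[None, :, :]
    return u


def envelope_peak_shear_radius_um(warp: WarpSpec, vol: Volume) -> float:
    """Radius (from screw axis, μm) where the imposed envelope's radial
    gradient |du_z/dr| — and hence the ground-truth shear — is largest:
    the midpoint of the cosine taper."""
    if warp.kind != "pullout_envelope":
        raise ParameterError("only defined for pullout_envelope warps")
    screw_r_um = float(vol.meta.get("screw_radius_um", 0.0))
    return screw_r_um + warp.envelope_inner_um + warp.envelope_decay_um / 2.0


def apply_warp(vol: Volume, warp: WarpSpec) -> Volume:
    """Resample the volume under the imposed displacement field.

    ``deformed(x) = reference(x - u(x))`` by trilinear interpolation; voxels
    pulling from outside the volume (or from masked NaN voxels) become NaN.
    Integer rigid translations are applied by exact index shifting so they
    incur no interpolation error.
    """
    if warp.kind == "rigid_translation":
        t = np.asarray(warp.translation_vox, dtype=np.float64)
        if np.allclose(t, np.round(t)):
            return _integer_shift(vol, np.round(t).astype(int))
    u = displacement_field(warp, vol)
    nz, ny, nx = vol.shape
    coords = np.empty((3, nz, ny, nx), dtype=np.float64)
    coords[0] = np.arange(nz, dtype=np.float64)[:, None, None] - u[0]
    coords[1] = np.arange(ny, dtype=np.float64)[None, :, None] - u[1]
    coords[2] = np.arange(nx, dtype=np.float64)[None, None, :] - u[2]
    warped = ndimage.map_coordinates(
        vol.data, coords.reshape(3, -1), order=1, mode="constant", cval=np.nan
    ).reshape(vol.shape)
    out = vol.with_data(warped)
    out.meta.update(warp_kind=warp.kind)
    if "screw_mask" in vol.meta:
        # carry the screw mask through the same geometric transform
        shifted = ndimage.map_coordinates(
            vol.meta["screw_mask"].astype(np.float64), coords.reshape(3, -1),
            order=1, mode="constant", cval=0.0,
        ).reshape(vol.shape)
        out.meta["screw_mask"] = shifted >= 0.5
    return out


def _integer_shift(vol: Volume, t: np.ndarray) -> Volume:
    out_data = np.full(vol.shape, np.nan)
    nz, ny, nx = vol.shape
    src = []
    dst = []
    for n, ti in zip((nz, ny, nx), t):
        dst.append(slice(max(ti, 0), min(n + ti, n)))
        src.append(slice(max(-ti, 0) + 0, min(n - ti, n)))
    out_data[tuple(dst)] = vol.data[tuple(src)]
    out = vol.with_data(out_data)
    out.meta.update(warp_kind="rigid_translation")
    if "screw_mask" in vol.meta:
        m = np.zeros(vol.shape, dtype=bool)
        m[tuple(dst)] = vol.meta["screw_mask"][tuple(src)]
        out.meta["screw_mask"] = m
    return out


def add_noise(vol: Volume, sigma: float, seed: int) -> Volume:
    """Add zero-mean Gaussian noise of standard deviation ``sigma`` (gray
    values). NaN voxels stay NaN; deterministic given ``seed``."""
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    out = vol.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=vol.shape)
    finite = np.isfinite(out.data)
    out.data[finite] += noise[finite]
    out.meta.update(noise_sigma=sigma, noise_seed=seed)
    return out


def make_phantom_pair(
    spec: PhantomSpec,
    warp: Optional[WarpSpec] = None,
    noise_sigma: float = 0.0,
    noise_seeds: tuple[int, int] = (1, 2),
) -> tuple[Volume, Volume]:
    """Convenience chain: texture -> screw -> (warp) -> independent noise.

    Returns (reference, deformed); with ``warp=None`` the pair is a
    repeated-scan couple (identical geometry, independent noise), the
    configuration used for DVC error quantification.
    """
    clean = insert_screw(make_trabecular_volume(spec), spec)
    moved = apply_warp(clean, warp) if warp is not None else clean
    ref = add_noise(clean, noise_sigma, noise_seeds[0])
    def_ = add_noise(moved, noise_sigma, noise_seeds[1])
    return ref, def_
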
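"""Error quantification, peri-implant morphometry, insertion geometry and
correlation statistics.

DVC accuracy/precision follow the repeated-scan protocol: correlate two
scans of the same unloaded specimen, then report the mean (accuracy, a
systematic error) and standard deviation (precision, a random error) of
each displacement component over ok nodes, and of the pooled absolute
values of the six Green-Lagrange strain components over valid elements.
Displacements are reported in μm, strains in microstrain (με, 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dvc import DisplacementField
from .strain import StrainField
from .volume import GeometryError, ParameterError, Volume


@dataclass
class ErrorReport:
    disp_accuracy_um: tuple[float, float, float]   # mean per (z, y, x) component
    disp_precision_um: tuple[float, float, float]  # std per (z, y, x) component
    strain_accuracy_ustrain: float   # mean of pooled |components|
    strain_precision_ustrain: float  # std of pooled |components|
    n_nodes: int
    n_elements: int

    @property
    def max_abs_accuracy_um(self) -> float:
        return float(np.max(np.abs(self.disp_accuracy_um)))

    @property
    def max_precision_um(self) -> float:
        return float(np.max(self.disp_precision_um))

    def as_dict(self) -> dict:
        return {
            "disp_accuracy_um": {"z": self.disp_accuracy_um[0], "y": self.disp_accuracy_um[1], "x": self.disp_accuracy_um[2]},
            "disp_precision_um": {"z": self.disp_precision_um[0], "y": self.disp_precision_um[1], "x": self.disp_precision_um[2]},
            "strain_accuracy_ustrain": self.strain_accuracy_ustrain,
            "strain_precision_ustrain": self.strain_precision_ustrain,
            "n_nodes": self.n_nodes,
            "n_elements": self.n_elements,
        }


@dataclass
class MorphometryResult:
    bv_mm3: float
    tv_mm3: float
    bvtv: float
    roi: dict = field(default_factory=dict)

    @property
    def bvtv_percent(self) -> float:
        return 100.0 * self.bvtv


@dataclass
class GeometryMeasure:
    plateau_distance_mm: float
    tilt_deg: float


def dvc_error_report(
    fld: DisplacementField, strain_fld: Optional[StrainField], voxel_size_um: float,
) -> ErrorReport:
    """Accuracy (mean) and precision (population std) of the displacement
    components over ok nodes, in μm; ditto for the pooled absolute strain
    components over valid elements, in με."""
    ok_u = fld.ok_displacements()
    if ok_u.shape[0] == 0:
        raise ParameterError("no ok nodes: cannot quantify errors")
    mean_vox = ok_u.mean(axis=0)
    std_vox = ok_u.std(axis=0)  # population std
    acc = tuple(float(v) for v in mean_vox * voxel_size_um)
    prec = tuple(float(v) for v in std_vox * voxel_size_um)
    s_acc = float("nan")
    s_prec = float("nan")
    n_el = 0
    if strain_fld is not None:
        comps = strain_fld.components[strain_fld.ok]
        comps = comps[np.isfinite(comps).all(axis=1)]
        n_el = comps.shape[0]
        if n_el > 0:
            pooled = np.abs(comps).ravel() * 1e6
            s_acc = float(pooled.mean())
            s_prec = float(pooled.std())
    return ErrorReport(
        disp_accuracy_um=acc, disp_precision_um=prec,
        strain_accuracy_ustrain=s_acc, strain_precision_ustrain=s_prec,
        n_nodes=int(ok_u.shape[0]), n_elements=int(n_el),
    )


def bvtv_cylinder(
    vol_binary: Volume,
    screw_axis: tuple[float, float, float],
    screw_max_radius_um: float,
    radial_extent_um: float = 500.0,
    axial_span_um: float = 2200.0,
) -> MorphometryResult:
    """BV/TV in a cylindrical shell ROI around the screw.

    The ROI contains voxels (decided by voxel-center coordinates) with
    radial distance from the screw axis in
    (screw_max_radius, screw_max_radius + radial_extent] and axial
    distance from the thread midpoint z0 within axial_span/2. Defaults are
    the peri-implant protocol: 0.5 mm radial shell beyond the screw
    maximal diameter over a 2.2 mm thread span. A ROI that leaves the
    volume is refused.

    ``vol_binary.data`` must be a 0/1 (or boolean) solid map; ``screw_axis``
    is (z0, cy, cx) in voxels, the axis running along z.
    """
    data = vol_binary.data
    if not np.isin(data[np.isfinite(data)], (0.0, 1.0)).all():
        raise ParameterError("bvtv_cylinder expects a binary (0/1) volume")
    vs = vol_binary.voxel_size_um
    z0, cy, cx = screw_axis
    nz, ny, nx = vol_binary.shape
    r_out_vox = (screw_max_radius_um + radial_extent_um) / vs
    half_span_vox = axial_span_um / 2.0 / vs
    if (cy - r_out_vox < -0.5 or cy + r_out_vox > ny - 0.5
            or cx - r_out_vox < -0.5 or cx + r_out_vox > nx - 0.5
            or z0 - half_span_vox < -0.5 or z0 + half_span_vox > nz - 0.5):
        raise GeometryError("cylindrical ROI extends beyond the volume (partial ROI refused)")
    z = np.arange(nz, dtype=np.float64)[:, None, None]
    y = np.arange(ny, dtype=np.float64)[None, :, None]
    x = np.arange(nx, dtype=np.float64)[None, None, :]
    r_um = np.hypot(y - cy, x - cx) * vs
    in_shell = (r_um > screw_max_radius_um) & (r_um <= screw_max_radius_um + radial_extent_um)
    in_span = np.abs(z - z0) * vs <= axial_span_um / 2.0
    roi = in_shell & in_span
    tv_vox = int(roi.sum())
    if tv_vox == 0:
        raise GeometryError("empty ROI")
    bv_vox = int(np.nansum(data[roi]))
    voxel_mm3 = (vs / 1000.0) ** 3
    return MorphometryResult(
        bv_mm3=bv_vox * voxel_mm3,
        tv_mm3=tv_vox * voxel_mm3,
        bvtv=bv_vox / tv_vox,
        roi={
            "screw_max_radius_um": screw_max_radius_um,
            "radial_extent_um": radial_extent_um,
            "axial_span_um": axial_span_um,
            "axis": tuple(float(v) for v in screw_axis),
            "tv_voxels": tv_vox,
            "bv_voxels": bv_vox,
        },
    )


def screw_plateau_geometry(
    screw_axis_2d: tuple[Sequence[float], Sequence[float]],
    plateau_2d: tuple[Sequence[float], Sequence[float]],
    thread_mid: Sequence[float],
) -> GeometryMeasure:
    """Screw-insertion geometry from 2D annotations (units mm).

    Each line is (point, direction). Distance is the orthogonal projection
    distance of the thread midpoint onto the plateau line; tilt is the
    acute angle between the screw axis and the plateau line.
    """
    pa, da = (np.asarray(v, dtype=np.float64) for v in screw_axis_2d)
    pp, dp = (np.asarray(v, dtype=np.float64) for v in plateau_2d)
    m = np.asarray(thread_mid, dtype=np.float64)
    for d in (da, dp):
        if np.linalg.norm(d) == 0:
            raise ParameterError("line direction must be nonzero")
    rel = m - pp
    dist = abs(float(dp[0] * rel[1] - dp[1] * rel[0])) / float(np.linalg.norm(dp))
    cosang = abs(float(da @ dp)) / (np.linalg.norm(da) * np.linalg.norm(dp))
    tilt = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    return GeometryMeasure(plateau_distance_mm=dist, tilt_deg=tilt)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Sample Pearson correlation with two-sided p from the t-transform
    (n-2 degrees of freedom). Returns (r, r^2, p)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ParameterError("pearson_r needs two equal-length 1D samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ParameterError("pearson_r requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)
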
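"""Local (subset-based) digital volume correlation.

A regular cubic grid of nodes is laid over the reference volume; around
each node a cubic subset of voxels is tracked into the deformed volume by
exhaustively scoring zero-normalized cross-correlation (ZNCC) over an
integer search window, followed by separable parabolic subpixel
refinement. NaN voxels (masked screw/background, out-of-domain regions)
are excluded from every correlation sum; nodes whose subsets lose too many
voxels, or whose best score is below ``cc_min``, are flagged rather than
reported.

Defaults reproduce the analysis grid used for peri-implant bone scans at
25 μm: node spacing 4 voxels and 17-voxel subsets, i.e. a 100 μm
displacement-map resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import (
    STATUS_INSUFFICIENT_VALID,
    STATUS_LOW_CC,
    STATUS_OK,
    STATUS_OUT_OF_BOUNDS,
)
from .volume import GeometryError, ParameterError, Volume

STATUS_NAMES = {
    STATUS_OK: "ok",
    STATUS_LOW_CC: "low_cc",
    STATUS_INSUFFICIENT_VALID: "insufficient_valid",
    STATUS_OUT_OF_BOUNDS: "out_of_bounds",
}


@dataclass
class DvcConfig:
    node_spacing_vox: int = 4
    subset_side_vox: int = 17
    search_radius_vox: int = 3
    min_valid_fraction: float = 0.5
    subpixel: bool = True
    cc_min: float = 0.5

    def __post_init__(self) -> None:
        if self.subset_side_vox < 3 or self.subset_side_vox % 2 == 0:
            raise ParameterError(f"subset_side_vox must be odd and >= 3, got {self.subset_side_vox}")
        if self.node_spacing_vox < 1:
            raise ParameterError(f"node_spacing_vox must be >= 1, got {self.node_spacing_vox}")
        if not (0.0 < self.min_valid_fraction <= 1.0):
            raise ParameterError(f"min_valid_fraction must lie in (0, 1], got {self.min_valid_fraction}")
        if self.search_radius_vox < 1:
            raise ParameterError(f"search_radius_vox must be >= 1, got {self.search_radius_vox}")

    @property
    def subset_half(self) -> int:
        return (self.subset_side_vox - 1) // 2

    @property
    def margin(self) -> int:
        return self.subset_half + self.search_radius_vox


@dataclass
class DisplacementField:
    """Per-node displacements on a regular grid.

    ``coords`` holds the node coordinates along (z, y, x) in reference-frame
    voxels; ``u`` is shaped ``(nz, ny, nx, 3)`` ordered (u_z, u_y, u_x) in
    voxels; ``cc`` and ``status`` are per-node. ``status == 0`` (ok) marks
    trustworthy nodes.
    """

    coords: tuple[np.ndarray, np.ndarray, np.ndarray]
    u: np.ndarray
    cc: np.ndarray
    status: np.ndarray
    voxel_size_um: float = 25.0
    node_spacing_vox: int = 4
    meta: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(len(c) for c in self.coords)  # type: ignore[return-value]

    @property
    def ok(self) -> np.ndarray:
        return self.status == STATUS_OK

    def ok_displacements(self) -> np.ndarray:
        """(n_ok, 3) displacements of ok nodes, in voxels."""
        return self.u[self.ok]

    def status_counts(self) -> dict[str, int]:
        return {name: int((self.status == code).sum()) for code, name in STATUS_NAMES.items()}


def build_node_grid(vol: Volume, cfg: DvcConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Node coordinates per axis: multiples of the node spacing whose full
    subset + search window stays inside the volume."""
    axes = []
    for n in vol.shape:
        lo = cfg.margin
        hi = n - 1 - cfg.margin
        if hi < lo:
            raise GeometryError(
                f"volume axis of {n} voxels cannot hold subset {cfg.subset_side_vox} "
                f"+ search {cfg.search_radius_vox}"
            )
        first = int(np.ceil(lo / cfg.node_spacing_vox)) * cfg.node_spacing_vox
        axes.append(np.arange(first, hi + 1, cfg.node_spacing_vox, dtype=np.int64))
    if any(len(a) == 0 for a in axes):
        raise GeometryError("no admissible nodes: volume too small for this grid")
    return tuple(axes)  # type: ignore[return-value]


def correlate_subset(
    ref: Volume, deformed: Volume, center: tuple[int, int, int],
    offset: tuple[int, int, int], cfg: DvcConfig,
) -> float:
    """ZNCC of the subset at ``center`` in ``ref`` against the subset at
    ``center + offset`` in ``deformed``, over jointly-finite voxels.

    Returns NaN when fewer than ``min_valid_fraction`` of the subset voxels
    are jointly finite, or when either valid window has zero variance.
    """
    h = cfg.subset_half
    cz, cy, cx = center
    oz, oy, ox = offset
    for (c, o, n) in zip(center, offset, ref.shape):
        if c - h < 0 or c + h >= n or c + o - h < 0 or c + o + h >= n:
            raise GeometryError("subset window leaves the volume")
    r = ref.data[cz - h:cz + h + 1, cy - h:cy + h + 1, cx - h:cx + h + 1]
    d = deformed.data[cz + oz - h:cz + oz + h + 1, cy + oy - h:cy + oy + h + 1, cx + ox - h:cx + ox + h + 1]
    both = np.isfinite(r) & np.isfinite(d)
    n_valid = int(both.sum())
    if n_valid < cfg.min_valid_fraction * r.size or n_valid < 2:
        return float("nan")
    rv = r[both]
    dv = d[both]
    rv = rv - rv.mean()
    dv = dv - dv.mean()
    denom = np.sqrt((rv @ rv) * (dv @ dv))
    if denom == 0.0:
        return float("nan")
    return float((rv @ dv) / denom)


def search_integer(
    ref: Volume, deformed: Volume, center: tuple[int, int, int], cfg: DvcConfig,
) -> tuple[tuple[int, int, int], float]:
    """Exhaustive integer search over the cubic window; global argmax with
    ties broken by smallest offset norm, then lexicographic (z, y, x)."""
    s = cfg.search_radius_vox
    best: tuple[int, int, int] | None = None
    best_score = -2.0
    best_norm = np.inf
    for oz in range(-s, s + 1):
        for oy in range(-s, s + 1):
            for ox in range(-s, s + 1):
                score = correlate_subset(ref, deformed, center, (oz, oy, ox), cfg)
                if np.isnan(score):
                    continue
                nrm = oz * oz + oy * oy + ox * ox
                if score > best_score or (score == best_score and nrm < best_norm):
                    best_score = score
                    best_norm = nrm
                    best = (oz, oy, ox)
    if best is None:
        raise ValueError("all offsets invalid (insufficient valid voxels)")
    return best, best_score


def refine_subpixel(scores: np.ndarray) -> np.ndarray:
    """Separable parabolic peak interpolation on a 3x3x3 score
    neighborhood centered at the integer optimum.

    Returns the fractional correction (dz, dy, dx), each clamped to
    (-0.5, 0.5). A symmetric axis (equal flanking scores) yields 0.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (3, 3, 3):
        raise ParameterError("subpixel refinement needs a 3x3x3 score neighborhood")
    if not np.all(np.isfinite(scores[1, 1, 1])):
        raise ParameterError("center score must be finite")
    c = scores[1, 1, 1]
    out = np.zeros(3)
    flanks = [
        (scores[0, 1, 1], scores[2, 1, 1]),
        (scores[1, 0, 1], scores[1, 2, 1]),
        (scores[1, 1, 0], scores[1, 1, 2]),
    ]
    for i, (sm, sp) in enumerate(flanks):
        out[i] = _kernels._parabolic(sm, c, sp)
    return out


def run_dvc(ref: Volume, deformed: Volume, cfg: DvcConfig | None = None) -> DisplacementField:
    """Correlate every node of the grid: integer search then subpixel
    refinement. Nodes are independent; execution order never changes the
    result."""
    cfg = cfg or DvcConfig()
    if ref.shape != deformed.shape:
        raise GeometryError(f"volume shapes differ: {ref.shape} vs {deformed.shape}")
    axes = build_node_grid(ref, cfg)
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1).astype(np.int64)
    u, cc, status = _kernels.dvc_at_nodes(
        np.ascontiguousarray(ref.data, dtype=np.float64),
        np.ascontiguousarray(deformed.data, dtype=np.float64),
        nodes,
        cfg.subset_half,
        cfg.search_radius_vox,
        cfg.min_valid_fraction,
        cfg.cc_min,
        cfg.subpixel,
    )
    gshape = tuple(len(a) for a in axes)
    fld = DisplacementField(
        coords=axes,
        u=u.reshape(gshape + (3,)),
        cc=cc.reshape(gshape),
        status=status.reshape(gshape),
        voxel_size_um=ref.voxel_size_um,
        node_spacing_vox=cfg.node_spacing_vox,
    )
    fld.meta.update(config=cfg.__dict__.copy(), status_counts=fld.status_counts())
    return fld
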
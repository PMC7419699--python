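"""Volume and field I/O.

Volumes travel as TIFF (single multi-page file or a directory of numbered
slices; 8/16-bit integer or 32/64-bit float) or as MHD header + raw.
Slices are ordered ascending z; arrays are indexed (z, y, x). Derived
fields are written both as a CSV node/element table and as a legacy ASCII
VTK structured grid (one array per component) readable by ParaView.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dvc import STATUS_NAMES, DisplacementField
from .strain import COMPONENT_NAMES, StrainField
from .volume import ParameterError, Volume


class FormatError(ValueError):
    """File contents violate the expected layout."""


# ---------------------------------------------------------------- volumes

def read_volume(path: str | Path, voxel_size_um: float = 25.0) -> Volume:
    """Read a TIFF stack (file or directory of numbered slices) or an
    MHD+raw volume. Slice order = ascending z."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise FormatError(f"directory {path} holds no TIFF slices")
        arrays = [tifffile.imread(p) for p in slices]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise FormatError(f"mixed slice shapes in {path}: {sorted(shapes)}")
        data = np.stack(arrays, axis=0)
    elif path.suffix.lower() == ".mhd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
    else:
        data = tifffile.imread(path)
    if data.ndim == 2:
        raise FormatError(f"{path} holds a single 2D image, not a volume")
    return Volume(np.asarray(data, dtype=np.float64), voxel_size_um=voxel_size_um)


def write_volume(vol: Volume, path: str | Path, dtype: str | None = None) -> Path:
    """Write a volume as multi-page TIFF (default), a directory of
    numbered slices (if ``path`` has no suffix), or MHD+raw (.mhd).
    ``dtype=None`` preserves the in-memory float64 exactly."""
    path = Path(path)
    data = vol.data if dtype is None else vol.data.astype(dtype)
    if path.suffix.lower() == ".mhd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(data))
        s = vol.voxel_size_um / 1000.0
        img.SetSpacing((s, s, s))
        sitk.WriteImage(img, str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, data)
    else:
        path.mkdir(parents=True, exist_ok=True)
        ndigits = len(str(vol.shape[0] - 1))
        for i, sl in enumerate(data):
            tifffile.imwrite(path / f"slice_{i:0{ndigits}d}.tif", sl)
    return path


def write_sidecar(path: str | Path, payload: dict) -> Path:
    """JSON sidecar for provenance (phantom spec, warp, seeds)."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ----------------------------------------------------------------- fields

def _field_tables(field: DisplacementField | StrainField) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    cz, cy, cx = field.coords
    zz, yy, xx = np.meshgrid(cz, cy, cx, indexing="ij")
    vs = field.voxel_size_um
    cols: dict[str, np.ndarray] = {
        "z_vox": zz.ravel(), "y_vox": yy.ravel(), "x_vox": xx.ravel(),
        "z_um": zz.ravel() * vs, "y_um": yy.ravel() * vs, "x_um": xx.ravel() * vs,
    }
    arrays: dict[str, np.ndarray] = {}
    if isinstance(field, DisplacementField):
        for i, name in enumerate(("u_z", "u_y", "u_x")):
            cols[name] = field.u[..., i].ravel()
            arrays[name] = field.u[..., i]
        cols["cc"] = field.cc.ravel()
        arrays["cc"] = field.cc
        cols["status"] = np.array([STATUS_NAMES[s] for s in field.status.ravel()])
        arrays["status"] = field.status.astype(np.float64)
    elif isinstance(field, StrainField):
        for i, name in enumerate(COMPONENT_NAMES):
            cols[name] = field.components[..., i].ravel()
            arrays[name] = field.components[..., i]
        cols["vol_strain"] = field.volumetric.ravel()
        arrays["vol_strain"] = field.volumetric
        cols["max_shear"] = field.max_shear.ravel()
        arrays["max_shear"] = field.max_shear
        cols["status"] = field.status.ravel()
        arrays["status"] = field.status.astype(np.float64)
    else:
        raise ParameterError(f"unsupported field type {type(field)}")
    return pd.DataFrame(cols), arrays


def write_field(field: DisplacementField | StrainField, out_dir: str | Path, stem: str = "field") -> dict[str, Path]:
    """Write a field as (a) a CSV node/element table with coordinates in
    voxels and μm plus all components, and (b) a legacy ASCII VTK
    structured grid with one array per component."""
    if any(len(c) == 0 for c in field.coords):
        raise ParameterError("empty field")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df, arrays = _field_tables(field)
    csv_path = out_dir / f"{stem}.csv"
    df.to_csv(csv_path, index=False, float_format="%.17g")  # exact float64 round trip
    vtk_path = out_dir / f"{stem}.vtk"
    _write_vtk_structured(vtk_path, field.coords, arrays, field.voxel_size_um)
    return {"csv": csv_path, "vtk": vtk_path}


def _write_vtk_structured(
    path: Path, coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    arrays: dict[str, np.ndarray], voxel_size_um: float,
) -> None:
    cz, cy, cx = coords
    nz, ny, nx = len(cz), len(cy), len(cx)
    npts = nz * ny * nx
    lines = [
        "# vtk DataFile Version 3.0",
        "peridvc field (coordinates in um)",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"POINTS {npts} float",
    ]
    # VTK point order: x fastest, z slowest
    for z in cz:
        for y in cy:
            for x in cx:
                lines.append(f"{x * voxel_size_um:.6g} {y * voxel_size_um:.6g} {z * voxel_size_um:.6g}")
    lines.append(f"POINT_DATA {npts}")
    for name, arr in arrays.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9g}" for v in arr.ravel())  # C order == x fastest
    path.write_text("\n".join(lines) + "\n")


def read_field_csv(path: str | Path) -> pd.DataFrame:
    """Read back a field table written by :func:`write_field`."""
    return pd.read_csv(path, float_precision="round_trip")


def read_displacement_field(path: str | Path, voxel_size_um: float = 25.0) -> DisplacementField:
    """Reconstruct a DisplacementField from its CSV table (regular grid)."""
    df = pd.read_csv(path, float_precision="round_trip")
    coords = tuple(np.unique(df[c].to_numpy()) for c in ("z_vox", "y_vox", "x_vox"))
    gshape = tuple(len(c) for c in coords)
    n = int(np.prod(gshape))
    if len(df) != n:
        raise FormatError(f"table is not a full regular grid: {len(df)} rows vs {gshape}")
    df = df.sort_values(["z_vox", "y_vox", "x_vox"], kind="mergesort")
    u = np.stack([df[c].to_numpy() for c in ("u_z", "u_y", "u_x")], axis=-1).reshape(gshape + (3,))
    cc = df["cc"].to_numpy().reshape(gshape)
    code = {name: c for c, name in STATUS_NAMES.items()}
    status = np.array([code[s] for s in df["status"]], dtype=np.int8).reshape(gshape)
    spacing = int(coords[0][1] - coords[0][0]) if len(coords[0]) > 1 else 1
    return DisplacementField(
        coords=coords, u=u, cc=cc, status=status,
        voxel_size_um=voxel_size_um, node_spacing_vox=spacing,
    )
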
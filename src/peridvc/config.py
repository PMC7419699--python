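"""Run configuration: TOML parsing with strict key validation.

Defaults reproduce the published analysis settings: node spacing 4 /
subset 17, image median radius 4, displacement median radius 1, a
cylindrical ROI of 0.5 mm radial extent over a 2.2 mm thread span, 25 μm
voxels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .dvc import DvcConfig
from .phantom import PhantomSpec, WarpSpec
from .volume import ParameterError


@dataclass
class RunConfig:
    phantom: Optional[PhantomSpec] = None
    warp: Optional[WarpSpec] = None
    dvc: DvcConfig = field(default_factory=DvcConfig)
    pre_median_radius_vox: int = 4
    post_median_radius_nodes: int = 1
    roi_radial_um: float = 500.0
    roi_axial_um: float = 2200.0
    noise_sigma_fraction: float = 0.0   # of bone-background contrast
    voxel_size_um: float = 25.0
    seed: int = 0
    out_dir: Path = Path("peridvc_out")
    ref_path: Optional[Path] = None     # real-scan inputs, alternative to phantom
    def_path: Optional[Path] = None
    t_background: Optional[float] = None
    t_screw: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pre_median_radius_vox < 0 or self.post_median_radius_nodes < 0:
            raise ParameterError("median radii must be >= 0")
        if self.roi_radial_um <= 0 or self.roi_axial_um <= 0:
            raise ParameterError("ROI extents must be > 0")
        if self.noise_sigma_fraction < 0:
            raise ParameterError("noise_sigma_fraction must be >= 0")
        if self.phantom is None and (self.ref_path is None or self.def_path is None):
            # default demo phantom keeps an empty config runnable
            self.phantom = PhantomSpec(seed=self.seed)
        self.out_dir = Path(self.out_dir)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(config_dict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def config_dict(cfg: RunConfig) -> dict:
    out: dict = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if dataclasses.is_dataclass(v):
            d = dataclasses.asdict(v)
            for k, sub in d.items():
                if hasattr(sub, "tolist"):
                    d[k] = sub.tolist()
            out[f.name] = d
        elif isinstance(v, Path):
            out[f.name] = str(v)
        else:
            out[f.name] = v
    return out


_SECTIONS = {
    "phantom": PhantomSpec,
    "warp": WarpSpec,
    "dvc": DvcConfig,
}
_TOP_KEYS = {
    "pre_median_radius_vox", "post_median_radius_nodes", "roi_radial_um",
    "roi_axial_um", "noise_sigma_fraction", "voxel_size_um", "seed", "out_dir",
    "ref_path", "def_path", "t_background", "t_screw",
}


def parse_config(path: str | Path) -> RunConfig:
    """Parse a TOML run configuration; unknown keys are an error, absent
    keys take the published defaults."""
    raw = tomllib.loads(Path(path).read_text())
    kwargs: dict = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            body = raw.pop(section)
            if not isinstance(body, dict):
                raise ParameterError(f"[{section}] must be a table")
            allowed = {f.name for f in dataclasses.fields(cls)}
            unknown = set(body) - allowed
            if unknown:
                raise ParameterError(f"unknown keys in [{section}]: {sorted(unknown)}")
            if "dims" in body:
                body["dims"] = tuple(body["dims"])
            if "translation_vox" in body and body["translation_vox"] is not None:
                body["translation_vox"] = tuple(body["translation_vox"])
            kwargs[section] = cls(**body)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs.update(raw)
    for key in ("out_dir", "ref_path", "def_path"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = Path(kwargs[key])
    return RunConfig(**kwargs)
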
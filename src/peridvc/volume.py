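"""Core in-memory container for 3D tomographic volumes.

Axis convention, used everywhere in this package: arrays are indexed
``(z, y, x)``, 0-based, with *z* the screw / pullout axis. Intensities are
dimensionless gray values; coordinates are kept in voxels internally and
converted to micrometres only at reporting boundaries. Masked (excluded)
voxels carry NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


class GeometryError(ValueError):
    """A geometric construction does not fit inside the volume."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. constant image)."""


@dataclass
class Volume:
    """A 3D scalar intensity grid with a physical voxel size.

    Parameters
    ----------
    data:
        3D float array indexed (z, y, x). NaN marks masked voxels.
    voxel_size_um:
        Physical edge length of a (cubic) voxel in micrometres.
    meta:
        Free-form provenance dictionary (seeds, warp parameters, ...).
    """

    data: np.ndarray
    voxel_size_um: float = 25.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ParameterError(f"volume must be 3D, got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise ParameterError(f"each axis needs >= 2 voxels, got {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise ParameterError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy(), meta=dict(self.meta))

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data, meta=dict(self.meta))
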
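"""Core voxel-volume container and coordinate conventions.

Conventions used throughout the package (defined here, nowhere else):

* Volume arrays are stored ``(z, y, x)`` with the cone/stack axis along ``z``.
* Voxel centers sit at integer indices; physical position in mm is
  ``index * voxel_size`` (isotropic voxels).
* 3D physical points are ``(x, y, z)`` in mm; 2D image points are
  ``(x, y) = (column, row)`` in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelVolume:
    """A 3D scalar grid with a physical voxel size.

    Parameters
    ----------
    data:
        Array of shape ``(nz, ny, nx)``; promoted to float32 on construction.
    voxel_size:
        Isotropic voxel edge length in mm; must be positive.
    """

    data: np.ndarray
    voxel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D (z, y, x), got shape {self.data.shape}")
        if self.data.dtype != np.float32:
            self.data = self.data.astype(np.float32)
        if not np.isfinite(self.voxel_size) or self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in mm spanned by voxel centers."""
        nz, ny, nx = self.data.shape
        return ((nx - 1) * self.voxel_size, (ny - 1) * self.voxel_size, (nz - 1) * self.voxel_size)

    def slice(self, k: int) -> np.ndarray:
        return self.data[k]
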
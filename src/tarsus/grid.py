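"""Core volumetric containers shared across the pipeline.

All grids use 0-based voxel indices in (z, y, x) axis order with isotropic
spacing; physical position = index * spacing.  Images carry Hounsfield-unit
calibrated scalars, label maps carry non-negative integers with 0 reserved
for background.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelImage", "BinaryMask", "LabelMap", "DEFAULT_SPACING_UM"]

#: Default isotropic voxel edge length in micrometres.
DEFAULT_SPACING_UM = 17.5


def _check_grid(values: np.ndarray, spacing_um: float) -> None:
    if values.ndim != 3:
        raise ValueError(f"expected a 3D grid, got {values.ndim}D")
    if values.size == 0:
        raise ValueError("grid is empty")
    if not np.isfinite(spacing_um) or spacing_um <= 0:
        raise ValueError(f"spacing must be positive and finite, got {spacing_um}")


@dataclass
class VoxelImage:
    """A 3D scalar grid in HU with isotropic voxel spacing (µm)."""

    values: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_grid(self.values, self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        # µm³ → mm³ via a single division keeps 17.5³ = 5359.375 exact
        return self.spacing_um**3 / 1e9


@dataclass
class BinaryMask:
    """Boolean grid marking bone voxels; shape matches its source image."""

    values: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        _check_grid(self.values, self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class LabelMap:
    """Integer-labeled partition of a bone mask; 0 is background."""

    values: np.ndarray
    spacing_um: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError(f"label map must be integer-typed, got {self.values.dtype}")
        if self.values.min(initial=0) < 0:
            raise ValueError("label map contains negative labels")
        _check_grid(self.values, self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def labels(self) -> np.ndarray:
        """Sorted array of positive labels present in the map."""
        u = np.unique(self.values)
        return u[u > 0]

    def voxel_counts(self) -> dict[int, int]:
        """Voxel count per positive label."""
        u, c = np.unique(self.values, return_counts=True)
        return {int(label): int(n) for label, n in zip(u, c) if label > 0}

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_um**3 / 1e9
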
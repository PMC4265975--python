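"""Regular Cartesian grids in the device frame.

The device frame follows the therapy-hardware convention: x is the
left-right (LR) axis, y the head-foot (HF) axis, and z the beam axis
pointing from the transducer toward its natural focus.  All public
lengths are millimetres; physics modules convert to SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid3D:
    """Axis-aligned voxel grid: ``origin_mm`` is the centre of voxel (0,0,0)."""

    origin_mm: tuple[float, float, float]
    spacing_mm: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("shape entries must be >= 1")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin_mm[i] + self.spacing_mm * np.arange(self.shape[i])
            for i in range(3)
        )

    def points_mm(self) -> np.ndarray:
        """All voxel centres as an (N, 3) array in C order."""
        ax = self.axes_mm()
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def index_of(self, point_mm) -> tuple[int, int, int]:
        """Nearest voxel index of a point (may lie outside the grid)."""
        p = np.asarray(point_mm, dtype=float)
        idx = np.rint((p - np.asarray(self.origin_mm)) / self.spacing_mm)
        return tuple(int(i) for i in idx)

    def contains(self, point_mm) -> bool:
        i, j, k = self.index_of(point_mm)
        return 0 <= i < self.shape[0] and 0 <= j < self.shape[1] and 0 <= k < self.shape[2]

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel coordinates of world points, shape (N, 3)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - np.asarray(self.origin_mm)) / self.spacing_mm


def centered_grid(extent_mm: tuple[float, float, float], spacing_mm: float,
                  center_mm=(0.0, 0.0, 0.0)) -> Grid3D:
    """Grid symmetric about ``center_mm`` covering at least ``extent_mm``."""
    shape = tuple(int(np.floor(e / spacing_mm)) + 1 for e in extent_mm)
    origin = tuple(
        float(c - spacing_mm * (n - 1) / 2.0) for c, n in zip(center_mm, shape)
    )
    return Grid3D(origin_mm=origin, spacing_mm=float(spacing_mm), shape=shape)
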
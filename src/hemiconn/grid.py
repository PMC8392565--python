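"""Voxel lattice geometry shared by every volume in a pipeline run.

All volumes are held in RAS+ orientation: the first array axis increases
toward the anatomical right (+x world), so "left hemisphere" always means
negative world x.  A single :class:`ImageGrid` is attached to masks, BOLD
runs and phantoms alike; operations that combine volumes first check that
their grids are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ImageGrid:
    """Regular isotropic voxel lattice in world (mm) coordinates, RAS+.

    Parameters
    ----------
    dims:
        Number of voxels along x, y, z.
    voxel_size:
        Isotropic voxel edge length in mm.
    origin:
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def symmetric(cls, dims: tuple[int, int, int], voxel_size: float = 2.5) -> "ImageGrid":
        """Grid whose voxel centers are symmetric about world (0, 0, 0).

        With odd dims an entire voxel plane sits exactly at x = 0; with even
        dims the midsagittal plane falls between two voxel columns.
        """
        origin = tuple(-(d - 1) / 2.0 * voxel_size for d in dims)
        return cls(tuple(dims), float(voxel_size), origin)  # type: ignore[arg-type]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (RAS+, axis-aligned)."""
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.voxel_size * np.arange(self.dims[axis])

    def coordinate_volumes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World x, y, z of every voxel center, broadcast to full volumes."""
        x, y, z = (self.axis_coords(a) for a in range(3))
        return np.meshgrid(x, y, z, indexing="ij")

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to (fractional) voxel indices."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / self.voxel_size

    @property
    def is_x_symmetric(self) -> bool:
        """True when the x voxel-center coordinates are symmetric about 0."""
        x = self.axis_coords(0)
        return bool(np.allclose(x, -x[::-1], atol=1e-9 * self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"ImageGrid(dims={self.dims}, voxel={self.voxel_size}mm, origin={self.origin})"
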
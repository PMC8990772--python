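"""Per-voxel FA + principal diffusion direction on a regular grid.

The tracker consumes this container directly: no diffusion-weighted signal
or tensor model is involved.  World coordinates are RAS millimetres; voxel
indices are 0-based; the affine maps voxel index -> world mm.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiffusionField:
    """FA scalar volume plus a unit principal-direction vector per voxel.

    Parameters
    ----------
    fa : (nx, ny, nz) float array in [0, 1]
    directions : (nx, ny, nz, 3) float array, unit vectors (sign arbitrary:
        diffusion is axial, so d and -d are equivalent)
    affine : (4, 4) voxel-index -> world-mm map
    """

    fa: np.ndarray
    directions: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.fa = np.asarray(self.fa, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.fa.ndim != 3:
            raise ValueError("fa must be a 3D volume")
        if self.directions.shape != self.fa.shape + (3,):
            raise ValueError("directions must be fa.shape + (3,)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        self._inv_affine = np.linalg.inv(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fa.shape

    @property
    def voxel_volume(self) -> float:
        """mm^3 per voxel (|det| of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def validate(self, atol: float = 1e-6) -> None:
        """Raise if FA leaves [0,1] or any stored direction is non-unit."""
        if self.fa.min() < -atol or self.fa.max() > 1 + atol:
            raise ValueError("FA values outside [0, 1]")
        norms = np.linalg.norm(self.directions, axis=-1)
        if not np.allclose(norms, 1.0, atol=atol):
            raise ValueError("directions are not unit-norm")

    # -- coordinate transforms ---------------------------------------------

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates for world-mm points."""
        p = np.atleast_2d(points)
        v = p @ self._inv_affine[:3, :3].T + self._inv_affine[:3, 3]
        return v if np.ndim(points) > 1 else v[0]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        i = np.atleast_2d(idx).astype(float)
        w = i @ self.affine[:3, :3].T + self.affine[:3, 3]
        return w if np.ndim(idx) > 1 else w[0]

    def voxel_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel integer index for world points (may be out of grid)."""
        return np.rint(self.world_to_voxel(points)).astype(np.int64)

    def contains(self, point: np.ndarray) -> bool:
        """True if the world point falls in some voxel (nearest-index in grid)."""
        i = np.rint(self.world_to_voxel(point))
        return bool(np.all(i >= 0) and np.all(i < np.array(self.shape)))

    # -- sampling -----------------------------------------------------------

    def fa_at(self, point: np.ndarray, interpolation: str = "nearest") -> float:
        """FA at a world point; nearest voxel (default) or trilinear."""
        c = self.world_to_voxel(point)
        if interpolation == "nearest":
            i = np.rint(c).astype(int)
            if np.any(i < 0) or np.any(i >= np.array(self.shape)):
                return 0.0
            return float(self.fa[tuple(i)])
        if interpolation == "linear":
            from scipy.ndimage import map_coordinates

            return float(map_coordinates(self.fa, np.asarray(c)[:, None],
                                         order=1, mode="constant", cval=0.0)[0])
        raise ValueError(f"unknown interpolation {interpolation!r}")

    def direction_at(self, point: np.ndarray) -> np.ndarray | None:
        """Unit principal direction of the nearest voxel, or None outside the grid."""
        i = np.rint(self.world_to_voxel(point)).astype(int)
        if np.any(i < 0) or np.any(i >= np.array(self.shape)):
            return None
        return self.directions[tuple(i)]

    def seed_points(self, fa_threshold: float) -> np.ndarray:
        """World-mm centers of all voxels with FA >= threshold."""
        idx = np.argwhere(self.fa >= fa_threshold)
        if len(idx) == 0:
            return np.empty((0, 3))
        return self.voxel_to_world(idx)
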
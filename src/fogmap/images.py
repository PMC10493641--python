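"""Minimal volumetric containers: a scalar field plus its voxel->mm affine.

Everything downstream (conductivity volumes, potentials, e-fields, VTA
masks, atlas labels, statistical maps) is an :class:`Image3D`.  World
coordinates are millimetres in a RAS-oriented analysis space; voxel
indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Image3D:
    """A 3-D (or 4-D) array with an affine mapping voxel indices to mm."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.data.ndim not in (3, 4):
            raise ValueError("Image3D holds 3-D or 4-D arrays")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm along the three spatial axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (ijk @ self.affine[:3, :3].T) + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (mm)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (xyz @ inv[:3, :3].T) + inv[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest voxel index of world points; may fall outside the grid."""
        return np.rint(self.world_to_voxel(xyz)).astype(int)

    def contains_index(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        shp = np.asarray(self.data.shape[:3])
        return np.all((ijk >= 0) & (ijk < shp), axis=1)

    def voxel_centres(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world coordinates of all voxel centres."""
        nx, ny, nz = self.data.shape[:3]
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.voxel_to_world(ijk).reshape(nx, ny, nz, 3)

    def like(self, data: np.ndarray) -> "Image3D":
        """New image on this grid holding ``data``."""
        if data.shape[:3] != self.data.shape[:3]:
            raise ValueError("shape mismatch with template grid")
        return Image3D(data, self.affine.copy())

    def same_grid(self, other: "Image3D", tol: float = 1e-6) -> bool:
        return self.data.shape[:3] == other.data.shape[:3] and np.allclose(
            self.affine, other.affine, atol=tol
        )


def require_same_grid(a: Image3D, b: Image3D, what: str = "images") -> None:
    if not a.same_grid(b):
        raise ValueError(f"{what} are not on the same grid (shape/affine mismatch)")


def make_grid(shape: tuple, voxel_size: float, origin: tuple) -> Image3D:
    """An empty float grid with an axis-aligned RAS affine.

    ``origin`` is the world coordinate (mm) of voxel (0, 0, 0).
    """
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
    affine[:3, 3] = origin
    return Image3D(np.zeros(shape, dtype=float), affine)
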
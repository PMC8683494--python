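"""Voxel grid geometry shared by all volumetric data.

Conventions: world coordinates are millimetres, voxel indices are 0-based,
and a voxel's world position refers to its *center* (``affine @ [i, j, k, 1]``).
The package-wide axis order is (x, y, z) = (left-right, posterior-anterior,
inferior-superior), matching the RAS+ orientation nibabel uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """A regular 3-D voxel lattice with a voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @classmethod
    def from_spacing(
        cls,
        shape: tuple[int, int, int],
        voxel_size: float | tuple[float, float, float],
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "VolumeGrid":
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        if np.any(vs <= 0):
            raise ValueError("voxel sizes must be positive")
        affine = np.eye(4)
        affine[:3, :3] = np.diag(vs)
        affine[:3, 3] = origin
        return cls(tuple(shape), affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of one voxel along each grid axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis.

        Valid for axis-aligned (diagonal) affines, which is all the phantom
        generator produces; raises otherwise.
        """
        lin = self.affine[:3, :3]
        if not np.allclose(lin, np.diag(np.diag(lin))):
            raise ValueError("axis_coords requires an axis-aligned affine")
        return tuple(
            self.affine[a, 3] + np.arange(self.shape[a]) * lin[a, a]
            for a in range(3)
        )

    def contains_world(self, xyz: np.ndarray) -> np.ndarray:
        """True where world points fall inside the voxel lattice."""
        v = self.world_to_voxel(xyz)
        lo = v >= -0.5
        hi = v <= np.asarray(self.shape) - 0.5
        return np.all(lo & hi, axis=1)

    def to_nifti(self, data: np.ndarray) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(data), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "VolumeGrid":
        return cls(tuple(img.shape[:3]), np.asarray(img.affine))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.shape, self.affine.tobytes()))
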
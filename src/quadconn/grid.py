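"""Voxel grid geometry: shape, voxel size and the voxel-index -> world-mm affine.

All voxel indices in the package are 0-based (i, j, k) triples; world
coordinates are millimetres obtained through the NIfTI-style 4x4 affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a volumetric image.

    Parameters
    ----------
    shape:
        Number of voxels along each axis (all >= 1).
    voxel_size:
        Voxel edge lengths in mm (all > 0).
    affine:
        4x4 voxel-index -> world-mm transform. Defaults to a diagonal
        scaling by ``voxel_size`` with the origin at voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ConfigError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(voxel_size) != 3 or any(v <= 0 for v in voxel_size):
            raise ConfigError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel_size)
        if self.affine is None:
            aff = np.diag(list(voxel_size) + [1.0])
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ConfigError("affine must be 4x4")
            if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
                raise ConfigError("affine must be invertible")
        aff = aff.copy()
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    # -- coordinate transforms -------------------------------------------------

    def voxel_to_world(self, idx) -> np.ndarray:
        """Map voxel indices (…, 3) to world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz) -> np.ndarray:
        """Map world mm coordinates to continuous voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_to_index(self, xyz) -> np.ndarray:
        """Map world mm coordinates to the nearest integer voxel index."""
        return np.rint(self.world_to_voxel(xyz)).astype(int)

    def contains(self, idx) -> np.ndarray:
        """Boolean mask of which integer indices (…, 3) fall inside the grid."""
        idx = np.asarray(idx)
        lo = (idx >= 0).all(axis=-1)
        hi = (idx < np.asarray(self.shape)).all(axis=-1)
        return lo & hi

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=tol)
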
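"""Scalar image volumes on a regular grid with a voxel-to-world affine.

``ImageVolume`` is the container every stage of the pipeline exchanges.  The
convention is the NIfTI one: ``world = affine @ [i, j, k, 1]`` with voxel
*centers* at integer indices.  All world coordinates are millimetres.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import ConfigurationError

__all__ = ["ImageVolume", "LabelVolume"]


@dataclass
class ImageVolume:
    """A 3-D scalar grid plus its voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError(f"volume must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ConfigurationError("affine must be 4x4")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Length of the voxel edges along each axis (mm)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        one = idx.ndim == 1
        out = np.atleast_2d(idx) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if one else out

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        one = xyz.ndim == 1
        inv = np.linalg.inv(self.affine)
        out = np.atleast_2d(xyz) @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if one else out

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        ).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    # -- I/O ----------------------------------------------------------------
    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(np.asanyarray(self.data), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), np.asarray(img.affine))

    def copy(self) -> "ImageVolume":
        return type(self)(self.data.copy(), self.affine.copy())


class LabelVolume(ImageVolume):
    """Integer/boolean tissue label on the same grid conventions."""

    @property
    def mask(self) -> np.ndarray:
        return np.asarray(self.data) > 0
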
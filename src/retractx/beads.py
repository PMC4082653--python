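"""Fiducial bead tables.

Beads are small high-intensity spheres embedded in the phantom; their exact
centers (continuous world mm, never voxelized) are the ground truth the
evaluation metrics run on.  A ``BeadSet`` is a thin wrapper over a DataFrame
with columns ``id, x, y, z, region`` plus the name of the coordinate space
it lives in (pre-retraction / post-retraction / model-updated).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PairingError

__all__ = ["BeadSet"]


@dataclass
class BeadSet:
    table: pd.DataFrame
    space: str = "pre-retraction"

    def __post_init__(self):
        required = {"id", "x", "y", "z", "region"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"bead table missing columns {sorted(missing)}")
        if self.table["id"].duplicated().any():
            raise ConfigurationError("bead ids must be unique")
        coords = self.table[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ConfigurationError("bead coordinates must be finite")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_centers(cls, centers, regions=None, space="pre-retraction", ids=None) -> "BeadSet":
        centers = np.atleast_2d(np.asarray(centers, dtype=float)).reshape(-1, 3)
        n = len(centers)
        if ids is None:
            ids = np.arange(1, n + 1)
        if regions is None:
            regions = ["unassigned"] * n
        df = pd.DataFrame(
            {"id": ids, "x": centers[:, 0], "y": centers[:, 1], "z": centers[:, 2],
             "region": regions}
        )
        return cls(df, space)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def centers(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(float)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def regions(self) -> np.ndarray:
        return self.table["region"].to_numpy()

    def with_centers(self, centers: np.ndarray, space: str) -> "BeadSet":
        """Same beads, new coordinates (e.g. after applying a displacement field)."""
        centers = np.asarray(centers, dtype=float)
        if centers.shape != (len(self), 3):
            raise ConfigurationError("centers shape must match bead count")
        df = self.table.copy()
        df[["x", "y", "z"]] = centers
        return BeadSet(df, space)

    def aligned_with(self, other: "BeadSet") -> tuple[np.ndarray, np.ndarray]:
        """Centers of self and other matched by id; raises on mismatch."""
        if len(self) != len(other) or not np.array_equal(
            np.sort(self.ids), np.sort(other.ids)
        ):
            raise PairingError("bead id sets differ between tables")
        a = self.table.sort_values("id")[["x", "y", "z"]].to_numpy(float)
        b = other.table.sort_values("id")[["x", "y", "z"]].to_numpy(float)
        return a, b

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, space="pre-retraction") -> "BeadSet":
        return cls(pd.read_csv(path), space)
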
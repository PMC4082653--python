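"""Point clouds (mm) with optional per-point normals, displacements and labels.

I/O: CSV (``x,y,z[,nx,ny,nz]``) and ASCII PLY.  PLY here is deliberately
minimal — vertices with optional ``nx,ny,nz`` properties — which is all the
scanner/probe round trip needs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["PointCloud"]


@dataclass
class PointCloud:
    points: np.ndarray
    normals: np.ndarray | None = None
    displacements: np.ndarray | None = None
    labels: np.ndarray | None = None   # e.g. source face tag per point

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ConfigurationError("points must be (n, 3)")
        for name in ("normals", "displacements"):
            v = getattr(self, name)
            if v is not None:
                v = np.atleast_2d(np.asarray(v, dtype=float))
                if v.shape != self.points.shape:
                    raise ConfigurationError(f"{name} must match points shape")
                setattr(self, name, v)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.points):
                raise ConfigurationError("labels must match point count")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, idx) -> "PointCloud":
        return PointCloud(
            self.points[idx],
            None if self.normals is None else self.normals[idx],
            None if self.displacements is None else self.displacements[idx],
            None if self.labels is None else self.labels[idx],
        )

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.points @ R.T + t,
            None if self.normals is None else self.normals @ R.T,
            self.displacements,
            self.labels,
        )

    @staticmethod
    def concatenate(clouds) -> "PointCloud":
        def cat(attr):
            vals = [getattr(c, attr) for c in clouds]
            return None if any(v is None for v in vals) else np.concatenate(vals)

        return PointCloud(
            np.concatenate([c.points for c in clouds]),
            cat("normals"), cat("displacements"), cat("labels"),
        )

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        cols = {"x": self.points[:, 0], "y": self.points[:, 1], "z": self.points[:, 2]}
        if self.normals is not None:
            cols.update(nx=self.normals[:, 0], ny=self.normals[:, 1], nz=self.normals[:, 2])
        if self.displacements is not None:
            cols.update(ux=self.displacements[:, 0], uy=self.displacements[:, 1],
                        uz=self.displacements[:, 2])
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PointCloud":
        df = pd.read_csv(path)
        pts = df[["x", "y", "z"]].to_numpy(float)
        nrm = df[["nx", "ny", "nz"]].to_numpy(float) if "nx" in df else None
        dis = df[["ux", "uy", "uz"]].to_numpy(float) if "ux" in df else None
        return cls(pts, nrm, dis)

    def to_ply(self, path) -> None:
        has_n = self.normals is not None
        props = ["property float x", "property float y", "property float z"]
        if has_n:
            props += ["property float nx", "property float ny", "property float nz"]
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(self)}\n")
            fh.write("\n".join(props) + "\nend_header\n")
            data = self.points if not has_n else np.hstack([self.points, self.normals])
            np.savetxt(fh, data, fmt="%.8g")

    @classmethod
    def from_ply(cls, path) -> "PointCloud":
        with open(path) as fh:
            line = fh.readline().strip()
            if line != "ply":
                raise ConfigurationError(f"{path} is not a PLY file")
            n_vert, props = 0, []
            while True:
                line = fh.readline().strip()
                if line.startswith("element vertex"):
                    n_vert = int(line.split()[-1])
                elif line.startswith("property"):
                    props.append(line.split()[-1])
                elif line == "end_header":
                    break
                elif line.startswith("format") and "ascii" not in line:
                    raise ConfigurationError("only ascii PLY is supported")
            data = np.loadtxt(fh, max_rows=n_vert, ndmin=2)
        cols = {p: data[:, i] for i, p in enumerate(props)}
        pts = np.stack([cols["x"], cols["y"], cols["z"]], axis=1)
        nrm = (np.stack([cols["nx"], cols["ny"], cols["nz"]], axis=1)
               if "nx" in cols else None)
        return cls(pts, nrm)
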
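r"""Planar crack geometry and its two level sets.

The retraction corridor is modeled as a planar rectangle embedded in the
tissue: the *mouth* edge lies on (or above) the cortical surface and the
opposite *front* edge is the interior crack tip line.  Two signed level sets
describe any point relative to the crack:

* ``psi`` — signed distance to the crack plane, positive along the outward
  normal ``e_n``;
* ``phi`` — signed in-plane distance past the crack front, negative over the
  cracked (open) region and zero exactly on the front line.

A point is *on the crack* iff ``psi == 0``, ``phi <= 0`` and it lies within
the rectangle laterally.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = [
    "CrackGeometry",
    "level_sets",
    "crack_coords",
    "heaviside",
    "front_polar",
    "crack_from_probe",
    "fit_plane",
]

_UNIT_TOL = 1e-12


@dataclass(frozen=True)
class CrackGeometry:
    """Planar rectangular crack.

    Parameters
    ----------
    origin
        Mouth-center point on the plane (mm); the in-plane depth coordinate
        is zero here and increases toward the front.
    normal
        Outward unit normal ``e_n`` of the crack plane.
    depth_dir
        Unit in-plane direction from mouth to front.
    width
        Full lateral extent of the rectangle (mm), centered on ``origin``.
    depth
        Mouth-to-front distance (mm); the crack front is the line
        ``origin + depth * depth_dir + span(width_dir)``.
    """

    origin: tuple
    normal: tuple
    depth_dir: tuple
    width: float
    depth: float

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        d = np.asarray(self.depth_dir, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise GeometryError("crack normal must be a unit vector")
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise GeometryError("depth_dir must be a unit vector")
        if abs(n @ d) > 1e-9:
            raise GeometryError("depth_dir must lie in the crack plane")
        if not (self.width > 0 and self.depth > 0):
            raise GeometryError("width and depth must be positive")
        object.__setattr__(self, "origin", tuple(o))
        object.__setattr__(self, "normal", tuple(n / np.linalg.norm(n)))
        object.__setattr__(self, "depth_dir", tuple(d / np.linalg.norm(d)))

    # cached ndarray views -------------------------------------------------
    @property
    def o(self) -> np.ndarray:
        return np.asarray(self.origin)

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.normal)

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.depth_dir)

    @property
    def w(self) -> np.ndarray:
        """Unit lateral (width) direction, ``n x depth_dir``."""
        return np.cross(self.n, self.d)

    @property
    def front_point(self) -> np.ndarray:
        """Center of the crack-front line."""
        return self.o + self.depth * self.d

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "normal": list(self.normal),
            "depth_dir": list(self.depth_dir),
            "width": float(self.width),
            "depth": float(self.depth),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrackGeometry":
        return cls(d["origin"], d["normal"], d["depth_dir"], d["width"], d["depth"])


def crack_coords(points: np.ndarray, crack: CrackGeometry):
    """Return ``(psi, ww, dd)`` crack-local coordinates of world ``points``.

    ``psi`` is the signed plane distance, ``ww`` the lateral in-plane
    coordinate (0 on the mouth-center axis) and ``dd`` the in-plane depth
    coordinate (0 at the mouth, ``crack.depth`` on the front).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float)) - crack.o
    return p @ crack.n, p @ crack.w, p @ crack.d


def level_sets(points: np.ndarray, crack: CrackGeometry):
    """Level-set pair ``(psi, phi)`` for each point (both mm, signed)."""
    psi, _, dd = crack_coords(points, crack)
    return psi, dd - crack.depth


def heaviside(points: np.ndarray, crack: CrackGeometry) -> np.ndarray:
    """Generalized step of the plane distance: +1 where ``psi >= 0``, else -1.

    The tie at ``psi == 0`` resolves to +1 (toward ``e_n``) by convention.
    """
    psi, _ = level_sets(points, crack)
    return np.where(psi >= 0.0, 1.0, -1.0)


def front_polar(points: np.ndarray, crack: CrackGeometry, side: np.ndarray | None = None):
    """Polar coordinates ``(r, theta)`` around the crack front.

    The frame lives in the plane normal to the front line: ``theta = 0`` on
    the crack-plane extension ahead of the front and ``theta = +-pi`` on the
    crack faces.  ``side`` (+-1) disambiguates theta for points exactly on
    the open crack (``psi == 0``, behind the front).
    """
    psi, phi = level_sets(points, crack)
    r = np.hypot(phi, psi)
    theta = np.arctan2(psi, phi)
    if side is not None:
        on_crack = (psi == 0.0) & (phi < 0.0)
        theta = np.where(on_crack, np.asarray(side, dtype=float) * np.pi, theta)
    return r, theta


def fit_plane(points: np.ndarray):
    """Least-squares plane through ``points`` -> ``(centroid, unit normal)``.

    Raises :class:`GeometryError` for fewer than 3 or collinear points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise GeometryError("plane fit needs at least 3 points")
    c = pts.mean(axis=0)
    _, s, vh = np.linalg.svd(pts - c)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise GeometryError("points are collinear; plane is undetermined")
    return c, vh[2]


def crack_from_probe(
    probe_points: np.ndarray,
    width: float,
    depth: float,
    depth_hint=(0.0, 0.0, -1.0),
    normal_hint=None,
    mouth_point=None,
) -> CrackGeometry:
    """Build a :class:`CrackGeometry` from probe-digitized in-plane points.

    The plane is a least-squares fit; ``depth_hint`` (a world direction,
    default inferior) is projected into the plane to orient the depth axis,
    and ``normal_hint`` fixes the sign of the normal.  ``mouth_point``
    overrides the mouth center (default: the most anti-depth probe point
    projected onto the fitted plane, centered laterally).
    """
    pts = np.atleast_2d(np.asarray(probe_points, dtype=float))
    c, n = fit_plane(pts)
    if normal_hint is not None and n @ np.asarray(normal_hint, dtype=float) < 0:
        n = -n
    hint = np.asarray(depth_hint, dtype=float)
    d = hint - (hint @ n) * n
    nrm = np.linalg.norm(d)
    if nrm < 1e-9:
        raise GeometryError("depth_hint is parallel to the plane normal")
    d = d / nrm
    if mouth_point is None:
        # place the mouth at the shallowest probe point, laterally centered
        rel = pts - c
        dd = rel @ d
        w = np.cross(n, d)
        mouth_point = c + dd.min() * d + (rel @ w).mean() * w
    else:
        mouth_point = np.asarray(mouth_point, dtype=float)
        mouth_point = mouth_point - ((mouth_point - c) @ n) * n
    return CrackGeometry(tuple(mouth_point), tuple(n), tuple(d), width, depth)
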
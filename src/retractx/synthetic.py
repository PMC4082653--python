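"""Synthetic phantom generator: every input the correction pipeline needs.

The physical experiment this emulates is a brain-shaped PVA-C phantom with
embedded steel beads, retracted along the inter-hemispheric fissure plane and
CT-scanned before and after.  Here the phantom is a smoothed ellipsoid, the
"true" retraction is an analytic crack-opening displacement field with known
parameters, the post-retraction scan is the pre volume resampled through that
field (with the opened gap filled with background), and the scanner/probe
acquisitions are noisy, partially occluded samplings of the displaced
retractor surfaces.  Everything is seeded and bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .beads import BeadSet
from .cloud import PointCloud
from .crack import CrackGeometry, crack_coords
from .errors import BoundsError, GeometryError, SamplingError, SizingError
from .volume import ImageVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "BeadZone",
    "GroundTruthField",
    "generate_phantom_volume",
    "analytic_retraction_field",
    "apply_field_to_volume",
    "simulate_lrs_cloud",
    "simulate_probe_points",
]


@dataclass(frozen=True)
class BeadZone:
    """Where beads may be placed, relative to the grid center (mm).

    Shallow beads sample ``|x - cx|`` in ``lateral_offset`` (both sides of
    the retraction plane), ``y - cy`` in ``along_range`` and ``z - cz`` in
    ``height_range``; the ``n_deep`` deepest beads instead use
    ``deep_height_range`` near the phantom base.  Defaults put the beads in
    the retraction-affected region so their true displacements span roughly
    the 1.4-5.4 mm range observed for embedded beads in a physical phantom.
    """

    lateral_offset: tuple = (5.0, 25.0)
    along_range: tuple = (-20.0, 20.0)
    height_range: tuple = (16.0, 34.0)
    n_deep: int = 2
    deep_lateral: tuple = (0.0, 15.0)
    deep_height_range: tuple = (-30.0, -18.0)
    min_separation: float = 6.0
    margin: float = 4.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom volume."""

    grid_shape: tuple = (128, 128, 128)
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    ellipsoid_semiaxes_mm: tuple = (55.0, 45.0, 38.0)
    n_beads: int = 23
    bead_diameter_mm: float = 1.5
    background_intensity: float = 0.0
    tissue_intensity: float = 80.0
    bead_intensity: float = 255.0
    seed: int = 0
    smooth_sigma_mm: float = 1.5
    bead_zone: BeadZone = dfield(default_factory=BeadZone)

    def __post_init__(self):
        if min(self.grid_shape) < 2 or min(self.voxel_size_mm) <= 0:
            raise SizingError("grid shape and voxel size must be positive")
        if min(self.ellipsoid_semiaxes_mm) <= 0 or self.bead_diameter_mm <= 0:
            raise SizingError("semiaxes and bead diameter must be positive")
        if self.n_beads < 0:
            raise SizingError("n_beads must be non-negative")
        ints = (self.background_intensity, self.tissue_intensity, self.bead_intensity)
        if len(set(ints)) != 3:
            raise SizingError("background/tissue/bead intensities must be pairwise distinct")
        half = 0.5 * (np.asarray(self.grid_shape) - 1) * np.asarray(self.voxel_size_mm)
        if np.any(np.asarray(self.ellipsoid_semiaxes_mm) + 2.0 > half):
            raise SizingError(
                f"ellipsoid semiaxes {self.ellipsoid_semiaxes_mm} do not fit in the "
                f"grid (half-extents {tuple(half)} mm, 2 mm margin required)"
            )

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = np.diag(self.voxel_size_mm)
        return A

    @property
    def center_world(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.grid_shape) - 1) * np.asarray(self.voxel_size_mm)


def _split_regions(n_shallow: int, n_deep: int, order: np.ndarray) -> np.ndarray:
    """Tag beads frontal/parietal/occipital in a 4:12:5(+deep) proportion.

    ``order`` sorts the shallow beads along the anterior-posterior axis; the
    two deep beads (placed near the base, mimicking peri-brainstem tissue)
    are tagged occipital, giving the 4/12/7 lobe split at the default count.
    """
    n = n_shallow
    n_front = int(round(4 / 21 * n))
    n_par = int(round(12 / 21 * n))
    regions = np.empty(n + n_deep, dtype=object)
    shallow = np.empty(n, dtype=object)
    shallow[order[:n_front]] = "frontal"
    shallow[order[n_front:n_front + n_par]] = "parietal"
    shallow[order[n_front + n_par:]] = "occipital"
    regions[:n] = shallow
    regions[n:] = "occipital"
    return regions


def generate_phantom_volume(spec: PhantomSpec):
    """Build the pre-retraction phantom.

    Returns ``(image, label, beads)``: the intensity volume (smoothed
    ellipsoid of tissue over background, beads rendered as spheres), the
    binary tissue label, and the bead table with *exact* (continuous, never
    voxelized) world centers and lobe-region tags.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    vox = np.asarray(spec.voxel_size_mm, dtype=float)
    center = spec.center_world
    semi = np.asarray(spec.ellipsoid_semiaxes_mm, dtype=float)

    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    world = idx * vox  # diagonal affine with zero translation
    rel = (world - center) / semi
    inside = (rel ** 2).sum(axis=-1) <= 1.0

    sigma_vox = spec.smooth_sigma_mm / vox
    smooth = ndimage.gaussian_filter(inside.astype(float), sigma=sigma_vox)
    label = LabelVolume((smooth >= 0.5).astype(np.uint8), spec.affine)
    img = spec.background_intensity + (
        spec.tissue_intensity - spec.background_intensity
    ) * smooth

    centers = _place_beads(spec, label, rng)
    # render beads as spheres with an anti-aliased rim
    r = 0.5 * spec.bead_diameter_mm
    for c in centers:
        lo = np.maximum(np.floor((c - r - vox) / vox).astype(int), 0)
        hi = np.minimum(np.ceil((c + r + vox) / vox).astype(int) + 1, shape)
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        d = np.linalg.norm(world[sl] - c, axis=-1)
        frac = np.clip((r - d) / vox.min() + 0.5, 0.0, 1.0)
        img[sl] = img[sl] * (1 - frac) + spec.bead_intensity * frac

    if spec.n_beads:
        n_deep = min(spec.bead_zone.n_deep, spec.n_beads)
        n_shallow = spec.n_beads - n_deep
        regions = _split_regions(n_shallow, n_deep, np.argsort(centers[:n_shallow, 1]))
    else:
        regions = []
    beads = BeadSet.from_centers(centers, regions=list(regions), space="pre-retraction")
    return ImageVolume(img.astype(np.float32), spec.affine), label, beads


def _place_beads(spec: PhantomSpec, label: LabelVolume, rng) -> np.ndarray:
    if spec.n_beads == 0:
        return np.empty((0, 3))
    zone = spec.bead_zone
    center = spec.center_world
    n_deep = min(zone.n_deep, spec.n_beads)
    n_shallow = spec.n_beads - n_deep
    # distance-to-surface map keeps beads strictly inside the tissue
    dist = ndimage.distance_transform_edt(label.mask, sampling=spec.voxel_size_mm)
    margin = zone.margin + 0.5 * spec.bead_diameter_mm

    def sample(n, lateral, height):
        out = []
        tries = 0
        while len(out) < n and tries < 20000:
            tries += 1
            s = rng.choice([-1.0, 1.0])
            p = center + np.array([
                s * rng.uniform(*lateral),
                rng.uniform(*zone.along_range),
                rng.uniform(*height),
            ])
            iv = np.round(p / spec.voxel_size_mm).astype(int)
            if np.any(iv < 0) or np.any(iv >= np.asarray(spec.grid_shape)):
                continue
            if dist[tuple(iv)] < margin:
                continue
            if out and np.min(np.linalg.norm(np.asarray(out) - p, axis=1)) < zone.min_separation:
                continue
            out.append(p)
        if len(out) < n:
            raise SamplingError(
                f"could not place {n} beads inside the tissue zone (placed {len(out)})"
            )
        return np.asarray(out)

    shallow = sample(n_shallow, zone.lateral_offset, zone.height_range) \
        if n_shallow else np.empty((0, 3))
    deep = sample(n_deep, zone.deep_lateral, zone.deep_height_range) \
        if n_deep else np.empty((0, 3))
    return np.vstack([shallow, deep])


# ---------------------------------------------------------------------------
# analytic ground-truth retraction field
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthField:
    r"""Analytic crack-opening displacement field with known parameters.

    .. math::

        u(x) = \pm d_{side}\,
               \Big(1 - \tfrac{|\psi|}{R}\Big)_+\,
               \mathrm{clip}\Big(\tfrac{-\phi}{\tau_f}, 0, 1\Big)\,
               \mathrm{clip}\Big(\tfrac{W/2 - |w|}{\tau_e}, 0, 1\Big)\, \hat n

    with the + branch (magnitude ``d_right``) on the positive side of the
    plane and the - branch (``d_left``) on the other.  The field is
    continuous everywhere except across the crack plane inside the crack
    rectangle; the jump there is ``(d_right + d_left)`` scaled by the depth
    and lateral tapers.  Displacement vanishes beyond ``decay_radius`` of
    the plane.
    """

    crack: CrackGeometry
    d_right_mm: float = 7.0
    d_left_mm: float = 6.3
    decay_radius_mm: float = 65.0
    front_taper_mm: float = 8.0
    edge_taper_mm: float = 20.0

    def __post_init__(self):
        if self.decay_radius_mm <= 0:
            raise GeometryError("decay_radius must be positive")
        if abs(np.linalg.norm(self.crack.n) - 1.0) > 1e-9:
            raise GeometryError("crack normal must be unit length")

    def _tapers(self, ww, dd):
        t_d = np.clip((self.crack.depth - dd) / self.front_taper_mm, 0.0, 1.0)
        t_w = np.clip((0.5 * self.crack.width - np.abs(ww)) / self.edge_taper_mm, 0.0, 1.0)
        return t_d * t_w

    def __call__(self, points, side=None) -> np.ndarray:
        """Displacement (mm) at world points; ``side`` (+-1) forces the branch
        taken at ``psi == 0`` (default: the +1 tie-break)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        psi, ww, dd = crack_coords(pts, self.crack)
        s = np.where(psi >= 0, 1.0, -1.0) if side is None else np.broadcast_to(
            np.asarray(side, dtype=float), psi.shape
        )
        d_side = np.where(s > 0, self.d_right_mm, self.d_left_mm)
        decay = np.clip(1.0 - np.abs(psi) / self.decay_radius_mm, 0.0, None)
        mag = s * d_side * decay * self._tapers(ww, dd)
        u = mag[:, None] * self.crack.n
        return u[0] if np.asarray(points).ndim == 1 else u

    def jump(self, points) -> np.ndarray:
        """u(x, +) - u(x, -) evaluated at (on-plane) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        psi, ww, dd = crack_coords(pts, self.crack)
        decay = np.clip(1.0 - np.abs(psi) / self.decay_radius_mm, 0.0, None)
        mag = (self.d_right_mm + self.d_left_mm) * decay * self._tapers(ww, dd)
        return mag[:, None] * self.crack.n

    def face_normal_offsets(self, points):
        """Normal coordinates of the two displaced crack faces above the
        plane-projection of each point: ``(u_n^+, u_n^-)``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _, ww, dd = crack_coords(pts, self.crack)
        t = self._tapers(ww, dd)
        return self.d_right_mm * t, -self.d_left_mm * t

    def to_dict(self) -> dict:
        return {
            "crack": self.crack.to_dict(),
            "d_right_mm": self.d_right_mm,
            "d_left_mm": self.d_left_mm,
            "decay_radius_mm": self.decay_radius_mm,
            "front_taper_mm": self.front_taper_mm,
            "edge_taper_mm": self.edge_taper_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthField":
        return cls(CrackGeometry.from_dict(d["crack"]),
                   d["d_right_mm"], d["d_left_mm"], d["decay_radius_mm"],
                   d["front_taper_mm"], d["edge_taper_mm"])


def analytic_retraction_field(
    crack: CrackGeometry,
    d_right_mm: float = 7.0,
    d_left_mm: float = 6.3,
    decay_radius_mm: float = 65.0,
    front_taper_mm: float = 8.0,
    edge_taper_mm: float = 20.0,
) -> GroundTruthField:
    """Construct the analytic ground-truth retraction field (see
    :class:`GroundTruthField`).  Default magnitudes are the 7.0 / 6.3 mm
    right/left maximum retraction distances of the phantom experiment."""
    return GroundTruthField(crack, d_right_mm, d_left_mm,
                            decay_radius_mm, front_taper_mm, edge_taper_mm)


def apply_field_to_volume(
    pre: ImageVolume,
    field: GroundTruthField,
    crack: CrackGeometry,
    beads: BeadSet,
    background_intensity: float = 0.0,
    order: int = 1,
    max_iter: int = 40,
    tol: float = 1e-8,
):
    """Deform ``pre`` through the ground-truth field -> synthetic post volume.

    Output voxels lying between the two displaced crack faces get
    ``background_intensity`` (the opened retraction corridor); every other
    voxel pulls its intensity from the material point found by fixed-point
    inversion of the field on its own side of the crack.  Bead centers are
    displaced exactly (field evaluated at the stored continuous centers).
    """
    shape = pre.shape
    x = pre.voxel_centers().reshape(-1, 3)
    psi, _, _ = crack_coords(x, crack)
    up, um = field.face_normal_offsets(x)
    gap = (psi > um) & (psi < up)
    s = np.where(psi >= up, 1.0, -1.0)  # side of the deformed configuration

    y = x.copy()
    live = ~gap
    for _ in range(max_iter):
        u = field(y[live], side=s[live])
        y_new = x[live] - u
        delta = np.abs(y_new - y[live]).max() if y_new.size else 0.0
        y[live] = y_new
        if delta < tol:
            break
    # keep the material point on its own side of the crack
    psi_y, ww_y, dd_y = crack_coords(y, crack)
    open_region = (dd_y <= crack.depth) & (np.abs(ww_y) <= 0.5 * crack.width)
    wrong = live & open_region & (np.where(psi_y >= 0, 1.0, -1.0) != s)
    y[wrong] -= (psi_y[wrong] - s[wrong] * 1e-9)[:, None] * crack.n

    iv = pre.world_to_index(y)
    snap = np.round(iv)
    near = np.abs(iv - snap) < 1e-6
    iv[near] = snap[near]
    vals = ndimage.map_coordinates(
        np.asarray(pre.data, dtype=float), iv.T, order=order,
        mode="constant", cval=background_intensity,
    )
    vals[gap] = background_intensity
    post = ImageVolume(vals.reshape(shape).astype(pre.data.dtype), pre.affine.copy())

    moved = beads.centers + field(beads.centers)
    iv_b = pre.world_to_index(moved) if len(moved) else moved
    if len(moved) and (np.any(iv_b < 0) or np.any(iv_b > np.asarray(shape) - 1)):
        raise BoundsError("ground-truth field displaces beads outside the grid")
    return post, beads.with_centers(moved, "post-retraction")


# ---------------------------------------------------------------------------
# simulated acquisitions
# ---------------------------------------------------------------------------


def simulate_lrs_cloud(
    post_surface: PointCloud,
    keep_fraction: float = 1.0,
    noise_sd_mm: float = 0.0,
    occluded_patch_fraction: float = 0.0,
    seed: int = 0,
) -> PointCloud:
    """Emulate a laser range scan of a surface: random subsampling, one
    contiguous angular patch removed (laser obstruction), isotropic Gaussian
    noise.  Reproducible under ``seed``."""
    if not (0 < keep_fraction <= 1):
        raise SamplingError("keep_fraction must be in (0, 1]")
    if not (0 <= occluded_patch_fraction < 1):
        raise SamplingError("occluded_patch_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(post_surface)
    if keep_fraction < 1.0:
        kept = np.nonzero(rng.random(n) < keep_fraction)[0]
    else:
        kept = np.arange(n)
    if len(kept) == 0:
        raise SamplingError("subsampling removed every point")

    if occluded_patch_fraction > 0:
        pts = post_surface.points[kept]
        c = pts.mean(axis=0)
        _, _, vh = np.linalg.svd(pts - c, full_matrices=False)
        uv = (pts - c) @ vh[:2].T
        ang = np.arctan2(uv[:, 1], uv[:, 0])
        order = np.argsort(ang)
        n_rm = int(round(occluded_patch_fraction * len(kept)))
        start = rng.integers(len(kept))
        rm = order[(start + np.arange(n_rm)) % len(kept)]
        keep_mask = np.ones(len(kept), dtype=bool)
        keep_mask[rm] = False
        kept = kept[keep_mask]
    if len(kept) == 0:
        raise SamplingError("occlusion removed every point")

    out = post_surface.select(kept)
    if noise_sd_mm > 0:
        out = PointCloud(
            out.points + rng.normal(0.0, noise_sd_mm, out.points.shape),
            out.normals, out.displacements, out.labels,
        )
    return out


def simulate_probe_points(
    crack: CrackGeometry,
    retractor,
    w_center_mm: float = 0.0,
    insert_depth_mm: float | None = None,
) -> np.ndarray:
    """World coordinates of the four blade corners a navigation probe would
    digitize: the in-plane rectangle of the inserted part of the blade.

    The blade must fit inside the crack rectangle; a degenerate (zero-area)
    request raises :class:`GeometryError`.
    """
    width = float(retractor.width_mm)
    insert = float(insert_depth_mm if insert_depth_mm is not None
                   else min(retractor.length_mm, crack.depth))
    if width <= 0 or insert <= 0:
        raise GeometryError("blade corners are collinear for zero width/insertion")
    if abs(w_center_mm) + width / 2 > crack.width / 2 + 1e-9 or insert > crack.depth + 1e-9:
        raise GeometryError("retractor blade does not fit inside the crack rectangle")
    w = crack.w
    corners = []
    for dw in (-width / 2, width / 2):
        for dd in (0.0, insert):
            corners.append(crack.o + (w_center_mm + dw) * w + dd * crack.d)
    return np.asarray(corners)
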
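"""Retractor surface tracking: from probe points and scanner clouds to
Dirichlet boundary conditions on the crack faces.

The chain mirrors the intraoperative procedure: a navigation probe digitizes
the blade corners (pre-retraction pose), a dense template cloud of the blade
is built from those corners and the blade dimensions, the partially occluded
post-retraction scan is completed by a trimmed rigid ICP fit of the template,
a nonrigid CPD registration yields per-point displacements, and finally the
displacements are offset by the blade thickness along the surface normal and
snapped to the crack-adjacent mesh nodes of the matching side.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .cpd import CPDParams, CPDResult, cpd_nonrigid_register  # noqa: F401  (re-export)
from .crack import CrackGeometry, crack_coords, fit_plane
from .errors import ConflictError, ConfigurationError, GeometryError, RegistrationError
from .mesh import EnrichmentTable, HexMesh, UNCUT

log = logging.getLogger(__name__)

__all__ = [
    "RetractorModel",
    "RigidTransform",
    "DisplacementBCSet",
    "build_retractor_cloud",
    "blade_contact_template",
    "apply_rigid",
    "rigid_augment",
    "cpd_nonrigid_register",
    "extract_contact_bcs",
]


@dataclass(frozen=True)
class RetractorModel:
    """Blade dimensions (mm) and template sampling pitch.

    The default 14 mm width matches a standard Plexiglas retractor blade.
    """

    width_mm: float = 14.0
    length_mm: float = 60.0
    thickness_mm: float = 2.0
    pitch_mm: float = 1.0

    def __post_init__(self):
        if min(self.width_mm, self.length_mm, self.thickness_mm, self.pitch_mm) <= 0:
            raise ConfigurationError("all retractor dimensions must be positive")


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid transform (rotation block orthonormal, det +1)."""

    matrix: tuple

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise GeometryError("rigid transform must be 4x4")
        R = m[:3, :3]
        if (np.abs(R @ R.T - np.eye(3)).max() > 1e-9
                or abs(np.linalg.det(R) - 1.0) > 1e-9
                or np.abs(m[3] - [0, 0, 0, 1]).max() > 1e-12):
            raise GeometryError("rotation block must be orthonormal with det +1")
        object.__setattr__(self, "matrix", tuple(map(tuple, m)))

    @property
    def m(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @property
    def R(self) -> np.ndarray:
        return self.m[:3, :3]

    @property
    def t(self) -> np.ndarray:
        return self.m[:3, 3]

    @classmethod
    def from_Rt(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = t
        return cls(tuple(map(tuple, m)))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls.from_Rt(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_Rt(self.R.T, -self.R.T @ self.t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(tuple(map(tuple, self.m @ other.m)))


def apply_rigid(cloud: PointCloud, T: RigidTransform) -> PointCloud:
    """Transform points and normals into the target space (e.g. the
    reference-frame -> image or scanner -> image transforms)."""
    return cloud.transformed(T.R, T.t)


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------


def _probe_frame(probe_points: np.ndarray):
    """Orthonormal frame from >=3 probe points: (centroid, long axis, short
    in-plane axis, plane normal)."""
    pts = np.atleast_2d(np.asarray(probe_points, dtype=float))
    c, n = fit_plane(pts)
    rel = pts - c
    rel -= np.outer(rel @ n, n)
    _, s, vh = np.linalg.svd(rel)
    long_axis, short_axis = vh[0], vh[1]
    short_axis = np.cross(n, long_axis)  # right-handed in-plane pair
    return c, long_axis, short_axis / np.linalg.norm(short_axis), n


def build_retractor_cloud(probe_points: np.ndarray, model: RetractorModel) -> PointCloud:
    """Dense rectangular-grid sampling of both blade faces, posed by the
    probe-derived frame; outward normals attached and faces labeled +/-."""
    c, axis_l, axis_w, n = _probe_frame(probe_points)
    nl = int(round(model.length_mm / model.pitch_mm)) + 1
    nw = int(round(model.width_mm / model.pitch_mm)) + 1
    ll = np.linspace(-model.length_mm / 2, model.length_mm / 2, nl)
    ww = np.linspace(-model.width_mm / 2, model.width_mm / 2, nw)
    L, W = np.meshgrid(ll, ww, indexing="ij")
    base = c + L.ravel()[:, None] * axis_l + W.ravel()[:, None] * axis_w
    half_t = model.thickness_mm / 2
    faces, normals, labels = [], [], []
    for s in (+1.0, -1.0):
        faces.append(base + s * half_t * n)
        normals.append(np.broadcast_to(s * n, base.shape).copy())
        labels.append(np.full(len(base), "+" if s > 0 else "-", dtype=object))
    return PointCloud(np.vstack(faces), np.vstack(normals), labels=np.concatenate(labels))


def blade_contact_template(
    probe_points: np.ndarray, model: RetractorModel, side: int,
    normal_hint: np.ndarray | None = None,
) -> PointCloud:
    """On-plane template of the blade surface whose motion drives the tissue
    of the given crack side (+1/-1): points at the probe-fitted midplane with
    contact-direction normals.  Used as the dense pre-retraction cloud for
    registration and BC extraction."""
    c, axis_l, axis_w, n = _probe_frame(probe_points)
    if normal_hint is not None and n @ np.asarray(normal_hint, dtype=float) < 0:
        n = -n
    pts = np.atleast_2d(np.asarray(probe_points, dtype=float))
    ext_l = (pts - c) @ axis_l
    ext_w = (pts - c) @ axis_w
    nl = max(int(round((ext_l.max() - ext_l.min()) / model.pitch_mm)), 1) + 1
    nw = max(int(round((ext_w.max() - ext_w.min()) / model.pitch_mm)), 1) + 1
    L, W = np.meshgrid(np.linspace(ext_l.min(), ext_l.max(), nl),
                       np.linspace(ext_w.min(), ext_w.max(), nw), indexing="ij")
    base = c + L.ravel()[:, None] * axis_l + W.ravel()[:, None] * axis_w
    s = float(side)
    if abs(s) != 1.0:
        raise ConfigurationError("side must be +1 or -1")
    normals = np.broadcast_to(s * n, base.shape).copy()
    return PointCloud(base, normals, labels=np.full(len(base), "+" if s > 0 else "-",
                                                    dtype=object))


# ---------------------------------------------------------------------------
# rigid augmentation (trimmed ICP)
# ---------------------------------------------------------------------------


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Least-squares rigid transform mapping P onto Q."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cq - R @ cp


def _icp_symmetric(src, tree_src, scan, t0, trim_fraction, max_iter, tol,
                   R0=None):
    """Symmetric trimmed ICP from a translation init.

    Scan->template correspondences are all kept (every scan point truly lies
    on the surface); template->scan correspondences are trimmed so the
    occluded patch cannot drag the fit.
    """
    tree_scan = cKDTree(scan)
    R = np.eye(3) if R0 is None else np.asarray(R0, dtype=float).copy()
    t = np.asarray(t0, dtype=float).copy()
    n_t = max(int(round(trim_fraction * len(src))), 3)
    for _ in range(max_iter):
        d2, j2 = tree_src.query((scan - t) @ R)
        d1, j1 = tree_scan.query(src @ R.T + t)
        k1 = np.argsort(d1)[:n_t]
        R_new, t_new = _kabsch(np.vstack([src[j2], src[k1]]),
                               np.vstack([scan, scan[j1[k1]]]))
        dR = np.abs(R_new - R).max()
        dt = np.abs(t_new - t).max()
        R, t = R_new, t_new
        if dR < tol and dt < tol:
            break
    d2, _ = tree_src.query((scan - t) @ R)
    d1, _ = tree_scan.query(src @ R.T + t)
    k1 = np.argsort(d1)[:n_t]
    rms = float(np.sqrt(np.concatenate([d2 ** 2, d1[k1] ** 2]).mean()))
    return R, t, rms


def rigid_augment(
    template: PointCloud,
    partial_scan: PointCloud,
    trim_fraction: float = 0.7,
    max_iter: int = 150,
    tol: float = 1e-12,
    residual_threshold_mm: float = 2.0,
    search_half_range_mm: float = 10.0,
):
    """Complete a partially occluded scan: rigid fit of the full template
    onto the scan, returning the template posed at the fit.

    Returns ``(augmented_cloud, transform, rms_residual_mm)``.  The fit is a
    symmetric trimmed ICP (template-side trimming at ``trim_fraction``
    absorbs the occluded patch) preceded by a coarse in-plane translation
    grid search and a one-lattice-pitch multistart, which are needed because
    regularly sampled blade templates create lattice-aliased ICP minima.
    For a flat blade the pose component *along* an occluded edge is only
    weakly identifiable; the surface-normal component — the one that carries
    the retraction displacement — is recovered to well under the sampling
    noise.  Raises :class:`RegistrationError` if the residual stays above
    ``residual_threshold_mm``.
    """
    if len(partial_scan) < 50:
        raise RegistrationError("partial scan too sparse for rigid augmentation (<50 points)")
    src = template.points
    scan = partial_scan.points
    tree = cKDTree(src)
    nn = tree.query(src, k=2)[0][:, 1]
    pitch = float(np.median(nn))
    mu_s, mu_x = src.mean(axis=0), scan.mean(axis=0)
    scale = float(np.sqrt(((src - mu_s) ** 2).sum(axis=1).mean()))

    # rotation seeds from principal-axis alignment (regular blade templates
    # alias badly under NN-based rotation refinement from identity)
    _, _, vt = np.linalg.svd(src - mu_s, full_matrices=False)
    _, _, vs = np.linalg.svd(scan - mu_x, full_matrices=False)
    seeds = [np.eye(3)]
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            s3 = s1 * s2 * np.sign(np.linalg.det(vs) * np.linalg.det(vt))
            R0 = vs.T @ np.diag([s1, s2, s3]) @ vt
            seeds.append(R0)

    def motion(R, t):
        return np.linalg.norm(R - np.eye(3)) + np.linalg.norm(t) / max(scale, 1.0)

    offs = np.arange(-search_half_range_mm, search_half_range_mm + 1e-9, 1.0)
    # a deterministic subsample of the scan is enough to score coarse inits
    step = max(len(scan) // 150, 1)
    scan_coarse = scan[::step]
    cands = []
    for R0 in seeds:
        # coarse in-plane translation search at this rotation
        e1, e2 = R0 @ vt[0], R0 @ vt[1]
        c0 = mu_x - R0 @ mu_s
        best_t, best_rms = c0, np.inf
        for o1 in offs:
            for o2 in offs:
                t = c0 + o1 * e1 + o2 * e2
                d, _ = tree.query((scan_coarse - t) @ R0)
                rms = float(np.sqrt((d ** 2).mean()))
                if rms < best_rms:
                    best_rms, best_t = rms, t
        for o1 in (-pitch, 0.0, pitch):
            for o2 in (-pitch, 0.0, pitch):
                cands.append(_icp_symmetric(src, tree, scan,
                                            best_t + o1 * e1 + o2 * e2,
                                            trim_fraction, min(max_iter, 40),
                                            tol, R0=R0))
    polished = []
    for R, t, _ in sorted(cands, key=lambda c: c[2])[:6]:
        # untrimmed scan->template polish: asymptotically exact for
        # full-overlap data, where trimming would bias the fixed point
        for _ in range(max_iter):
            d, j = tree.query((scan - t) @ R)
            R_new, t_new = _kabsch(src[j], scan)
            dR = np.abs(R_new - R).max()
            dt = np.abs(t_new - t).max()
            R, t = R_new, t_new
            if dR < tol and dt < tol:
                break
        d, _ = tree.query((scan - t) @ R)
        polished.append((R, t, float(np.sqrt((d ** 2).mean()))))
    # a symmetric template makes some poses exactly equivalent: break ties
    # toward the least motion (retraction moves blades only modestly)
    R, t, rms = min(polished, key=lambda c: c[2] + 1e-6 * motion(c[0], c[1]))
    if rms > residual_threshold_mm:
        raise RegistrationError(
            f"ICP residual {rms:.3f} mm exceeds threshold {residual_threshold_mm} mm"
        )
    T = RigidTransform.from_Rt(R, t)
    return apply_rigid(template, T), T, rms


def track_blade_displacements(
    template: PointCloud,
    scan: PointCloud,
    cpd_params: CPDParams | None = None,
    trim_fraction: float = 0.7,
    fill_distance_mm: float | None = None,
    residual_threshold_mm: float = 2.0,
    normal_only: bool = True,
):
    """Full tracking chain for one blade: rigid augmentation of the occluded
    scan, completion of the missing patch with posed-template points, and
    nonrigid CPD of the dense template onto the completed cloud.

    ``normal_only`` (default) projects the recovered displacement onto the
    blade surface normal: a featureless flat face cannot measure tangential
    motion (the aperture problem), and a low-friction blade constrains the
    tissue only along its normal, so the tangential estimate is noise and is
    discarded.  Returns ``(registered_cloud, icp_rms)`` where the cloud
    carries the template points/normals plus per-point ``displacements``.
    """
    augmented, _, rms = rigid_augment(
        template, scan, trim_fraction, residual_threshold_mm=residual_threshold_mm
    )
    if fill_distance_mm is None:
        nn = cKDTree(template.points).query(template.points, k=2)[0][:, 1]
        fill_distance_mm = 2.0 * float(np.median(nn))
    d_fill, _ = cKDTree(scan.points).query(augmented.points)
    fill = augmented.points[d_fill > fill_distance_mm]
    target = np.vstack([scan.points, fill]) if len(fill) else scan.points
    res = cpd_nonrigid_register(template.points, target,
                                cpd_params or CPDParams(w=0.05),
                                init_displacements=augmented.points - template.points)
    disp = res.displacements
    if normal_only and template.normals is not None:
        disp = np.sum(disp * template.normals, axis=1, keepdims=True) * template.normals
    return (
        PointCloud(template.points, template.normals, disp, template.labels),
        rms,
    )


# ---------------------------------------------------------------------------
# boundary-condition extraction
# ---------------------------------------------------------------------------


@dataclass
class DisplacementBCSet:
    """Dirichlet data: side-resolved displacements at crack-adjacent nodes
    plus the zero-displacement node set (phantom base / brainstem region)."""

    entries: list = field(default_factory=list)   # (node, side in {+1,-1,0}, vec)
    zero_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        self.zero_nodes = np.asarray(self.zero_nodes, dtype=int)
        seen = set()
        zset = set(self.zero_nodes.tolist())
        for node, side, vec in self.entries:
            key = (int(node), int(side))
            if key in seen:
                raise ConflictError(f"duplicate BC entry for node {node} side {side}")
            seen.add(key)
            if int(node) in zset:
                raise ConflictError(f"node {node} is both zero-region and crack-face BC")

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {"node_id": int(n), "side": {1: "+", -1: "-", 0: "none"}[int(s)],
             "ux": v[0], "uy": v[1], "uz": v[2]}
            for n, s, v in self.entries
        ]
        pd.DataFrame(rows, columns=["node_id", "side", "ux", "uy", "uz"]).to_csv(
            path, index=False
        )


def extract_contact_bcs(
    registered: PointCloud,
    model: RetractorModel,
    mesh: HexMesh,
    crack: CrackGeometry,
    zero_region,
    enrichment: EnrichmentTable | None = None,
    snap_max_mm: float | None = None,
    conflict_tol_mm: float = 0.5,
    thickness_mm: float | None = None,
    footprint_margin_mm: float = 0.5,
) -> DisplacementBCSet:
    """Turn registered retractor-surface displacements into nodal BCs.

    Each point's displacement is offset by the blade thickness along its
    surface normal (inner scanned surface -> tissue contact surface), then
    attached to the nearest crack-adjacent mesh node on the matching side of
    the plane (nearest neighbor, capped at one element size).  Only nodes in
    *direct contact* with a blade are eligible: a node whose in-plane
    position falls outside the measured cloud's in-plane footprint (plus
    ``footprint_margin_mm``) receives no prescription, since tissue there is
    not touching a retractor.  Points that reach no node are dropped with a
    log entry; two different source faces prescribing incompatible vectors
    at one (node, side) raise :class:`ConflictError`.  ``zero_region`` is an
    array of node indices or a predicate over node coordinates selecting the
    fixed base.
    """
    if registered.displacements is None or registered.normals is None:
        raise ConfigurationError("registered cloud needs displacements and normals")
    t = model.thickness_mm if thickness_mm is None else thickness_mm
    snap_max = float(np.max(mesh.element_size)) if snap_max_mm is None else snap_max_mm
    bc_disp = registered.displacements + t * registered.normals
    side_pt = np.where(registered.normals @ crack.n >= 0, 1, -1)
    labels = (registered.labels if registered.labels is not None
              else np.zeros(len(registered), dtype=int))

    psi_nodes, ww_nodes, dd_nodes = crack_coords(mesh.nodes, crack)
    if enrichment is not None:
        adjacent = np.unique(mesh.elements[enrichment.elem_type != UNCUT])
    else:
        adjacent = np.nonzero(np.abs(psi_nodes) <= snap_max)[0]
    node_side = np.where(psi_nodes >= 0, 1, -1)

    # per-blade in-plane footprint of the measured cloud (direct contact area)
    _, ww_pts, dd_pts = crack_coords(registered.points, crack)
    footprint = {}
    for lab in np.unique(labels):
        sel = labels == lab
        footprint[lab] = (ww_pts[sel].min() - footprint_margin_mm,
                          ww_pts[sel].max() + footprint_margin_mm,
                          dd_pts[sel].min() - footprint_margin_mm,
                          dd_pts[sel].max() + footprint_margin_mm)

    collected: dict = {}
    n_dropped = 0
    for s in (+1, -1):
        cand = adjacent[node_side[adjacent] == s]
        sel = side_pt == s
        if not sel.any():
            continue
        if cand.size == 0:
            n_dropped += int(sel.sum())
            continue
        tree = cKDTree(mesh.nodes[cand])
        d, j = tree.query(registered.points[sel])
        for pi, (dist, jj) in zip(np.nonzero(sel)[0], zip(d, j)):
            node = int(cand[jj])
            w_lo, w_hi, d_lo, d_hi = footprint[labels[pi]]
            if dist > snap_max or not (
                w_lo <= ww_nodes[node] <= w_hi and d_lo <= dd_nodes[node] <= d_hi
            ):
                n_dropped += 1
                continue
            collected.setdefault((node, s), []).append((labels[pi], bc_disp[pi]))
    if n_dropped:
        log.info("extract_contact_bcs: dropped %d unreachable cloud points", n_dropped)

    entries = []
    for (node, s), items in sorted(collected.items()):
        by_label: dict = {}
        for lab, vec in items:
            by_label.setdefault(lab, []).append(vec)
        means = {lab: np.mean(v, axis=0) for lab, v in by_label.items()}
        vals = list(means.values())
        for i in range(1, len(vals)):
            if np.linalg.norm(vals[i] - vals[0]) > conflict_tol_mm:
                raise ConflictError(
                    f"conflicting face prescriptions at node {node} side {s:+d}"
                )
        entries.append((node, s, np.mean(vals, axis=0)))

    if callable(zero_region):
        zero_nodes = np.nonzero(zero_region(mesh.nodes))[0]
    else:
        zero_nodes = np.asarray(zero_region, dtype=int)
    if zero_nodes.size == 0:
        raise ConfigurationError("zero-displacement region is empty")
    return DisplacementBCSet(entries, zero_nodes)
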
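"""Uniform hexahedral meshing of a label volume and XFEM node classification.

The mesh tiles the voxel grid with axis-aligned hexahedra whose edge length is
an integer multiple of the voxel size; a cell is kept when the fraction of
in-mask voxels it covers reaches ``occupancy_threshold``.  Node classification
follows the Heaviside/tip split: elements *completely cut* by the crack
contribute their nodes to set ``J``, elements containing the crack *front*
contribute theirs to set ``M`` (which takes precedence so ``J`` and ``M``
stay disjoint).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crack import CrackGeometry, crack_coords
from .errors import ConfigurationError, ConsistencyError, MeshError
from .volume import LabelVolume

__all__ = ["HexMesh", "EnrichmentTable", "build_hex_mesh", "classify_enrichment"]

# VTK_HEXAHEDRON corner ordering in the unit cell
_CORNERS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=int
)
# the 12 hexahedron edges as corner-index pairs
_EDGES = np.array(
    [[0, 1], [1, 2], [2, 3], [3, 0],
     [4, 5], [5, 6], [6, 7], [7, 4],
     [0, 4], [1, 5], [2, 6], [3, 7]], dtype=int
)


@dataclass
class HexMesh:
    """Uniform axis-aligned hexahedral mesh in world coordinates (mm).

    ``nodes`` are deduplicated corner coordinates; ``elements`` index into
    them in VTK hexahedron order.  ``cell_to_elem`` maps lattice cells to
    element ids (-1 where the mask was below the occupancy threshold), which
    makes point-in-element lookup O(1) on the uniform grid.
    """

    nodes: np.ndarray            # (N, 3) float
    elements: np.ndarray         # (E, 8) int
    element_size: np.ndarray     # (3,) mm
    origin: np.ndarray           # world position of lattice node (0,0,0)
    lattice_shape: tuple         # number of cells along each axis
    cell_to_elem: np.ndarray     # int array of lattice_shape
    node_lattice: np.ndarray     # (N, 3) int lattice index of each node

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def node_to_elements(self) -> list:
        """Adjacency: for each node, the element ids touching it."""
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for e, conn in enumerate(self.elements):
            for n in conn:
                adj[n].append(e)
        return adj

    # -- point location ----------------------------------------------------
    def lattice_coords(self, points: np.ndarray) -> np.ndarray:
        """Continuous lattice coordinates (element units) of world points."""
        return (np.atleast_2d(points) - self.origin) / self.element_size

    def elem_index_of(self, points: np.ndarray) -> np.ndarray:
        """Element id containing each point (-1 outside), upper faces inclusive."""
        lc = self.lattice_coords(points)
        shape = np.asarray(self.lattice_shape)
        inside = np.all((lc >= -1e-9) & (lc <= shape + 1e-9), axis=1)
        # points exactly on the upper boundary belong to the last cell
        cell = np.clip(np.floor(lc).astype(int), 0, shape - 1)
        out = np.full(len(lc), -1, dtype=int)
        idx = cell[inside]
        out[inside] = self.cell_to_elem[idx[:, 0], idx[:, 1], idx[:, 2]]
        return out

    def local_coords(self, points: np.ndarray, elem: np.ndarray) -> np.ndarray:
        """Reference coordinates xi in [-1, 1]^3 of points within elements."""
        lc = self.lattice_coords(points)
        cells = self.node_lattice[self.elements[elem, 0]]
        return 2.0 * (lc - cells) - 1.0


def build_hex_mesh(
    label: LabelVolume,
    element_size_mm: float,
    occupancy_threshold: float = 0.5,
) -> HexMesh:
    """Tile the in-mask region of ``label`` with uniform hexahedra.

    ``element_size_mm`` must be an integer multiple of the voxel size along
    each axis.  Raises :class:`MeshError` on an empty mask.
    """
    mask = np.asarray(label.mask)
    if not mask.any():
        raise MeshError("label mask is empty; nothing to mesh")
    R = label.affine[:3, :3]
    if np.any(np.abs(R - np.diag(np.diag(R))) > 1e-9) or np.any(np.diag(R) <= 0):
        raise ConfigurationError("meshing requires an axis-aligned affine with positive spacing")
    vox = np.diag(R)
    m = np.asarray(element_size_mm, dtype=float) / vox
    m_int = np.round(m).astype(int)
    if np.any(np.abs(m - m_int) > 1e-9) or np.any(m_int < 1):
        raise ConfigurationError(
            f"element size {element_size_mm} mm is not an integer multiple of voxel size {vox}"
        )
    h = m_int * vox

    # pad the mask up to a whole number of cells, then box-sum occupancy
    shape = np.asarray(mask.shape)
    ncell = -(-shape // m_int)
    pad = ncell * m_int - shape
    mp = np.pad(mask, [(0, p) for p in pad]).astype(float)
    occ = mp.reshape(ncell[0], m_int[0], ncell[1], m_int[1], ncell[2], m_int[2]).sum(
        axis=(1, 3, 5)
    ) / m_int.prod()
    keep = occ >= occupancy_threshold - 1e-12
    if not keep.any():
        raise MeshError("no element reaches the occupancy threshold")

    cells = np.argwhere(keep)
    # node lattice indices of the 8 corners of every kept cell
    corner_lat = cells[:, None, :] + _CORNERS[None, :, :]
    flat_dim = ncell + 1
    flat = np.ravel_multi_index(
        (corner_lat[..., 0], corner_lat[..., 1], corner_lat[..., 2]), flat_dim
    )
    uniq, inv = np.unique(flat, return_inverse=True)
    elements = inv.reshape(-1, 8)
    node_lat = np.stack(np.unravel_index(uniq, flat_dim), axis=-1)

    # world position of lattice node (a,b,c): corner of voxel block = center
    # of voxel (a*m) minus half a voxel
    origin = label.index_to_world(-0.5 * np.ones(3))
    nodes = origin + node_lat * h

    cell_to_elem = np.full(tuple(ncell), -1, dtype=int)
    cell_to_elem[cells[:, 0], cells[:, 1], cells[:, 2]] = np.arange(len(cells))

    return HexMesh(
        nodes=np.asarray(nodes, dtype=float),
        elements=elements.astype(int),
        element_size=h.astype(float),
        origin=np.asarray(origin, dtype=float),
        lattice_shape=tuple(int(n) for n in ncell),
        cell_to_elem=cell_to_elem,
        node_lattice=node_lat.astype(int),
    )


# ---------------------------------------------------------------------------
# enrichment classification
# ---------------------------------------------------------------------------

UNCUT, FULLY_CUT, FRONT = 0, 1, 2


@dataclass
class EnrichmentTable:
    """XFEM node sets and DOF layout.

    ``set_I`` is every node (3 standard DOFs each); nodes in ``set_J`` carry
    3 extra Heaviside DOFs and nodes in ``set_M`` 12 extra tip DOFs (4 branch
    functions x 3 components).  ``J`` and ``M`` are disjoint, with ``M``
    taking precedence on overlap.
    """

    n_nodes: int
    set_J: np.ndarray
    set_M: np.ndarray
    elem_type: np.ndarray          # per element: UNCUT / FULLY_CUT / FRONT
    heav_slot: np.ndarray = field(default=None)  # node -> J slot or -1
    tip_slot: np.ndarray = field(default=None)   # node -> M slot or -1

    def __post_init__(self):
        self.set_J = np.asarray(self.set_J, dtype=int)
        self.set_M = np.asarray(self.set_M, dtype=int)
        if np.intersect1d(self.set_J, self.set_M).size:
            raise ConfigurationError("sets J and M must be disjoint")
        self.heav_slot = np.full(self.n_nodes, -1, dtype=int)
        self.heav_slot[self.set_J] = np.arange(len(self.set_J))
        self.tip_slot = np.full(self.n_nodes, -1, dtype=int)
        self.tip_slot[self.set_M] = np.arange(len(self.set_M))

    @property
    def set_I(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_nodes + 3 * len(self.set_J) + 12 * len(self.set_M)

    # DOF indexing: standard block | Heaviside block | tip block
    def std_dof(self, node, comp):
        return 3 * np.asarray(node) + comp

    def heav_dof(self, node, comp):
        slot = self.heav_slot[np.asarray(node)]
        if np.any(slot < 0):
            raise ConsistencyError("node carries no Heaviside DOF")
        return 3 * self.n_nodes + 3 * slot + comp

    def tip_dof(self, node, l, comp):
        slot = self.tip_slot[np.asarray(node)]
        if np.any(slot < 0):
            raise ConsistencyError("node carries no tip DOF")
        return 3 * self.n_nodes + 3 * len(self.set_J) + 12 * slot + 3 * l + comp


def _element_cut_points(corners: np.ndarray, psi: np.ndarray, tol: float) -> np.ndarray:
    """Points where the crack plane meets an element (edge crossings + on-plane nodes)."""
    pts = [corners[np.abs(psi) <= tol]]
    a, b = _EDGES[:, 0], _EDGES[:, 1]
    pa, pb = psi[a], psi[b]
    crossing = (pa * pb) < -tol * tol
    if crossing.any():
        t = pa[crossing] / (pa[crossing] - pb[crossing])
        pts.append(corners[a[crossing]] + t[:, None] * (corners[b[crossing]] - corners[a[crossing]]))
    pts = [p for p in pts if len(p)]
    return np.vstack(pts) if pts else np.empty((0, 3))


def classify_enrichment(
    mesh: HexMesh, crack: CrackGeometry, tol: float = 1e-9
) -> EnrichmentTable:
    """Split mesh nodes into the standard/Heaviside/tip sets for the crack.

    An element is a *cut candidate* when its nodal plane distances change
    sign (a zero distance counts as positive, matching the Heaviside
    tie-break).  Candidates are then classified by where the crack rectangle
    actually meets them: entirely behind the front -> fully cut (nodes to
    ``J``); straddling the front -> front element (nodes to ``M``); beyond
    the front or outside the lateral extent -> uncut.
    """
    psi_nodes, ww_nodes, dd_nodes = crack_coords(mesh.nodes, crack)
    epsi = psi_nodes[mesh.elements]
    cand = (epsi.min(axis=1) < -tol) & (epsi.max(axis=1) >= -tol)

    elem_type = np.full(mesh.n_elements, UNCUT, dtype=int)
    half_w = 0.5 * crack.width
    for e in np.nonzero(cand)[0]:
        corners = mesh.nodes[mesh.elements[e]]
        pts = _element_cut_points(corners, epsi[e], tol)
        if not len(pts):
            continue
        _, ww, dd = crack_coords(pts, crack)
        inside = np.abs(ww) <= half_w + tol
        if not inside.any():
            continue
        phi = dd[inside] - crack.depth
        if phi.min() >= -tol:
            continue  # entirely beyond the front
        if phi.max() > tol:
            elem_type[e] = FRONT
        else:
            elem_type[e] = FULLY_CUT

    set_M = np.unique(mesh.elements[elem_type == FRONT])
    set_J = np.setdiff1d(np.unique(mesh.elements[elem_type == FULLY_CUT]), set_M)
    if set_J.size == 0 and set_M.size == 0:
        warnings.warn("crack does not cut any element; enrichment is empty", stacklevel=2)
    return EnrichmentTable(mesh.n_nodes, set_J, set_M, elem_type)
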
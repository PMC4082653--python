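r"""Enriched linear-elastic solver: assemble and solve ``K a = P``.

The displacement ansatz is the Heaviside/crack-tip enriched trilinear field

.. math::

    u(x) = \sum_{i\in I}\varphi_i(x)\,u_i
         + \sum_{j\in J}\varphi_j(x)\,[H(x) - H(x_j)]\,a_j
         + \sum_{m\in M}\varphi_m(x)\sum_{l=1}^4 [F_l(x) - F_l(x_m)]\,c_m^l

with *shifted* enrichment (the enrichment value at the owning node is
subtracted), so standard nodal DOFs keep their physical meaning and nodal
Dirichlet data can be imposed directly.  ``H`` is the ±1 step of the signed
plane distance; ``F_l`` are the four asymptotic crack-tip branch functions in
polar coordinates around the crack front.

Elements are uniform trilinear hexahedra with 2x2x2 Gauss quadrature; cut
elements are integrated on a uniform sub-cell refinement with the step/tip
functions evaluated per sub-cell point.  A mean-dilatation (B-bar) treatment
of the volumetric strain is used by default, averaged separately on each side
of the crack in cut elements, to avoid locking at Poisson ratios near 0.5.
Dirichlet constraints are imposed by exact elimination.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .crack import CrackGeometry, crack_coords
from .errors import (AssemblyError, ConfigurationError, ConflictError,
                     ConsistencyError, LocationError, SolverError)
from .mesh import EnrichmentTable, HexMesh, UNCUT
from .tracking import DisplacementBCSet

__all__ = [
    "MaterialParams",
    "XFEMSystem",
    "XFEMSolution",
    "heaviside_at",
    "tip_functions",
    "tip_function_gradients",
    "assemble",
    "apply_boundary_conditions",
    "solve_system",
    "displacement_at",
]

_G1 = 1.0 / np.sqrt(3.0)
_CORNER_SIGNS = np.array(
    [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float
)


@dataclass(frozen=True)
class MaterialParams:
    """Isotropic linear elasticity: Young's modulus (Pa) and Poisson ratio.

    Defaults match a PVA-C brain phantom: E = 3 kPa, nu = 0.45.
    """

    E: float = 3000.0
    nu: float = 0.45

    def __post_init__(self):
        if self.E <= 0:
            raise ConfigurationError("Young's modulus must be positive")
        if not (0 <= self.nu < 0.5):
            raise ConfigurationError("Poisson ratio must lie in [0, 0.5)")

    @property
    def C(self) -> np.ndarray:
        """6x6 constitutive matrix, Voigt order (xx, yy, zz, xy, yz, zx)."""
        E, nu = self.E, self.nu
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        C = np.zeros((6, 6))
        C[:3, :3] = lam
        C[np.arange(3), np.arange(3)] = lam + 2 * mu
        C[np.arange(3, 6), np.arange(3, 6)] = mu
        return C


def heaviside_at(points, crack: CrackGeometry):
    """±1 step of the signed plane distance (tie at 0 resolves to +1)."""
    psi, _, _ = crack_coords(np.atleast_2d(points), crack)
    return np.where(psi >= 0.0, 1.0, -1.0)


def tip_functions(r, theta) -> np.ndarray:
    r"""The four crack-tip branch functions
    ``{sqrt(r) sin(t/2), sqrt(r) cos(t/2), sqrt(r) sin(t/2) sin t,
    sqrt(r) cos(t/2) sin t}``; only the first is discontinuous across the
    crack faces (theta = ±pi), where it jumps by ``2 sqrt(r)``."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    sq = np.sqrt(np.clip(r, 0.0, None))
    s2, c2 = np.sin(theta / 2), np.cos(theta / 2)
    st = np.sin(theta)
    return np.stack([sq * s2, sq * c2, sq * s2 * st, sq * c2 * st], axis=-1)


def tip_function_gradients(r, theta, eps: float = 1e-12) -> np.ndarray:
    """Partials of the branch functions w.r.t. local in-plane coordinates
    ``(rho1, rho2)`` (crack-plane extension, plane normal); shape (..., 4, 2)."""
    r = np.clip(np.asarray(r, dtype=float), eps, None)
    theta = np.asarray(theta, dtype=float)
    sq = np.sqrt(r)
    s2, c2 = np.sin(theta / 2), np.cos(theta / 2)
    st, ct = np.sin(theta), np.cos(theta)
    dr = np.stack([s2, c2, s2 * st, c2 * st], axis=-1) / (2 * sq)[..., None]
    dth = np.stack(
        [0.5 * c2, -0.5 * s2,
         0.5 * c2 * st + s2 * ct,
         -0.5 * s2 * st + c2 * ct], axis=-1
    ) * sq[..., None]
    ct_, st_ = np.cos(theta)[..., None], np.sin(theta)[..., None]
    d1 = dr * ct_ - dth * st_ / r[..., None]
    d2 = dr * st_ + dth * ct_ / r[..., None]
    return np.stack([d1, d2], axis=-1)


# ---------------------------------------------------------------------------
# shape functions
# ---------------------------------------------------------------------------


def shape_functions(xi: np.ndarray):
    """Trilinear shape values and reference gradients at points ``xi`` in
    [-1, 1]^3 -> ``(N (..., 8), dN (..., 8, 3))``."""
    xi = np.atleast_2d(xi)
    t = 1.0 + xi[:, None, :] * _CORNER_SIGNS[None, :, :]   # (Q, 8, 3)
    N = t.prod(axis=-1) / 8.0
    dN = np.empty(t.shape)
    for a in range(3):
        others = [b for b in range(3) if b != a]
        dN[..., a] = _CORNER_SIGNS[None, :, a] * t[..., others[0]] * t[..., others[1]] / 8.0
    return N, dN


def _gauss_points(n_sub: int):
    """Sub-cell 2-point Gauss rule on [-1,1]^3: points (Q,3), weight per point."""
    g = np.array([-_G1, _G1])
    centers = (2 * np.arange(n_sub) + 1) / n_sub - 1.0
    loc = (centers[:, None] + g[None, :] / n_sub).ravel()
    pts = np.stack(np.meshgrid(loc, loc, loc, indexing="ij"), axis=-1).reshape(-1, 3)
    w = 1.0 / n_sub ** 3
    return pts, np.full(len(pts), w)


# ---------------------------------------------------------------------------
# system / solution containers
# ---------------------------------------------------------------------------


@dataclass
class XFEMSystem:
    K: sp.spmatrix
    P: np.ndarray
    mesh: HexMesh
    enrichment: EnrichmentTable
    crack: CrackGeometry | None
    material: MaterialParams
    # dof -> (constant, [(other_dof, coeff), ...]); the constrained DOF equals
    # constant + sum(coeff * value(other_dof))
    constraints: dict = field(default_factory=dict)


@dataclass
class XFEMSolution:
    dofs: np.ndarray
    mesh: HexMesh
    enrichment: EnrichmentTable
    crack: CrackGeometry | None
    diagnostics: dict = field(default_factory=dict)

    @property
    def u(self) -> np.ndarray:
        """Standard nodal DOFs (N, 3)."""
        return self.dofs[: 3 * self.mesh.n_nodes].reshape(-1, 3)

    @property
    def a(self) -> np.ndarray:
        """Heaviside DOFs per node in J (|J|, 3)."""
        n = 3 * self.mesh.n_nodes
        return self.dofs[n: n + 3 * len(self.enrichment.set_J)].reshape(-1, 3)

    @property
    def c(self) -> np.ndarray:
        """Tip DOFs per node in M (|M|, 4, 3)."""
        n = 3 * self.mesh.n_nodes + 3 * len(self.enrichment.set_J)
        return self.dofs[n:].reshape(-1, 4, 3)

    def nodal_side_displacements(self, side: int) -> np.ndarray:
        """Displacement at every node approached from the given crack side.

        With shifted enrichment this is ``u_i + (side - H_i) a_i`` for nodes
        in J and plain ``u_i`` otherwise (tip enrichment vanishes at nodes).
        """
        out = self.u.copy()
        J = self.enrichment.set_J
        if len(J) and self.crack is not None:
            H = heaviside_at(self.mesh.nodes[J], self.crack)
            out[J] += (float(side) - H)[:, None] * self.a
        return out


# ---------------------------------------------------------------------------
# element basis evaluation (shared by assembly and field evaluation)
# ---------------------------------------------------------------------------


def _element_blocks(mesh: HexMesh, enr: EnrichmentTable, elem: int):
    """DOF blocks active in an element: list of (kind, node, l, dof_base).

    kind 0 = standard, 1 = Heaviside, 2 = tip branch l.
    """
    conn = mesh.elements[elem]
    blocks = [(0, int(n), 0, 3 * int(n)) for n in conn]
    nJ = 3 * mesh.n_nodes
    nM = nJ + 3 * len(enr.set_J)
    for n in conn:
        s = enr.heav_slot[n]
        if s >= 0:
            blocks.append((1, int(n), 0, nJ + 3 * int(s)))
    for n in conn:
        s = enr.tip_slot[n]
        if s >= 0:
            for l in range(4):
                blocks.append((2, int(n), l, nM + 12 * int(s) + 3 * l))
    return blocks


def _eval_blocks(mesh, enr, crack, elem, xi, side=None, need_grads=True):
    """Evaluate every active block's scalar value (and gradient) at reference
    points ``xi`` of element ``elem``.  ``side`` overrides the crack side at
    points lying exactly on the plane."""
    conn = mesh.elements[elem]
    corners = mesh.nodes[conn]
    N, dN_ref = shape_functions(xi)
    h = mesh.element_size
    dN = dN_ref * (2.0 / h)
    x = N @ corners
    blocks = _element_blocks(mesh, enr, elem)
    nb = len(blocks)
    Q = len(x)
    vals = np.empty((Q, nb))
    grads = np.empty((Q, nb, 3)) if need_grads else None

    local = {int(n): k for k, n in enumerate(conn)}
    if crack is not None and any(b[0] != 0 for b in blocks):
        psi, ww, dd = crack_coords(x, crack)
        s = np.where(psi >= 0.0, 1.0, -1.0)
        if side is not None:
            # the reference-coordinate round trip perturbs on-plane points by
            # ~1e-15 mm, so the side hint applies within a roundoff band
            s = np.where(np.abs(psi) <= 1e-9, np.broadcast_to(side, psi.shape), s)
        H_nodes = heaviside_at(mesh.nodes, crack)
        rho1 = dd - crack.depth
        r = np.hypot(rho1, psi)
        theta = np.arctan2(psi, rho1)
        theta = np.where((np.abs(psi) <= 1e-9) & (rho1 < 0), s * np.pi, theta)
        F = tip_functions(r, theta)
        dF = tip_function_gradients(r, theta)
        psi_n, _, dd_n = crack_coords(mesh.nodes, crack)

    for k, (kind, node, l, _) in enumerate(blocks):
        li = local[node]
        if kind == 0:
            vals[:, k] = N[:, li]
            if need_grads:
                grads[:, k] = dN[:, li]
        elif kind == 1:
            fac = s - H_nodes[node]
            vals[:, k] = N[:, li] * fac
            if need_grads:
                grads[:, k] = dN[:, li] * fac[:, None]
        else:
            r1n = dd_n[node] - crack.depth
            th_n = np.arctan2(psi_n[node], r1n)
            if psi_n[node] == 0.0 and r1n < 0:
                th_n = np.pi  # node tie-break toward the + side
            Fn = tip_functions(np.hypot(r1n, psi_n[node]), th_n)[l]
            shifted = F[:, l] - Fn
            vals[:, k] = N[:, li] * shifted
            if need_grads:
                gF = dF[:, l, 0][:, None] * crack.d + dF[:, l, 1][:, None] * crack.n
                grads[:, k] = dN[:, li] * shifted[:, None] + N[:, li, None] * gF
    sides = s if (crack is not None and any(b[0] != 0 for b in blocks)) else np.ones(Q)
    return blocks, vals, grads, sides


def _B_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices from block gradients: (Q, nb, 3) ->
    (Q, 6, 3*nb), Voigt (xx, yy, zz, xy, yz, zx) with engineering shears."""
    Q, nb, _ = grads.shape
    B = np.zeros((Q, 6, 3 * nb))
    gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
    cols = 3 * np.arange(nb)
    B[:, 0, cols + 0] = gx
    B[:, 1, cols + 1] = gy
    B[:, 2, cols + 2] = gz
    B[:, 3, cols + 0] = gy
    B[:, 3, cols + 1] = gx
    B[:, 4, cols + 1] = gz
    B[:, 4, cols + 2] = gy
    B[:, 5, cols + 0] = gz
    B[:, 5, cols + 2] = gx
    return B


def _apply_bbar(B: np.ndarray, grads: np.ndarray, w: np.ndarray, groups: np.ndarray):
    """Mean-dilatation correction, averaging gradients within each group
    (crack side) separately."""
    for g in np.unique(groups):
        sel = groups == g
        wg = w[sel]
        gbar = (grads[sel] * wg[:, None, None]).sum(axis=0) / wg.sum()  # (nb, 3)
        corr = (gbar[None] - grads[sel]) / 3.0                          # (q, nb, 3)
        nb = grads.shape[1]
        cols = 3 * np.arange(nb)
        for c in range(3):
            for row in range(3):
                B[np.nonzero(sel)[0][:, None], row, (cols + c)[None, :]] += corr[:, :, c]
    return B


def _element_stiffness(C, B, w):
    CB = np.einsum("ij,qjb->qib", C, B)
    return np.einsum("qia,qib->ab", B * w[:, None, None], CB)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble(
    mesh: HexMesh,
    enrichment: EnrichmentTable,
    crack: CrackGeometry | None,
    material: MaterialParams,
    bbar: bool = True,
    subcells: int = 4,
) -> XFEMSystem:
    """Assemble the enriched stiffness matrix (no body forces: ``P = 0``).

    Uncut elements share one stiffness (the mesh is uniform) which is
    computed once and scattered; cut elements are integrated on a
    ``subcells^3`` refinement with 2x2x2 Gauss per sub-cell.
    """
    h = mesh.element_size
    if np.any(h <= 0):
        raise AssemblyError("non-positive element Jacobian")
    detJ = h.prod() / 8.0
    C = material.C

    rows, cols, data = [], [], []

    def scatter(dofs, Ke):
        d = np.asarray(dofs)
        rows.append(np.repeat(d, len(d)))
        cols.append(np.tile(d, len(d)))
        data.append(Ke.ravel())

    # one stiffness for every uncut element
    xi, w = _gauss_points(1)
    N, dN_ref = shape_functions(xi)
    grads = dN_ref * (2.0 / h)
    B = _B_matrices(grads)
    wq = w * detJ
    if bbar:
        B = _apply_bbar(B, grads, wq, np.zeros(len(wq)))
    K_uncut = _element_stiffness(C, B, wq)
    uncut = np.nonzero(enrichment.elem_type == UNCUT)[0]
    if len(uncut):
        conn = mesh.elements[uncut]                       # (E, 8)
        dofs = (3 * conn[:, :, None] + np.arange(3)).reshape(len(uncut), 24)
        rows.append(np.repeat(dofs, 24, axis=1).ravel())
        cols.append(np.tile(dofs, (1, 24)).ravel())
        data.append(np.broadcast_to(K_uncut.ravel(), (len(uncut), 576)).ravel())

    # cut elements: sub-cell quadrature with side-resolved enrichment
    xi_c, w_c = _gauss_points(subcells)
    wq_c = w_c * detJ
    for e in np.nonzero(enrichment.elem_type != UNCUT)[0]:
        blocks, _, grads, sides = _eval_blocks(mesh, enrichment, crack, e, xi_c)
        B = _B_matrices(grads)
        if bbar:
            B = _apply_bbar(B, grads, wq_c, sides)
        Ke = _element_stiffness(C, B, wq_c)
        scatter([b[3] + c for b in blocks for c in range(3)], Ke)

    n = enrichment.n_dofs
    K = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    K = 0.5 * (K + K.T)  # symmetrize away roundoff
    return XFEMSystem(K, np.zeros(n), mesh, enrichment, crack, material)


# ---------------------------------------------------------------------------
# boundary conditions and solve
# ---------------------------------------------------------------------------


def apply_boundary_conditions(system: XFEMSystem, bcs: DisplacementBCSet) -> XFEMSystem:
    """Record Dirichlet constraints (imposed later by exact elimination).

    Side-resolved values convert through the shifted-enrichment trace
    ``u(side s at node j) = u_j + (s - H_j) a_j``: with both faces prescribed
    the Heaviside DOF carries half the jump, ``a_j = (u+ - u-)/2``; with one
    face prescribed the standard DOF is eliminated against ``a_j``.
    """
    enr = system.enrichment
    mesh = system.mesh

    def set_pivot(dof, const, terms=()):
        if dof in system.constraints:
            old = system.constraints[dof]
            if abs(old[0] - const) > 1e-9 or len(old[1]) != len(terms):
                raise ConflictError(f"conflicting constraints on DOF {dof}")
            return
        system.constraints[dof] = (float(const), list(terms))

    for node in np.asarray(bcs.zero_nodes, dtype=int):
        for c in range(3):
            set_pivot(3 * node + c, 0.0)
        if enr.heav_slot[node] >= 0:
            for c in range(3):
                set_pivot(int(enr.heav_dof(node, c)), 0.0)
        if enr.tip_slot[node] >= 0:
            for l in range(4):
                for c in range(3):
                    set_pivot(int(enr.tip_dof(node, l, c)), 0.0)

    by_node: dict = {}
    for node, side, vec in bcs.entries:
        by_node.setdefault(int(node), {})[int(side)] = np.asarray(vec, dtype=float)

    if system.crack is not None:
        H_nodes = heaviside_at(mesh.nodes, system.crack)
    for node, sides in by_node.items():
        if node >= mesh.n_nodes:
            raise ConsistencyError(f"BC node {node} does not exist")
        if 0 in sides and len(sides) == 1:
            for c in range(3):
                set_pivot(3 * node + c, sides[0][c])
            continue
        if enr.heav_slot[node] < 0:
            raise ConsistencyError(
                f"side-resolved BC on node {node}, which carries no Heaviside DOF"
            )
        Hj = H_nodes[node]
        if 1 in sides and -1 in sides:
            gp, gm = sides[1], sides[-1]
            a = 0.5 * (gp - gm)
            u = gp if Hj > 0 else gm
            for c in range(3):
                set_pivot(int(enr.heav_dof(node, c)), a[c])
                set_pivot(3 * node + c, u[c])
        else:
            (s, g), = sides.items()
            fac = s - Hj
            for c in range(3):
                if fac == 0.0:
                    set_pivot(3 * node + c, g[c])
                else:
                    set_pivot(3 * node + c, g[c], [(int(enr.heav_dof(node, c)), -fac)])
    return system


def solve_system(system: XFEMSystem, residual_tol: float = 1e-8) -> XFEMSolution:
    """Eliminate constraints, factorize, solve, and verify the residual.

    Enriched DOFs whose basis has no support on their own side (zero
    stiffness) are automatically fixed to zero.  A singular reduced system
    raises :class:`SolverError` naming the likely cause.
    """
    K = system.K.tocsr()
    n = K.shape[0]
    diag = K.diagonal()
    scale = diag.max() if n else 1.0
    for dof in np.nonzero(diag <= 1e-12 * scale)[0]:
        system.constraints.setdefault(int(dof), (0.0, []))

    pivoted = np.zeros(n, dtype=bool)
    for dof in system.constraints:
        pivoted[dof] = True
    free = np.nonzero(~pivoted)[0]
    col_of = -np.ones(n, dtype=int)
    col_of[free] = np.arange(len(free))

    g0 = np.zeros(n)
    t_rows, t_cols, t_vals = list(free), list(col_of[free]), [1.0] * len(free)
    for dof, (const, terms) in system.constraints.items():
        g0[dof] = const
        for other, coeff in terms:
            if pivoted[other]:
                raise ConflictError(
                    f"constraint on DOF {dof} references constrained DOF {other}"
                )
            t_rows.append(dof)
            t_cols.append(col_of[other])
            t_vals.append(float(coeff))
    T = sp.coo_matrix((t_vals, (t_rows, t_cols)), shape=(n, len(free))).tocsr()

    rhs_full = system.P - K @ g0
    K_red = (T.T @ K @ T).tocsc()
    P_red = T.T @ rhs_full

    diagnostics = {"n_dofs": n, "n_free": len(free), "n_constraints": int(pivoted.sum())}
    if len(free) == 0:
        q = np.zeros(0)
        residual = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("error", spla.MatrixRankWarning)
            try:
                lu = spla.splu(K_red)
            except (RuntimeError, spla.MatrixRankWarning) as exc:
                raise SolverError(
                    "reduced stiffness matrix is singular; rigid modes are likely "
                    "unconstrained (no/insufficient zero-displacement region)"
                ) from exc
        udiag = np.abs(lu.U.diagonal())
        if udiag.min() <= 1e-12 * udiag.max():
            raise SolverError(
                "reduced stiffness matrix is numerically singular; rigid modes "
                "are likely unconstrained (no/insufficient zero-displacement region)"
            )
        q = lu.solve(P_red)
        if not np.all(np.isfinite(q)):
            raise SolverError("solver returned non-finite values (singular system?)")
        rnorm = np.linalg.norm(K_red @ q - P_red)
        residual = float(rnorm / max(np.linalg.norm(P_red), 1e-300))
        if residual > residual_tol:
            raise SolverError(f"relative residual {residual:.2e} exceeds {residual_tol:.0e}")
    diagnostics["residual"] = residual
    a_full = T @ q + g0
    return XFEMSolution(a_full, system.mesh, system.enrichment, system.crack, diagnostics)


# ---------------------------------------------------------------------------
# field evaluation
# ---------------------------------------------------------------------------


def displacement_at(sol: XFEMSolution, points, side_hint="auto"):
    """Evaluate the enriched displacement field at world points.

    ``side_hint`` in {"auto", +1, -1} resolves the branch taken at points
    exactly on the crack plane ("auto" follows the +1 tie-break).  Raises
    :class:`LocationError` for points outside the mesh.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    mesh, enr, crack = sol.mesh, sol.enrichment, sol.crack
    elems = mesh.elem_index_of(pts)
    if np.any(elems < 0):
        bad = pts[elems < 0][0]
        raise LocationError(f"point {bad} lies outside the mesh")
    side = None if side_hint == "auto" else float(side_hint)
    out = np.empty_like(pts)
    for e in np.unique(elems):
        sel = elems == e
        xi = mesh.local_coords(pts[sel], np.full(sel.sum(), e))
        blocks, vals, _, _ = _eval_blocks(mesh, enr, crack, int(e), xi,
                                          side=side, need_grads=False)
        dof_idx = np.array([[b[3] + c for c in range(3)] for b in blocks])
        coeffs = sol.dofs[dof_idx]          # (nb, 3)
        out[sel] = vals @ coeffs
    return out[0] if np.asarray(points).ndim == 1 else out
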
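"""Independent conforming-FEM oracle with node duplication along a plane.

Used to verify the enriched solver: when the crack coincides with element
faces, splitting the mesh by duplicating the on-plane nodes and assembling a
plain trilinear hexahedral model spans exactly the same solution space as
Heaviside enrichment.  Everything here (shape functions, B matrices, mean
dilatation, assembly, elimination, solve) is written from scratch and shares
no code with the package's solver.
"""
import numpy as np

_CORNERS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
)
_SIGNS = 2.0 * _CORNERS - 1.0
_G = 1.0 / np.sqrt(3.0)


def _shape_grads(xi):
    """Gradients of the 8 trilinear shape functions at one reference point."""
    g = np.empty((8, 3))
    for i, s in enumerate(_SIGNS):
        for a in range(3):
            term = s[a] / 8.0
            for b in range(3):
                if b != a:
                    term *= 1.0 + xi[b] * s[b]
            g[i, a] = term
    return g


def hex_stiffness(h, E, nu, bbar=True):
    """Stiffness of one axis-aligned hexahedron with edge lengths ``h``."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    h = np.asarray(h, dtype=float)
    detJ = h.prod() / 8.0
    pts = [np.array([sx * _G, sy * _G, sz * _G])
           for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    grads = [(_shape_grads(xi) * (2.0 / h)) for xi in pts]
    gbar = np.mean(grads, axis=0)

    K = np.zeros((24, 24))
    for g in grads:
        geff = g.copy()
        B = np.zeros((6, 24))
        for i in range(8):
            gx, gy, gz = geff[i]
            bx, by, bz = (gbar[i] - geff[i]) / 3.0 if bbar else (0.0, 0.0, 0.0)
            c = 3 * i
            B[0, c], B[1, c + 1], B[2, c + 2] = gx, gy, gz
            if bbar:
                B[:3, c] += bx
                B[:3, c + 1] += by
                B[:3, c + 2] += bz
            B[3, c], B[3, c + 1] = gy, gx
            B[4, c + 1], B[4, c + 2] = gz, gy
            B[5, c], B[5, c + 2] = gz, gx
        K += B.T @ C @ B * detJ
    return K


class DuplicatedNodeFEM:
    """Conforming FEM on a uniform hex grid, with nodes on a splitting plane
    duplicated so elements on either side deform independently."""

    def __init__(self, nodes, elements, h, plane_x, E, nu, bbar=True):
        nodes = np.asarray(nodes, dtype=float)
        elements = np.asarray(elements, dtype=int)
        on_plane = np.abs(nodes[:, 0] - plane_x) < 1e-9
        dup_index = {}
        new_nodes = list(map(tuple, nodes))
        for n in np.nonzero(on_plane)[0]:
            dup_index[n] = len(new_nodes)
            new_nodes.append(tuple(nodes[n]))
        self.nodes = np.asarray(new_nodes)
        self.plus_copy = dup_index  # original id -> minus-side duplicate id

        elems = elements.copy()
        centro = nodes[elements].mean(axis=1)
        minus = centro[:, 0] < plane_x
        for e in np.nonzero(minus)[0]:
            for k in range(8):
                n = elems[e, k]
                if n in dup_index:
                    elems[e, k] = dup_index[n]
        self.elements = elems
        self.Ke = hex_stiffness(h, E, nu, bbar)
        n_dof = 3 * len(self.nodes)
        K = np.zeros((n_dof, n_dof))
        for conn in self.elements:
            dofs = np.concatenate([[3 * n, 3 * n + 1, 3 * n + 2] for n in conn])
            K[np.ix_(dofs, dofs)] += self.Ke
        self.K = K

    def solve(self, fixed: dict):
        """Dirichlet solve; ``fixed`` maps dof index -> value."""
        n = self.K.shape[0]
        free = np.array([i for i in range(n) if i not in fixed])
        g = np.zeros(n)
        for d, v in fixed.items():
            g[d] = v
        rhs = -self.K[np.ix_(free, np.arange(n))] @ g
        u = g.copy()
        u[free] = np.linalg.solve(self.K[np.ix_(free, free)], rhs[: len(free)])
        return u.reshape(-1, 3)
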
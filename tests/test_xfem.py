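"""Enriched solver: tip functions, assembly invariants, patch test, BC
conversion, oracle equivalence and field evaluation."""
import numpy as np
import pytest

from retractx.crack import CrackGeometry
from retractx.errors import ConfigurationError, ConsistencyError, SolverError
from retractx.mesh import build_hex_mesh, classify_enrichment
from retractx.tracking import DisplacementBCSet
from retractx.volume import LabelVolume
from retractx.xfem import (MaterialParams, apply_boundary_conditions, assemble,
                           displacement_at, heaviside_at, solve_system,
                           tip_functions, tip_function_gradients)

from fem_oracle import DuplicatedNodeFEM


def _empty_enrichment(mesh):
    import warnings

    from retractx.crack import CrackGeometry as CG

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return classify_enrichment(
            mesh, CG((1e5, 0, 0), (1, 0, 0), (0, 0, -1), 1.0, 1.0)
        )


class TestMaterial:
    def test_invalid_parameters(self):
        with pytest.raises(ConfigurationError):
            MaterialParams(E=-1.0)
        with pytest.raises(ConfigurationError):
            MaterialParams(nu=0.5)

    def test_constitutive_matrix_symmetric_pd(self):
        C = MaterialParams(3000.0, 0.45).C
        assert np.allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) > 0)


class TestHeavisideAndTips:
    def test_heaviside_branches(self, simple_crack):
        xs = simple_crack.o + 5.0 * simple_crack.d
        assert heaviside_at(xs + simple_crack.n, simple_crack)[0] == 1.0
        assert heaviside_at(xs - simple_crack.n, simple_crack)[0] == -1.0
        assert heaviside_at(xs, simple_crack)[0] == 1.0

    def test_tip_function_closed_forms(self):
        assert np.allclose(tip_functions(1.0, 0.0), [0, 1, 0, 0], atol=1e-15)
        assert np.allclose(tip_functions(4.0, np.pi), [2, 0, 0, 0], atol=1e-12)

    def test_first_branch_jumps_others_continuous(self):
        """Across theta = +-pi the first branch jumps by 2 sqrt(r); the other
        three are continuous there."""
        rng = np.random.default_rng(0)
        r = rng.uniform(0.01, 25.0, 50)
        eps = 1e-9
        up = tip_functions(r, np.pi - eps)
        dn = tip_functions(r, -np.pi + eps)
        jump = up - dn
        assert np.abs(jump[:, 0] - 2.0 * np.sqrt(r)).max() < 1e-6
        assert np.abs(jump[:, 1:]).max() < 1e-6

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            rho = rng.uniform(-5, 5, 2)
            if np.hypot(*rho) < 0.5:
                continue
            r, th = np.hypot(rho[0], rho[1]), np.arctan2(rho[1], rho[0])
            g = tip_function_gradients(r, th)
            h = 1e-6
            for axis in range(2):
                d = np.zeros(2)
                d[axis] = h
                rp = np.hypot(*(rho + d))
                tp = np.arctan2(*(rho + d)[::-1])
                rm = np.hypot(*(rho - d))
                tm = np.arctan2(*(rho - d)[::-1])
                fd = (tip_functions(rp, tp) - tip_functions(rm, tm)) / (2 * h)
                assert np.abs(g[:, axis] - fd).max() < 1e-5


class TestAssembly:
    def test_rigid_translations_annihilated(self, cube_mesh):
        sys0 = assemble(cube_mesh, _empty_enrichment(cube_mesh), None,
                        MaterialParams())
        K = sys0.K
        scale = np.abs(K).max()
        for c in range(3):
            t = np.zeros(K.shape[0])
            t[c::3] = 1.0
            assert np.abs(K @ t).max() <= 1e-9 * scale

    def test_symmetry_and_positive_semidefinite(self, cube_mesh, simple_crack):
        crack = CrackGeometry((7.2, 7.0, 15.0), (1, 0, 0), (0, 0, -1), 100.0, 50.0)
        enr = classify_enrichment(cube_mesh, crack)
        sys0 = assemble(cube_mesh, enr, crack, MaterialParams())
        K = sys0.K.toarray()
        assert np.abs(K - K.T).max() < 1e-9 * np.abs(K).max()
        evals = np.linalg.eigvalsh(K)
        assert evals.min() > -1e-9 * np.abs(K).max()

    @pytest.mark.parametrize("E,nu", [(3000.0, 0.45), (1000.0, 0.3),
                                      (5.0e4, 0.0), (200.0, 0.49)])
    def test_patch_test_linear_field_exact(self, cube_mesh, E, nu):
        """Linear displacement imposed on the boundary is reproduced exactly
        at interior nodes for any material in range."""
        A = np.array([[0.01, 0.002, 0.0], [0.0, -0.003, 0.001],
                      [0.004, 0.0, 0.005]])
        u_exact = cube_mesh.nodes @ A.T
        boundary = np.any((cube_mesh.node_lattice == 0)
                          | (cube_mesh.node_lattice == 3), axis=1)
        bcs = DisplacementBCSet(
            [(int(n), 0, u_exact[n]) for n in np.nonzero(boundary)[0]])
        sys0 = assemble(cube_mesh, _empty_enrichment(cube_mesh), None,
                        MaterialParams(E, nu))
        sol = solve_system(apply_boundary_conditions(sys0, bcs))
        rel = np.abs(sol.u - u_exact).max() / np.abs(u_exact).max()
        assert rel < 1e-8

    def test_dirichlet_scaling_invariance(self, cube_mesh):
        """With all-Dirichlet driving, displacements are invariant under
        scaling of the Young modulus."""
        boundary = np.any((cube_mesh.node_lattice == 0)
                          | (cube_mesh.node_lattice == 3), axis=1)
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, (cube_mesh.n_nodes, 3))
        bcs = DisplacementBCSet(
            [(int(n), 0, vals[n]) for n in np.nonzero(boundary)[0]])
        sols = []
        for E in (3000.0, 6000.0):
            sys0 = assemble(cube_mesh, _empty_enrichment(cube_mesh), None,
                            MaterialParams(E, 0.45))
            sols.append(solve_system(apply_boundary_conditions(sys0, bcs)).u)
        assert np.abs(sols[0] - sols[1]).max() < 1e-9


@pytest.fixture
def cut_bar():
    """4x2x2-element bar with the crack on the mid element interface."""
    lab = LabelVolume(np.ones((20, 10, 10), dtype=np.uint8), np.eye(4))
    mesh = build_hex_mesh(lab, 5.0)
    crack = CrackGeometry((9.5, -0.5, 9.5), (1, 0, 0), (0, 0, -1), 1000.0, 1000.0)
    enr = classify_enrichment(mesh, crack)
    return mesh, crack, enr


class TestOracleEquivalence:
    def test_face_aligned_crack_matches_duplicated_node_fem(self, cut_bar):
        """Heaviside XFEM with the crack on element faces equals a conforming
        FEM with duplicated interface nodes, node by node, to 1e-6 mm."""
        mesh, crack, enr = cut_bar
        mat = MaterialParams(3000.0, 0.45)
        left = mesh.nodes[:, 0] < 0.0
        right = mesh.nodes[:, 0] > 19.0
        rng = np.random.default_rng(2)
        g_left = rng.normal(0, 1, 3) + np.array([-2.0, 0, 0])
        g_right = rng.normal(0, 1, 3) + np.array([2.0, 0, 0])
        entries = [(int(n), 0, g_left) for n in np.nonzero(left)[0]]
        entries += [(int(n), 0, g_right) for n in np.nonzero(right)[0]]
        bcs = DisplacementBCSet(entries)
        sys0 = assemble(mesh, enr, crack, mat)
        sol = solve_system(apply_boundary_conditions(sys0, bcs))

        fem = DuplicatedNodeFEM(mesh.nodes, mesh.elements, mesh.element_size,
                                plane_x=9.5, E=mat.E, nu=mat.nu)
        fixed = {}
        for n in np.nonzero(left)[0]:
            for c in range(3):
                fixed[3 * n + c] = g_left[c]
                if n in fem.plus_copy:
                    fixed[3 * fem.plus_copy[n] + c] = g_left[c]
        for n in np.nonzero(right)[0]:
            for c in range(3):
                fixed[3 * n + c] = g_right[c]
        u_fem = fem.solve(fixed)

        u_plus = sol.nodal_side_displacements(+1)
        u_minus = sol.nodal_side_displacements(-1)
        for n in range(mesh.n_nodes):
            x = mesh.nodes[n, 0]
            if x > 9.5 + 1e-9:
                assert np.abs(u_plus[n] - u_fem[n]).max() < 1e-6
            elif x < 9.5 - 1e-9:
                assert np.abs(u_minus[n] - u_fem[n]).max() < 1e-6
            else:  # interface: + side keeps the original id, - the duplicate
                assert np.abs(u_plus[n] - u_fem[n]).max() < 1e-6
                assert np.abs(u_minus[n] - u_fem[fem.plus_copy[n]]).max() < 1e-6


class TestBoundaryConditions:
    def test_side_resolved_constraints_reproduce_traces(self, cut_bar):
        """Prescribing u+ and u- at interface nodes yields exactly those
        side displacements (and a Heaviside DOF of half the jump)."""
        mesh, crack, enr = cut_bar
        g_plus = np.array([7.0, 0.0, 0.0])
        g_minus = np.array([-6.3, 0.0, 0.0])
        entries = []
        iface = np.nonzero(np.abs(mesh.nodes[:, 0] - 9.5) < 1e-9)[0]
        for n in iface:
            entries.append((int(n), +1, g_plus))
            entries.append((int(n), -1, g_minus))
        outer = np.nonzero((mesh.nodes[:, 0] < 0) | (mesh.nodes[:, 0] > 19))[0]
        entries += [(int(n), 0, np.sign(mesh.nodes[n, 0] - 9.5) * np.array([1.0, 0, 0]))
                    for n in outer]
        bcs = DisplacementBCSet(entries)
        sys0 = assemble(mesh, crack=crack, enrichment=enr,
                        material=MaterialParams())
        sol = solve_system(apply_boundary_conditions(sys0, bcs))
        u_plus = sol.nodal_side_displacements(+1)
        u_minus = sol.nodal_side_displacements(-1)
        for n in iface:
            assert np.allclose(u_plus[n], g_plus, atol=1e-9)
            assert np.allclose(u_minus[n], g_minus, atol=1e-9)
            slot = enr.heav_slot[n]
            assert np.allclose(sol.a[slot], (g_plus - g_minus) / 2, atol=1e-9)

    def test_equal_sides_mean_no_jump(self, cut_bar):
        mesh, crack, enr = cut_bar
        g = np.array([0.5, 0.1, 0.0])
        iface = np.nonzero(np.abs(mesh.nodes[:, 0] - 9.5) < 1e-9)[0]
        entries = [(int(n), s, g) for n in iface for s in (+1, -1)]
        outer = np.nonzero((mesh.nodes[:, 0] < 0) | (mesh.nodes[:, 0] > 19))[0]
        entries += [(int(n), 0, np.zeros(3)) for n in outer]
        sys0 = assemble(mesh, enr, crack, MaterialParams())
        sol = solve_system(apply_boundary_conditions(sys0, DisplacementBCSet(entries)))
        for n in iface:
            assert np.allclose(sol.a[enr.heav_slot[n]], 0.0, atol=1e-9)

    def test_zero_region_nodes_fully_fixed(self, cube_mesh):
        enr = _empty_enrichment(cube_mesh)
        top = np.nonzero(cube_mesh.nodes[:, 2] > 14.0)[0]
        bottom = np.nonzero(cube_mesh.nodes[:, 2] < 0.0)[0]
        entries = [(int(n), 0, np.array([0.0, 0.0, -1.0])) for n in top]
        bcs = DisplacementBCSet(entries, zero_nodes=bottom)
        sys0 = assemble(cube_mesh, enr, None, MaterialParams())
        sol = solve_system(apply_boundary_conditions(sys0, bcs))
        assert np.abs(sol.u[bottom]).max() == 0.0

    def test_side_bc_on_unenriched_node_raises(self, cube_mesh):
        enr = _empty_enrichment(cube_mesh)
        sys0 = assemble(cube_mesh, enr, None, MaterialParams())
        bcs = DisplacementBCSet([(0, +1, np.ones(3))])
        with pytest.raises(ConsistencyError):
            apply_boundary_conditions(sys0, bcs)

    def test_unconstrained_system_raises_solver_error(self, cube_mesh):
        sys0 = assemble(cube_mesh, _empty_enrichment(cube_mesh), None,
                        MaterialParams())
        with pytest.raises(SolverError):
            solve_system(apply_boundary_conditions(sys0, DisplacementBCSet(
                [(0, 0, np.zeros(3))])))


class TestDisplacementAt:
    def test_nodal_interpolation_property(self, cube_mesh):
        enr = _empty_enrichment(cube_mesh)
        sys0 = assemble(cube_mesh, enr, None, MaterialParams())
        boundary = np.any((cube_mesh.node_lattice == 0)
                          | (cube_mesh.node_lattice == 3), axis=1)
        A = np.array([[0.02, 0, 0], [0, 0.01, 0], [0, 0, -0.01]])
        u_exact = cube_mesh.nodes @ A.T
        bcs = DisplacementBCSet(
            [(int(n), 0, u_exact[n]) for n in np.nonzero(boundary)[0]])
        sol = solve_system(apply_boundary_conditions(sys0, bcs))
        # interior point of an uncut element: plain trilinear interpolation
        x = np.array([7.5, 7.5, 7.5])
        assert np.allclose(displacement_at(sol, x), x @ A.T, atol=1e-8)

    def test_jump_equals_twice_heaviside_sum(self, cut_bar):
        mesh, crack, enr = cut_bar
        g_plus, g_minus = np.array([1.0, 0, 0]), np.array([-1.0, 0, 0])
        iface = np.nonzero(np.abs(mesh.nodes[:, 0] - 9.5) < 1e-9)[0]
        entries = [(int(n), s, g if s > 0 else -g)
                   for n in iface for s, g in ((+1, g_plus), (-1, g_plus))]
        outer = np.nonzero((mesh.nodes[:, 0] < 0) | (mesh.nodes[:, 0] > 19))[0]
        entries += [(int(n), 0, np.sign(mesh.nodes[n, 0] - 9.5) * g_plus)
                    for n in outer]
        sys0 = assemble(mesh, enr, crack, MaterialParams())
        sol = solve_system(apply_boundary_conditions(sys0, DisplacementBCSet(entries)))
        x = np.array([9.5, 4.0, 5.0])
        jump = displacement_at(sol, x, side_hint=+1) \
            - displacement_at(sol, x, side_hint=-1)
        # independent evaluation of 2 sum(phi_j a_j) at this point
        from retractx.mesh import FULLY_CUT

        e = int(mesh.elem_index_of(np.array([9.4, 4.0, 5.0]))[0])
        xi = mesh.local_coords(np.array([[9.5, 4.0, 5.0]]), np.array([e]))[0]
        from retractx.xfem import shape_functions

        N, _ = shape_functions(xi[None])
        expected = np.zeros(3)
        for k, n in enumerate(mesh.elements[e]):
            slot = enr.heav_slot[n]
            if slot >= 0:
                expected += 2.0 * N[0, k] * sol.a[slot]
        assert np.allclose(jump, expected, atol=1e-9)

    def test_point_outside_mesh_raises(self, cube_mesh):
        enr = _empty_enrichment(cube_mesh)
        sys0 = assemble(cube_mesh, enr, None, MaterialParams())
        bcs = DisplacementBCSet([(int(n), 0, np.zeros(3))
                                 for n in range(cube_mesh.n_nodes)])
        sol = solve_system(apply_boundary_conditions(sys0, bcs))
        from retractx.errors import LocationError

        with pytest.raises(LocationError):
            displacement_at(sol, np.array([100.0, 0.0, 0.0]))
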
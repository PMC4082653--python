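"""Retractor templates, rigid transforms/ICP, CPD and BC extraction."""
import numpy as np
import pytest

from retractx.cloud import PointCloud
from retractx.cpd import CPDParams, CPDResult, cpd_nonrigid_register
from retractx.crack import CrackGeometry, crack_coords, fit_plane
from retractx.errors import (ConflictError, ConfigurationError, GeometryError,
                             RegistrationError)
from retractx.mesh import build_hex_mesh, classify_enrichment
from retractx.synthetic import GroundTruthField, simulate_lrs_cloud
from retractx.tracking import (DisplacementBCSet, RetractorModel,
                               RigidTransform, apply_rigid,
                               blade_contact_template, build_retractor_cloud,
                               extract_contact_bcs, rigid_augment,
                               track_blade_displacements)
from retractx.volume import LabelVolume

from conftest import rotation_matrix

PROBE = np.array([[0.0, 0.0, 0.0], [14.0, 0.0, 0.0],
                  [0.0, 0.0, -60.0], [14.0, 0.0, -60.0]])


class TestTemplates:
    def test_grid_counts_both_faces(self):
        cloud = build_retractor_cloud(PROBE, RetractorModel(14.0, 60.0, 2.0, 1.0))
        assert len(cloud) == 2 * 15 * 61
        assert set(cloud.labels.tolist()) == {"+", "-"}
        # faces sit half a thickness on either side of the probe plane
        y = cloud.points[:, 1]
        assert set(np.round(y, 9).tolist()) == {1.0, -1.0}

    def test_rotation_equivariance(self):
        R = rotation_matrix([0.3, 1.0, -0.2], 0.6)
        t = np.array([5.0, -2.0, 1.0])
        a = build_retractor_cloud(PROBE, RetractorModel(14, 60, 2, 2.0))
        b = build_retractor_cloud(PROBE @ R.T + t, RetractorModel(14, 60, 2, 2.0))
        moved = a.points @ R.T + t
        # the grids coincide as sets (axis signs may flip)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(b.points).query(moved)
        assert d.max() < 1e-9

    def test_plane_refit_of_cloud(self):
        cloud = build_retractor_cloud(PROBE, RetractorModel())
        _, n = fit_plane(cloud.points)
        assert min(np.abs(n - [0, 1, 0]).max(), np.abs(n + [0, 1, 0]).max()) < 1e-9

    def test_collinear_probe_rejected(self):
        with pytest.raises(GeometryError):
            build_retractor_cloud(np.outer(np.arange(4.0), [1, 1, 0]),
                                  RetractorModel())


class TestRigidTransform:
    def test_non_orthonormal_rejected(self):
        m = np.eye(4)
        m[0, 0] = 2.0
        with pytest.raises(GeometryError):
            RigidTransform(tuple(map(tuple, m)))

    def test_identity_and_translation(self):
        cloud = PointCloud(np.random.default_rng(0).normal(size=(20, 3)))
        ident = apply_rigid(cloud, RigidTransform.identity())
        assert np.array_equal(ident.points, cloud.points)
        T = RigidTransform.from_Rt(np.eye(3), np.array([1.0, 2.0, 3.0]))
        assert np.allclose(apply_rigid(cloud, T).points, cloud.points + [1, 2, 3])

    def test_compose_with_inverse_is_identity(self):
        R = rotation_matrix([1, 1, 1], 1.1)
        T = RigidTransform.from_Rt(R, np.array([4.0, -1.0, 2.0]))
        eye = T.compose(T.inverse()).m
        assert np.abs(eye - np.eye(4)).max() < 1e-12

    def test_lengths_preserved(self):
        rng = np.random.default_rng(1)
        cloud = PointCloud(rng.normal(size=(30, 3)))
        T = RigidTransform.from_Rt(rotation_matrix([0, 1, 0], 0.4), np.ones(3))
        out = apply_rigid(cloud, T)
        d0 = np.linalg.norm(cloud.points[1:] - cloud.points[:-1], axis=1)
        d1 = np.linalg.norm(out.points[1:] - out.points[:-1], axis=1)
        assert np.abs(d0 - d1).max() < 1e-12


@pytest.fixture
def template():
    return build_retractor_cloud(PROBE, RetractorModel(14.0, 60.0, 2.0, 1.0))


class TestRigidAugment:
    def test_exact_pose_recovery(self, template):
        R = rotation_matrix([0.1, 0.9, 0.2], 0.08)
        t = np.array([2.0, 5.0, -1.0])
        scan = PointCloud(template.points @ R.T + t)
        aug, T, rms = rigid_augment(template, scan)
        assert np.abs(T.R - R).max() < 1e-6
        assert np.abs(T.t - t).max() < 1e-6
        assert rms < 1e-6

    def test_self_registration_is_identity(self, template):
        aug, T, rms = rigid_augment(template, PointCloud(template.points))
        assert np.abs(T.m - np.eye(4)).max() < 1e-9

    def test_idempotent_on_own_output(self, template):
        scan = PointCloud(template.points + np.array([0.0, 5.0, 0.0]))
        aug1, T1, _ = rigid_augment(template, scan)
        aug2, T2, _ = rigid_augment(template, PointCloud(aug1.points))
        assert np.abs(T2.m - T1.m).max() < 1e-9

    def test_normal_translation_under_occlusion_and_noise(self, template):
        """Monte-Carlo: the identifiable (surface-normal) translation of a
        flat blade is recovered to well under 0.5 mm with a 30 % occluded,
        0.3 mm-noise scan; in-plane slide is aperture-limited instead."""
        n = np.array([0.0, 1.0, 0.0])
        errs = []
        for seed in range(10):
            rg = np.random.default_rng(seed)
            t_true = rg.normal(0, 3, 3)
            moved = PointCloud(template.points + t_true, template.normals,
                               labels=template.labels)
            scan = simulate_lrs_cloud(moved, 0.7, 0.3, 0.3, seed=seed)
            _, T, _ = rigid_augment(template, scan)
            errs.append(abs((T.t - t_true) @ n))
        assert max(errs) < 0.5

    def test_sparse_scan_rejected(self, template):
        with pytest.raises(RegistrationError):
            rigid_augment(template, PointCloud(template.points[:10]))

    def test_residual_threshold(self, template):
        rng = np.random.default_rng(0)
        junk = PointCloud(rng.uniform(-50, 50, size=(200, 3)))
        with pytest.raises(RegistrationError):
            rigid_augment(template, junk, residual_threshold_mm=0.5)


class TestCPD:
    @pytest.fixture
    def dense(self, template):
        return template.points[template.labels == "+"]

    def test_identity_registration(self, dense):
        res = cpd_nonrigid_register(dense, dense[::4])
        assert np.abs(res.displacements).max() < 1e-3

    def test_translation_recovery(self, dense):
        res = cpd_nonrigid_register(dense, dense + np.array([2.0, 0.0, 0.0]))
        rmse = np.sqrt(((res.displacements - [2, 0, 0]) ** 2).sum(1).mean())
        assert rmse < 0.1

    def test_smooth_bend_with_noise(self, dense):
        rng = np.random.default_rng(0)
        l = (dense[:, 2] - dense[:, 2].min()) / 60.0
        true = np.outer(1.0 + 0.8 * np.sin(np.pi * l), [0, 1, 0])
        noisy = dense + true + rng.normal(0, 0.3, dense.shape)
        res = cpd_nonrigid_register(dense, noisy, CPDParams(beta=1.0))
        rmse = np.sqrt(((res.displacements - true) ** 2).sum(1).mean())
        assert rmse <= 0.3

    def test_nll_monotone_nonincreasing(self, dense):
        rng = np.random.default_rng(1)
        target = dense + rng.normal(0, 0.5, dense.shape)
        res = cpd_nonrigid_register(dense, target)
        nll = np.asarray(res.nll_history)
        assert np.all(np.diff(nll) <= 1e-6 * np.abs(nll[:-1]) + 1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(RegistrationError):
            cpd_nonrigid_register(np.zeros((5, 3)), np.ones((4, 3)))
        with pytest.raises(RegistrationError):
            cpd_nonrigid_register(np.empty((0, 3)), np.ones((4, 3)))


class TestExtractContactBCs:
    @pytest.fixture
    def setup(self):
        lab = LabelVolume(np.ones((42, 42, 42), dtype=np.uint8), np.eye(4))
        mesh = build_hex_mesh(lab, 3.0)
        # plane mid-way between node columns: nearest nodes sit at |psi|=1.5
        crack = CrackGeometry((19.0, 20.5, 41.5), (1, 0, 0), (0, 0, -1), 60.0, 24.0)
        enr = classify_enrichment(mesh, crack)
        return mesh, crack, enr

    def _cloud(self, crack, disp, thickness_included=False, n_pts=60, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-8, 8, n_pts)
        b = rng.uniform(1, 15, n_pts)
        pts = crack.o + np.outer(a, crack.w) + np.outer(b, crack.d)
        normals = np.tile(crack.n, (n_pts, 1))
        disp = np.broadcast_to(disp, (n_pts, 3)).copy()
        return PointCloud(pts, normals, disp, np.full(n_pts, "+", dtype=object))

    def test_zero_thickness_passthrough(self, setup):
        mesh, crack, enr = setup
        cloud = self._cloud(crack, [5.0, 0.0, 0.0])
        bcs = extract_contact_bcs(cloud, RetractorModel(thickness_mm=2.0), mesh,
                                  crack, zero_region=np.array([0]),
                                  enrichment=enr, thickness_mm=0.0)
        assert len(bcs) > 0
        for node, side, vec in bcs.entries:
            assert side == 1
            assert np.allclose(vec, [5.0, 0.0, 0.0])

    def test_thickness_offset_along_normal(self, setup):
        mesh, crack, enr = setup
        cloud = self._cloud(crack, [5.0, 0.0, 0.0])
        bcs = extract_contact_bcs(cloud, RetractorModel(thickness_mm=2.0), mesh,
                                  crack, zero_region=np.array([0]), enrichment=enr)
        for node, side, vec in bcs.entries:
            assert np.allclose(vec, [7.0, 0.0, 0.0])

    def test_never_assigns_to_wrong_side(self, setup):
        mesh, crack, enr = setup
        cloud = self._cloud(crack, [5.0, 0.0, 0.0])
        bcs = extract_contact_bcs(cloud, RetractorModel(), mesh, crack,
                                  zero_region=np.array([0]), enrichment=enr)
        psi, _, _ = crack_coords(mesh.nodes, crack)
        for node, side, vec in bcs.entries:
            assert np.sign(psi[node]) == side or psi[node] == 0

    def test_bc_matches_truth_field_at_snapped_nodes(self, setup):
        """Sampling the ground-truth field on the blade contact face and
        extracting BCs reproduces the field at the snapped nodes to 0.2 mm."""
        mesh, crack, enr = setup
        field = GroundTruthField(crack, 7.0, 6.3, decay_radius_mm=60.0,
                                 front_taper_mm=6.0, edge_taper_mm=8.0)
        n_pts = 400
        rng = np.random.default_rng(3)
        a = rng.uniform(-8, 8, n_pts)
        b = rng.uniform(0.5, 15, n_pts)   # inside the full-opening plateau
        pts = crack.o + np.outer(a, crack.w) + np.outer(b, crack.d)
        cloud = PointCloud(pts, np.tile(crack.n, (n_pts, 1)),
                           field(pts, side=+1), np.full(n_pts, "+", dtype=object))
        bcs = extract_contact_bcs(cloud, RetractorModel(), mesh, crack,
                                  zero_region=np.array([0]), enrichment=enr,
                                  thickness_mm=0.0)
        assert len(bcs) >= 4
        for node, side, vec in bcs.entries:
            truth = field(mesh.nodes[node], side=side)
            assert np.linalg.norm(vec - truth) < 0.2

    def test_conflicting_faces_raise(self, setup):
        mesh, crack, enr = setup
        c1 = self._cloud(crack, [5.0, 0.0, 0.0])
        c2 = self._cloud(crack, [1.0, 0.0, 0.0], seed=1)
        c2 = PointCloud(c2.points, c2.normals, c2.displacements,
                        np.full(len(c2), "other", dtype=object))
        both = PointCloud.concatenate([c1, c2])
        with pytest.raises(ConflictError):
            extract_contact_bcs(both, RetractorModel(), mesh, crack,
                                zero_region=np.array([0]), enrichment=enr)

    def test_empty_zero_region_raises(self, setup):
        mesh, crack, enr = setup
        cloud = self._cloud(crack, [5.0, 0.0, 0.0])
        with pytest.raises(ConfigurationError):
            extract_contact_bcs(cloud, RetractorModel(), mesh, crack,
                                zero_region=np.empty(0, dtype=int), enrichment=enr)

    def test_duplicate_entries_rejected(self):
        with pytest.raises(ConflictError):
            DisplacementBCSet([(1, 1, np.zeros(3)), (1, 1, np.ones(3))])

    def test_zero_set_disjoint_from_entries(self):
        with pytest.raises(ConflictError):
            DisplacementBCSet([(1, 1, np.zeros(3))], zero_nodes=np.array([1]))
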
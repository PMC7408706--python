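"""Landmark alignment, exact nearest-point queries, and robust ICP."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from scanbody_congruence import (
    ICPConfig,
    LandmarkPairs,
    RigidTransform,
    SurfaceIndex,
    closest_point_on_triangle,
    closest_surface_point,
    icp_point_to_plane,
    landmark_align,
    robust_weights,
)
from scanbody_congruence.errors import (
    DegenerateGeometryError,
    IllConditionedRegistrationError,
    ParameterError,
)
from scanbody_congruence.mesh_io import TriangleMesh
from scanbody_congruence.registration import _closest_on_triangles, brute_force_closest


class TestRigidTransform:
    def test_compose_inverse_roundtrip(self, rng):
        for _ in range(20):
            t1 = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.normal(0, 5, 3))
            t2 = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.normal(0, 5, 3))
            p = rng.normal(0, 3, (10, 3))
            assert np.allclose(t1.compose(t2).apply(p), t1.apply(t2.apply(p)), atol=1e-9)
            back = t1.inverse().compose(t1)
            assert np.allclose(back.rotation, np.eye(3), atol=1e-9)
            assert np.allclose(back.translation, 0, atol=1e-9)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ParameterError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))
        with pytest.raises(ParameterError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_json_serialisation(self, tmp_path):
        t = RigidTransform.from_rotvec_deg([10, -4, 3], [0.1, 0.2, 0.3])
        t.save_json(tmp_path / "t.json")
        back = RigidTransform.load_json(tmp_path / "t.json")
        assert np.allclose(back.rotation, t.rotation)
        assert np.allclose(back.translation, t.translation)


class TestLandmarkAlign:
    POINTS = np.array([[0.0, 0, 0], [10, 0, 0], [0, 7, 3]])

    def test_identity(self):
        t = landmark_align(LandmarkPairs(self.POINTS, self.POINTS))
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-12)

    def test_recovers_exact_rigid_motion(self):
        truth = RigidTransform.from_rotvec_deg([0, 0, 90], [1, 2, 3])
        t = landmark_align(LandmarkPairs(self.POINTS, truth.apply(self.POINTS)))
        assert np.allclose(t.rotation, truth.rotation, atol=1e-9)
        assert np.allclose(t.translation, truth.translation, atol=1e-9)

    def test_beats_random_search_on_noisy_pairs(self, rng):
        """Kabsch is the global least-squares optimum; no random rigid
        transform may do better."""
        truth = RigidTransform.from_rotvec_deg([5, -3, 12], [0.5, -1, 2])
        target = truth.apply(self.POINTS) + rng.normal(0, 0.1, (3, 3))
        pairs = LandmarkPairs(self.POINTS, target)
        t = landmark_align(pairs)
        best = np.sum((t.apply(self.POINTS) - target) ** 2)
        for _ in range(1000):
            r = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.normal(0, 2, 3))
            assert np.sum((r.apply(self.POINTS) - target) ** 2) >= best - 1e-12

    def test_collinear_landmarks_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            LandmarkPairs(line, line)


class TestClosestPointOnTriangle:
    TRI = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0]])

    def test_lifted_centroid(self):
        centroid = self.TRI.mean(axis=0)
        foot, dist = closest_point_on_triangle(centroid + [0, 0, 1], self.TRI)
        assert dist == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(foot, centroid, atol=1e-12)

    def test_vertex_query(self):
        _, dist = closest_point_on_triangle(self.TRI[1], self.TRI)
        assert dist == pytest.approx(0.0, abs=1e-12)

    def test_point_beyond_edge_matches_dense_sampling(self, rng):
        """Feet for exterior points agree with a dense barycentric grid oracle."""
        u = np.linspace(0, 1, 201)
        uu, vv = np.meshgrid(u, u)
        keep = uu + vv <= 1
        grid = (
            self.TRI[0]
            + np.outer(uu[keep], self.TRI[1] - self.TRI[0])
            + np.outer(vv[keep], self.TRI[2] - self.TRI[0])
        )
        for _ in range(50):
            p = rng.uniform(-2, 4, 3)
            _, dist = closest_point_on_triangle(p, self.TRI)
            oracle = np.linalg.norm(grid - p, axis=1).min()
            assert dist <= oracle + 1e-12
            assert dist >= oracle - 0.02  # grid resolution bound

    def test_degenerate_triangle_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            closest_point_on_triangle([0, 0, 1], np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2]]))


class TestSurfaceIndex:
    def test_matches_brute_force_on_random_points(self, library, library_index, rng):
        """Accelerated search must equal the all-triangles minimum exactly."""
        pts = np.vstack(
            [
                rng.uniform(-4, 8, (400, 3)),  # around and inside the body
                library.vertices[rng.integers(0, library.n_vertices, 300)]
                + rng.normal(0, 0.05, (300, 3)),  # near-surface
                rng.uniform(-60, 60, (100, 3)),  # far field
            ]
        )
        corr = library_index.query(pts)
        oracle = brute_force_closest(pts, library)
        assert np.abs(corr.distances - oracle).max() < 1e-9

    def test_point_on_surface_has_zero_distance(self, library, library_index):
        corr = library_index.query(library.vertices[:50])
        assert corr.distances.max() < 1e-9

    def test_far_point_equals_brute_force(self, library, library_index):
        radius = np.linalg.norm(library.vertices, axis=1).max()
        p = np.array([10 * radius, 3.0, 5.0])
        corr = closest_surface_point(p, library, library_index)
        assert corr.distances[0] == pytest.approx(brute_force_closest(p, library)[0], abs=1e-9)

    def test_feet_lie_on_their_triangles(self, library, library_index, rng):
        pts = rng.uniform(-4, 8, (200, 3))
        corr = library_index.query(pts)
        bary = corr.barycentric(library.mesh if hasattr(library, "mesh") else library)
        assert np.all(bary > -1e-9)
        assert np.allclose(bary.sum(axis=1), 1.0, atol=1e-9)


class TestRobustWeights:
    def test_equal_residuals_equal_weights(self):
        w = robust_weights(np.full(10, 3.3))
        assert np.allclose(w, 1.0)

    def test_gross_outlier_gets_zero_weight(self):
        """One 10-MAD outlier among tight residuals: Tukey weight exactly 0."""
        r = np.concatenate([np.linspace(-0.01, 0.01, 100), [1.0]])
        w = robust_weights(r, scheme="tukey")
        assert w[-1] == 0.0
        assert w[:100].min() > 0.5

    def test_matches_biweight_formula(self):
        r = np.array([-0.3, -0.1, 0.0, 0.1, 0.2, 0.25, 4.0])
        c = 4.685
        med = np.median(r)
        centred = r - med
        s = 1.4826 * np.median(np.abs(centred - np.median(centred)))
        u = centred / (c * s)
        expected = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        assert np.allclose(robust_weights(r, scheme="tukey"), expected)

    def test_scheme_none_is_all_ones(self):
        assert np.all(robust_weights(np.arange(5.0), scheme="none") == 1.0)

    def test_all_zero_residuals_safe(self):
        assert np.all(robust_weights(np.zeros(7)) == 1.0)

    def test_weights_non_increasing_in_magnitude(self, rng):
        r = np.sort(np.abs(rng.normal(0, 1, 200)))
        w = robust_weights(np.concatenate([[0.0], r]), center=False)
        assert np.all(np.diff(w) <= 1e-12)


class TestICP:
    def test_recovers_known_perturbation(self, library, library_index):
        truth = RigidTransform.from_rotvec_deg([0.5, -1.0, 1.5], [0.03, -0.02, 0.04])
        source = library.transformed(truth.rotation, truth.translation)
        cfg = ICPConfig(min_iterations=30, max_iterations=60, sample_count=1500, seed=3)
        t, trace = icp_point_to_plane(source, library, config=cfg, index=library_index)
        err = t.compose(truth)
        assert err.rotation_angle_deg() < 1e-3
        assert 1000 * np.linalg.norm(err.translation) < 0.1
        assert len(trace) >= cfg.min_iterations

    def test_uniform_normal_offset_not_absorbed(self, library, library_index):
        """A uniformly grown scan is normal-symmetric: ICP must not trade the
        30 um offset for pose.  The residual pose error is bounded by the
        rim artefacts of vertex-normal offsetting (a few um), far below the
        offset itself."""
        grown = TriangleMesh(
            library.vertices + 0.030 * library.vertex_normals, library.faces.copy()
        )
        cfg = ICPConfig(min_iterations=20, max_iterations=40, sample_count=1500, seed=4)
        t, _ = icp_point_to_plane(grown, library, config=cfg, index=library_index)
        assert 1000 * np.linalg.norm(t.translation) < 5.0  # << 30 um offset
        assert t.rotation_angle_deg() < 0.1

    def test_exact_init_is_fixed_point(self, library, library_index):
        cfg = ICPConfig(min_iterations=1, max_iterations=1, sample_count=1000, seed=5)
        t, _ = icp_point_to_plane(library, library, config=cfg, index=library_index)
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-9
        assert np.linalg.norm(t.translation) < 1e-9

    def test_transform_equivariance(self, library, library_index):
        """Registering (T o source) returns (solution o T^-1)."""
        pre = RigidTransform.from_rotvec_deg([0, 0, 1.0], [0.02, 0, -0.01])
        cfg = ICPConfig(min_iterations=25, max_iterations=40, sample_count=1200, seed=6)
        t_plain, _ = icp_point_to_plane(library, library, config=cfg, index=library_index)
        moved = library.transformed(pre.rotation, pre.translation)
        t_moved, _ = icp_point_to_plane(moved, library, config=cfg, index=library_index)
        expected = t_plain.compose(pre.inverse())
        assert np.abs(t_moved.rotation - expected.rotation).max() < 1e-6
        assert np.abs(t_moved.translation - expected.translation).max() < 1e-6

    @pytest.mark.parametrize(
        "scheme,c,bound_mm",
        [
            ("tukey", 4.685, 0.010),  # redescending: outliers fully rejected
            ("huber", 2.0, 0.025),  # bounded influence: small residual pull
        ],
    )
    def test_robust_to_gross_outlier_vertices(
        self, library, library_index, rng, scheme, c, bound_mm
    ):
        """10% of vertices thrown ~1 mm off: Tukey keeps the error at the
        clean level (<= 2x, with a 5 um floor); Huber stays within its
        bounded-influence margin."""
        truth = RigidTransform.from_rotvec_deg([0, 1.0, 0.5], [0.02, 0.03, -0.01])
        clean = library.transformed(truth.rotation, truth.translation)
        v = clean.vertices.copy()
        n_out = len(v) // 10
        idx = rng.choice(len(v), n_out, replace=False)
        v[idx] += rng.normal(0, 1, (n_out, 3)) * (1.0 / np.sqrt(3))
        dirty = TriangleMesh(v, clean.faces.copy())
        cfg = ICPConfig(
            min_iterations=40, max_iterations=60, sample_count=2000, seed=7,
            robust_scheme=scheme, tuning_c=c,
        )
        t_clean, _ = icp_point_to_plane(clean, library, config=cfg, index=library_index)
        t_dirty, _ = icp_point_to_plane(dirty, library, config=cfg, index=library_index)
        e_clean = np.linalg.norm(t_clean.compose(truth).translation) + 1e-6
        e_dirty = np.linalg.norm(t_dirty.compose(truth).translation)
        assert e_dirty <= max(2 * max(e_clean, 0.005), bound_mm)

    def test_planar_source_is_ill_conditioned(self):
        g = np.linspace(0, 1, 6)
        xx, yy = np.meshgrid(g, g)
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(36)])
        faces = []
        for i in range(5):
            for j in range(5):
                a = i * 6 + j
                faces.append([a, a + 1, a + 7])
                faces.append([a, a + 7, a + 6])
        plane = TriangleMesh(verts, np.asarray(faces))
        cfg = ICPConfig(min_iterations=1, max_iterations=5, sample_count=500, seed=8)
        with pytest.raises(IllConditionedRegistrationError):
            icp_point_to_plane(plane, plane, config=cfg)

    def test_deterministic_given_seed(self, library, library_index):
        truth = RigidTransform.from_rotvec_deg([0, 0, 1.0], [0.02, 0, 0])
        src = library.transformed(truth.rotation, truth.translation)
        cfg = ICPConfig(min_iterations=10, max_iterations=15, sample_count=800, seed=11)
        t1, tr1 = icp_point_to_plane(src, library, config=cfg, index=library_index)
        t2, tr2 = icp_point_to_plane(src, library, config=cfg, index=library_index)
        assert np.array_equal(t1.rotation, t2.rotation)
        assert np.array_equal(t1.translation, t2.translation)
        assert tr1 == tr2


def test_pairwise_triangle_kernel_agrees_with_scalar(rng):
    tris = rng.normal(0, 2, (50, 3, 3))
    pts = rng.normal(0, 3, (50, 3))
    feet = _closest_on_triangles(pts, tris)
    for p, tri, foot in zip(pts, tris, feet):
        f, d = closest_point_on_triangle(p, tri)
        assert np.linalg.norm(p - foot) == pytest.approx(d, abs=1e-12)
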
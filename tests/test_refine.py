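import numpy as np
import pytest

from meshdose.io_formats import LabeledPointCloud
from meshdose.meshes import SurfaceMesh
from meshdose.phantom import (
    OrganSpec,
    PhantomSpec,
    make_ellipsoid_mesh,
    make_labeled_cloud,
)
from meshdose.refine import (
    RefineConfig,
    dice,
    extract_surface,
    farthest_point_sample,
    largest_component,
    propagate_labels,
    refine_pipeline,
    remove_outliers,
    smooth,
    voxelize,
)


def cloud_of(points, labels=None):
    points = np.asarray(points, dtype=float)
    if labels is None:
        labels = np.zeros(len(points), dtype=int)
    return LabeledPointCloud(points, labels)


class TestFarthestPointSample:
    def test_m_equals_n_selects_all(self, rng):
        pts = cloud_of(rng.normal(size=(20, 3)))
        idx = farthest_point_sample(pts, 20, seed=3)
        assert sorted(idx) == list(range(20))

    def test_m_one_is_seeded_first_pick(self, rng):
        pts = cloud_of(rng.normal(size=(15, 3)))
        idx = farthest_point_sample(pts, 1, seed=5)
        expected = np.random.default_rng(5).integers(15)
        assert list(idx) == [expected]

    def test_square_corners_beat_center(self):
        """4 corners + center: after a corner first pick, FPS must select
        the remaining 3 corners (hand-checked greedy argument)."""
        pts = np.array(
            [[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0], [5, 5, 0]],
            dtype=float,
        )
        for seed in range(10):
            idx = farthest_point_sample(cloud_of(pts), 4, seed=seed)
            if idx[0] == 4:  # center first pick: corners still win the rest
                assert set(idx[1:]) <= {0, 1, 2, 3}
            else:
                assert set(idx) == {0, 1, 2, 3}

    def test_greedy_maximin_property(self, rng):
        """Each selected point attains the maximal min-distance at its turn
        (brute-force re-check of the greedy invariant)."""
        pts = rng.normal(size=(60, 3)) * 40
        idx = farthest_point_sample(cloud_of(pts), 12, seed=0)
        for i in range(1, 12):
            sel = pts[idx[:i]]
            dists = np.linalg.norm(pts[:, None] - sel[None], axis=2).min(axis=1)
            assert dists[idx[i]] == pytest.approx(dists.max())

    def test_m_out_of_range(self, rng):
        pts = cloud_of(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            farthest_point_sample(pts, 6)


class TestPropagateLabels:
    def test_unanimous_vote(self, rng):
        sparse = cloud_of(rng.normal(size=(30, 3)), np.ones(30, dtype=int))
        dense = rng.normal(size=(100, 3))
        assert np.all(propagate_labels(sparse, dense, k=10) == 1)

    def test_k1_equals_nearest_neighbor_brute_force(self, rng):
        sparse = cloud_of(rng.normal(size=(200, 3)) * 10,
                          rng.integers(1, 5, 200))
        dense = rng.normal(size=(400, 3)) * 10
        got = propagate_labels(sparse, dense, k=1)
        d = np.linalg.norm(dense[:, None] - sparse.points[None], axis=2)
        expected = sparse.labels[np.argmin(d, axis=1)]
        np.testing.assert_array_equal(got, expected)

    def test_majority_wins_six_four_split(self):
        """Dense point equidistant from a 6-vs-4 label split."""
        angles = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        ring = np.column_stack([np.cos(angles), np.sin(angles), np.zeros(10)])
        labels = np.array([2] * 6 + [1] * 4)
        sparse = cloud_of(ring, labels)
        got = propagate_labels(sparse, np.zeros((1, 3)), k=10)
        assert got[0] == 2

    def test_tie_broken_by_nearest(self):
        pts = np.array([[1.0, 0, 0], [2.0, 0, 0], [-1.5, 0, 0], [-2.5, 0, 0]])
        sparse = cloud_of(pts, np.array([1, 1, 2, 2]))
        got = propagate_labels(sparse, np.zeros((1, 3)), k=4)
        assert got[0] == 1  # nearest point (distance 1) carries label 1

    def test_empty_sparse_rejected(self):
        empty = cloud_of(np.empty((0, 3)))
        with pytest.raises(ValueError):
            propagate_labels(empty, np.zeros((1, 3)))


class TestRemoveOutliers:
    def test_clean_blob_mostly_kept(self, rng):
        cloud = cloud_of(rng.normal(size=(500, 3)))
        kept, removed = remove_outliers(cloud, k=30, sd_factor=2.0)
        assert len(removed) / 500 < 0.10

    def test_planted_far_point_removed(self, rng):
        pts = np.vstack([rng.normal(size=(500, 3)), [[100.0, 100.0, 100.0]]])
        cloud = cloud_of(pts)
        kept, removed = remove_outliers(cloud, k=30, sd_factor=2.0)
        assert 500 in removed
        # brute-force statistic confirms the planted point is extreme
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        np.fill_diagonal(d, np.inf)
        stat = np.sort(d, axis=1)[:, :30].mean(axis=1)
        assert stat[500] == stat.max()

    def test_infinite_threshold_removes_nothing(self, rng):
        cloud = cloud_of(rng.normal(size=(100, 3)))
        _, removed = remove_outliers(cloud, k=30, sd_factor=np.inf)
        assert len(removed) == 0

    def test_point_order_invariance(self, rng):
        pts = np.vstack([rng.normal(size=(200, 3)), rng.normal(size=(5, 3)) + 20])
        perm = rng.permutation(len(pts))
        _, removed_a = remove_outliers(cloud_of(pts), k=20)
        _, removed_b = remove_outliers(cloud_of(pts[perm]), k=20)
        assert set(perm[removed_b]) == set(removed_a)

    def test_too_small_cloud_rejected(self, rng):
        with pytest.raises(ValueError):
            remove_outliers(cloud_of(rng.normal(size=(10, 3))), k=30)


class TestVoxelize:
    def test_single_point_single_voxel(self):
        grid = voxelize(cloud_of([[5.0, 5.0, 5.0]], [1]), 1, spacing=(1, 1, 1))
        assert grid.array.sum() == 1

    def test_two_points_same_voxel(self):
        cloud = cloud_of([[5.0, 5.0, 5.0], [5.2, 5.1, 4.9]], [1, 1])
        grid = voxelize(cloud, 1, spacing=(1, 1, 1))
        assert grid.array.sum() == 1

    def test_occupancy_matches_brute_force_binning(self, rng):
        """1000 sphere-interior points at 2 mm spacing vs independent binning."""
        u = rng.normal(size=(1000, 3))
        pts = u / np.linalg.norm(u, axis=1, keepdims=True) * \
            (rng.random((1000, 1)) ** (1 / 3)) * 20
        grid = voxelize(cloud_of(pts, np.ones(1000, int)), 1, spacing=(2, 2, 2))
        keys = {tuple(np.round((p - grid.origin) / grid.spacing).astype(int))
                for p in pts}
        assert grid.array.sum() == len(keys)

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            voxelize(cloud_of([[0, 0, 0]], [1]), 2)


class TestExtractSurface:
    def test_single_voxel_closed_small_volume(self):
        grid = voxelize(cloud_of([[0.0, 0, 0]], [1]), 1, spacing=(1, 1, 1))
        mesh = extract_surface(grid)
        assert mesh.is_closed()
        # marching cubes yields the mid-edge octahedron: 1/6 voxel volume
        assert mesh.volume == pytest.approx(1 / 6, rel=1e-6)

    def test_sphere_volume_within_five_percent(self):
        r, sp = 20.0, 1.0
        coords = np.arange(-25, 26) * sp
        x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
        occ = x**2 + y**2 + z**2 <= r**2
        from meshdose.io_formats import VoxelGrid

        grid = VoxelGrid(occ, origin=(-25, -25, -25), spacing=(sp, sp, sp))
        mesh = extract_surface(grid)
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)
        assert mesh.as_trimesh().euler_number == 2

    def test_vertices_in_physical_coordinates(self):
        grid = voxelize(cloud_of([[100.0, 50.0, -30.0]], [1]), 1, spacing=(2, 2, 3))
        mesh = extract_surface(grid)
        center = mesh.vertices.mean(axis=0)
        np.testing.assert_allclose(center, [100.0, 50.0, -30.0], atol=2.0)

    def test_uniform_grid_rejected(self):
        from meshdose.io_formats import VoxelGrid

        grid = VoxelGrid(np.ones((3, 3, 3)), (0, 0, 0), (1, 1, 1))
        with pytest.raises(ValueError):
            extract_surface(grid)


class TestSmooth:
    def test_zero_iterations_identity(self, sphere_mesh):
        out = smooth(sphere_mesh, iterations=0)
        np.testing.assert_array_equal(out.vertices, sphere_mesh.vertices)

    def test_tetrahedron_full_relaxation(self):
        """relaxation=1, one step: each vertex lands on the centroid of the
        other three (hand computation on 4 vertices)."""
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        f = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
        out = smooth(SurfaceMesh(v, f), iterations=1, relaxation=1.0)
        for i in range(4):
            others = np.delete(v, i, axis=0).mean(axis=0)
            np.testing.assert_allclose(out.vertices[i], others, atol=1e-12)

    def test_noisy_sphere_rms_decreases(self, rng):
        # fine mesh: umbrella-smoothing shrinkage (~ edge^2 * curvature per
        # step) stays well below the injected noise amplitude
        base = make_ellipsoid_mesh((0, 0, 0), (30, 30, 30), 4)
        noisy = SurfaceMesh(base.vertices + rng.normal(scale=2.0,
                                                       size=base.vertices.shape),
                            base.faces)

        def rms(mesh):
            return np.sqrt(np.mean(
                (np.linalg.norm(mesh.vertices, axis=1) - 30.0) ** 2))

        out = smooth(noisy, iterations=80, relaxation=0.1)
        assert rms(out) < rms(noisy)

    def test_topology_unchanged(self, rng):
        base = make_ellipsoid_mesh((0, 0, 0), (20, 15, 10), 2)
        out = smooth(base, iterations=10, relaxation=0.3)
        assert out.n_vertices == base.n_vertices
        np.testing.assert_array_equal(out.faces, base.faces)


class TestLargestComponent:
    def test_single_component_identity(self, sphere_mesh):
        out = largest_component(sphere_mesh)
        assert out.n_faces == sphere_mesh.n_faces

    def test_sphere_beats_detached_cube(self):
        sphere = make_ellipsoid_mesh((0, 0, 0), (10, 10, 10), 2)
        import trimesh

        cube = trimesh.creation.box(extents=(2, 2, 2))
        cube.apply_translation([50, 0, 0])
        merged = SurfaceMesh(
            np.vstack([sphere.vertices, cube.vertices]),
            np.vstack([sphere.faces, np.asarray(cube.faces) + sphere.n_vertices]),
        )
        out = largest_component(merged)
        assert out.n_faces == sphere.n_faces

    def test_equal_faces_tie_broken_by_area(self):
        small = make_ellipsoid_mesh((0, 0, 0), (1, 1, 1), 1)
        big = make_ellipsoid_mesh((50, 0, 0), (5, 5, 5), 1)
        merged = SurfaceMesh(
            np.vstack([small.vertices, big.vertices]),
            np.vstack([small.faces, big.faces + small.n_vertices]),
        )
        out = largest_component(merged)
        assert out.area == pytest.approx(big.area)


class TestDice:
    def test_identical_labelings(self):
        labels = np.array([1, 1, 2, 0, 2])
        assert dice(labels, labels, 2) == 1.0

    def test_disjoint_sets(self):
        assert dice([1, 1, 0, 0], [0, 0, 1, 1], 1) == 0.0

    def test_set_arithmetic(self):
        """|A| = |B| = 10 with overlap 6 -> 0.6."""
        truth = np.zeros(30, dtype=int)
        pred = np.zeros(30, dtype=int)
        truth[:10] = 1
        pred[4:14] = 1
        assert dice(pred, truth, 1) == pytest.approx(0.6)

    def test_symmetric_and_bounded(self, rng):
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 3, 200)
        d1, d2 = dice(a, b, 1), dice(b, a, 1)
        assert d1 == d2 and 0.0 <= d1 <= 1.0

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            dice([0, 0], [0, 0], 5)


@pytest.fixture(scope="module")
def liver_phantom():
    organ = OrganSpec("liver", "ellipsoid", (0, 0, 0), (40, 30, 25), 1, 1.0)
    spec = PhantomSpec((organ,), (0, 0, 0), 0)
    cloud, _ = make_labeled_cloud(spec, points_per_organ=30000, seed=3)
    return organ, spec, cloud


class TestRefinePipeline:
    CONFIG = RefineConfig(voxel_spacing=(3.0, 3.0, 3.0))

    def test_clean_cloud_volume_within_ten_percent(self, liver_phantom):
        organ, spec, cloud = liver_phantom
        idx = farthest_point_sample(cloud, 3000, seed=1)
        mesh, audit = refine_pipeline(cloud.subset(idx), cloud, 1, self.CONFIG)
        truth = 4 / 3 * np.pi * 40 * 30 * 25
        assert mesh.volume == pytest.approx(truth, rel=0.10)
        assert audit["dense_points"] == 30000

    def test_planted_outlier_recall(self, liver_phantom, rng):
        organ, spec, _ = liver_phantom
        cloud, planted = make_labeled_cloud(
            spec, points_per_organ=4000, noise_sd=0.5, outlier_fraction=0.05,
            seed=11,
        )
        _, removed = remove_outliers(cloud, k=30, sd_factor=2.0)
        recall = np.isin(np.flatnonzero(planted), removed).mean()
        assert recall >= 0.90

    def test_sparse_equals_dense_gives_perfect_dice(self):
        """Disjoint liver+spleen scene, sparse = dense: every point's own
        label wins its neighborhood, so propagated Dice is exactly 1."""
        spec = PhantomSpec(
            (
                OrganSpec("liver", "ellipsoid", (0, 0, 0), (40, 30, 25), 1, 1.0),
                OrganSpec("spleen", "ellipsoid", (120, 0, 0), (20, 15, 12), 2, 1.0),
            ),
            (0, 0, 0),
            0,
        )
        cloud, _ = make_labeled_cloud(spec, points_per_organ=400, seed=2)
        got = propagate_labels(cloud, cloud.points, k=10)
        assert dice(got, cloud.labels, 1) == 1.0
        assert dice(got, cloud.labels, 2) == 1.0
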
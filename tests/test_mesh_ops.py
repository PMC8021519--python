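"""Mesh post-processing: smoothing, component filtering, decimation,
proximity painting, pruning, geodesics."""

import numpy as np
import pytest
import trimesh

from splenvas.mesh_ops import (
    bounding_sphere_diameter,
    geodesic_path_length,
    laplacian_smooth,
    paint_by_proximity,
    prune_cell_components,
    quadric_decimate,
    remove_small_components,
    taubin_smooth,
)


def sphere_at(center, radius, subdiv=2):
    s = trimesh.creation.icosphere(subdiv, radius=radius)
    s.apply_translation(center)
    return s


from conftest import oracle_mesh_distances


class TestTaubin:
    def test_zero_iterations_identity(self):
        s = trimesh.creation.icosphere(2)
        out = taubin_smooth(s, 0)
        assert np.array_equal(out.vertices, s.vertices)

    def test_flat_interior_fixed(self):
        # regular grid patch: interior vertices have zero uniform Laplacian
        n = 7
        xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
        verts = np.stack([xs.ravel(), ys.ravel(), np.zeros(n * n)], axis=1)
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
        patch = trimesh.Trimesh(verts, faces, process=False)
        out = taubin_smooth(patch, 10)
        interior = [i * n + j for i in range(1, n - 1) for j in range(1, n - 1)]
        assert np.abs(out.vertices[interior, 2]).max() <= 1e-12

    def test_volume_preserved_better_than_laplacian(self):
        s = trimesh.creation.icosphere(3)
        tb = taubin_smooth(s, 10)
        lp = laplacian_smooth(s, 10)
        assert abs(tb.volume - s.volume) < abs(lp.volume - s.volume)

    def test_topology_unchanged(self):
        s = trimesh.creation.icosphere(2)
        out = taubin_smooth(s, 10)
        assert np.array_equal(out.faces, s.faces)


class TestRemoveSmallComponents:
    def test_single_component_unchanged(self):
        s = trimesh.creation.icosphere(2)
        out = remove_small_components(s, 0.05)
        assert len(out.faces) == len(s.faces)

    def test_forced_removal_by_size(self):
        big = sphere_at((0, 0, 0), 50.0)
        small = sphere_at((80, 0, 0), 0.5)
        both = trimesh.util.concatenate([big, small])
        out = remove_small_components(both, 0.05)
        assert len(out.split(only_watertight=False)) == 1
        assert out.bounds[1][0] < 70

    def test_removal_monotone_in_fraction(self):
        rng = np.random.default_rng(0)
        comps = [sphere_at(rng.uniform(0, 200, 3), r)
                 for r in (40, 10, 4, 1.5, 0.6)]
        mesh = trimesh.util.concatenate(comps)

        def surviving(frac):
            out = remove_small_components(mesh, frac)
            return len(out.split(only_watertight=False))

        counts = [surviving(f) for f in (0.01, 0.05, 0.2, 0.6)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            remove_small_components(trimesh.creation.icosphere(1), 1.5)


class TestQuadricDecimate:
    def test_keep_all_identity(self):
        s = trimesh.creation.icosphere(2)
        out = quadric_decimate(s, 1.0)
        assert len(out.faces) == len(s.faces)

    def test_sphere_to_ten_percent(self):
        s = trimesh.creation.icosphere(4)
        out = quadric_decimate(s, 0.1)
        assert len(out.faces) <= 0.1 * len(s.faces) + 1
        assert out.area == pytest.approx(s.area, rel=0.05)

    def test_output_stays_manifold(self):
        s = trimesh.creation.icosphere(3)
        out = quadric_decimate(s, 0.2)
        assert out.is_watertight
        assert out.is_winding_consistent
        # every edge shared by exactly two faces
        edges = out.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert set(counts) == {2}

    def test_commutes_with_component_removal(self):
        big = sphere_at((0, 0, 0), 50.0, subdiv=3)
        small = sphere_at((90, 0, 0), 1.0, subdiv=2)
        mesh = trimesh.util.concatenate([big, small])
        a = quadric_decimate(remove_small_components(mesh, 0.1), 0.5)
        b = remove_small_components(quadric_decimate(mesh, 0.5), 0.1)
        assert len(a.split(only_watertight=False)) == \
               len(b.split(only_watertight=False)) == 1
        assert a.bounds[1][0] < 60 and b.bounds[1][0] < 60


class TestPaintByProximity:
    def _plane(self, z, size=10.0, n=4):
        xs, ys = np.meshgrid(np.linspace(0, size, n), np.linspace(0, size, n))
        verts = np.stack([xs.ravel(), ys.ravel(), np.full(n * n, z)], axis=1)
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
        return trimesh.Trimesh(verts, faces, process=False)

    def test_parallel_planes_5um_all_highlighted(self):
        paint = paint_by_proximity(self._plane(0), self._plane(5.0), 8.75)
        assert paint.highlighted.all()

    def test_parallel_planes_20um_none(self):
        paint = paint_by_proximity(self._plane(0), self._plane(20.0), 8.75)
        assert not paint.highlighted.any()

    def test_threshold_strictly_less(self):
        paint = paint_by_proximity(self._plane(0), self._plane(8.75), 8.75)
        assert not paint.highlighted.any()

    def test_matches_bruteforce_oracle(self):
        """Labels equal an independent brute-force point-triangle oracle on
        small random meshes (<= 500 triangles)."""
        rng = np.random.default_rng(0)
        src = trimesh.creation.icosphere(1, radius=6.0)  # 80 faces
        tgt = trimesh.creation.icosphere(1, radius=3.0)
        tgt.apply_translation([9.0, 1.0, 0.5])
        paint = paint_by_proximity(src, tgt, 8.75)
        d_oracle = oracle_mesh_distances(src.vertices, tgt)
        assert np.abs(paint.distances - d_oracle).max() <= 1e-6
        assert np.array_equal(paint.highlighted, d_oracle < 8.75)

    def test_empty_target_all_plain(self):
        src = trimesh.creation.icosphere(1)
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        paint = paint_by_proximity(src, empty, 8.75)
        assert not paint.highlighted.any()

    def test_colored_mesh_export(self):
        paint = paint_by_proximity(self._plane(0), self._plane(5.0), 8.75)
        m = paint.colored_mesh()
        assert np.all(m.visual.vertex_colors[:, :3] == 255)


class TestPruneCellComponents:
    def test_small_component_removed(self):
        ref = sphere_at((0, 0, 0), 10.0)
        cells = sphere_at((12, 0, 0), 4.0)  # diameter 8 < 10
        out = prune_cell_components(cells, [ref], max_distance_um=50.0)
        assert len(out.faces) == 0

    def test_large_touching_component_kept(self):
        ref = sphere_at((0, 0, 0), 10.0)
        cells = sphere_at((14, 0, 0), 6.0)  # diameter 12, near the reference
        out = prune_cell_components(cells, [ref], max_distance_um=5.0)
        assert len(out.faces) == len(cells.faces)

    def test_distant_component_removed(self):
        ref = sphere_at((0, 0, 0), 10.0)
        cells = sphere_at((100, 0, 0), 6.0)
        out = prune_cell_components(cells, [ref], max_distance_um=20.0)
        assert len(out.faces) == 0

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        ref = sphere_at((0, 0, 0), 10.0)
        comps = [sphere_at(rng.uniform(-40, 40, 3), rng.uniform(3, 7))
                 for _ in range(5)]
        a = prune_cell_components(trimesh.util.concatenate(comps), [ref], 25.0)
        b = prune_cell_components(trimesh.util.concatenate(comps[::-1]), [ref],
                                  25.0)
        assert len(a.faces) == len(b.faces)
        assert a.area == pytest.approx(b.area, rel=1e-9)

    def test_bounding_sphere_diameter(self):
        s = trimesh.creation.icosphere(3, radius=5.0)
        d = bounding_sphere_diameter(s.vertices)
        assert d == pytest.approx(10.0, rel=0.02)


class TestGeodesic:
    def test_entry_equals_exit_zero(self, long_cylinder):
        p = np.array([8.0, 0.0, 0.0])
        assert geodesic_path_length(long_cylinder, p, p) == 0.0

    def test_straight_cylinder_axial_length(self, long_cylinder):
        g = geodesic_path_length(long_cylinder,
                                 np.array([8.0, 0.0, 0.0]),
                                 np.array([8.0, 0.0, 300.0]))
        assert g == pytest.approx(300.0, rel=0.03)

    def test_lower_bounded_by_euclidean(self, long_cylinder):
        a = np.array([8.0, 0.0, 20.0])
        b = np.array([-8.0, 0.0, 250.0])
        g = geodesic_path_length(long_cylinder, a, b)
        va = long_cylinder.vertices[
            np.argmin(np.linalg.norm(long_cylinder.vertices - a, axis=1))]
        vb = long_cylinder.vertices[
            np.argmin(np.linalg.norm(long_cylinder.vertices - b, axis=1))]
        assert g >= np.linalg.norm(va - vb) - 1e-9

    def test_disconnected_components_fail(self):
        two = trimesh.util.concatenate([
            sphere_at((0, 0, 0), 5.0), sphere_at((100, 0, 0), 5.0)])
        with pytest.raises(ValueError):
            geodesic_path_length(two, np.array([5.0, 0, 0]),
                                 np.array([95.0, 0, 0]))
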
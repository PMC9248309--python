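"""Mesh model, refinement, families, projection, clustering."""

import numpy as np
import pytest

import blurkit as bk
from blurkit.imgcore import FormatError
from blurkit.surface import (ProjectionReport, filter_clusters, refine_labels,
                             vertex_clusters)


class TestMeshModel:
    def test_euler_characteristic_closed(self, icosahedron):
        assert icosahedron.euler_characteristic == 2
        assert len(icosahedron.edges) == 30

    def test_degenerate_face_rejected(self):
        with pytest.raises(ValueError):
            bk.TriangleMesh(np.zeros((3, 3)), [[0, 0, 1]])

    def test_out_of_range_face_rejected(self):
        with pytest.raises(ValueError):
            bk.TriangleMesh(np.zeros((3, 3)), [[0, 1, 5]])


class TestSurfaceIO:
    def test_icosahedron_round_trip(self, tmp_path, icosahedron):
        p = bk.write_surface(icosahedron, tmp_path / "lh.ico")
        m = bk.read_surface(p)
        assert np.allclose(m.vertices, icosahedron.vertices)
        assert np.array_equal(m.faces, icosahedron.faces)

    def test_sheet_round_trip_exact(self, tmp_path, sheet):
        white, _ = sheet
        m = bk.read_surface(bk.write_surface(white, tmp_path / "lh.white"))
        # coordinates are float32 on disk
        assert np.array_equal(m.vertices,
                              white.vertices.astype(np.float32))

    def test_truncated_file_raises(self, tmp_path, icosahedron):
        p = bk.write_surface(icosahedron, tmp_path / "lh.trunc")
        data = p.read_bytes()
        p.write_bytes(data[: len(data) // 2])
        with pytest.raises(FormatError):
            bk.read_surface(p)


class TestRefinement:
    def test_icosahedron_counts(self, icosahedron):
        r = bk.refine_mesh(icosahedron, 1)
        assert r.n_vertices == 42
        assert r.n_faces == 80
        assert r.euler_characteristic == 2

    def test_closed_mesh_vertex_formula(self, icosahedron):
        # for closed genus-0: E = 3V - 6, so V' = V + E = 4V - 6
        m = bk.refine_mesh(icosahedron, 2)  # V = 162
        r = bk.refine_mesh(m, 1)
        assert r.n_vertices == 4 * m.n_vertices - 6
        assert r.n_faces == 4 * m.n_faces

    def test_mean_edge_length_halves_exactly_closed(self, icosahedron):
        # exact for closed meshes by the midsegment theorem
        r = bk.refine_mesh(icosahedron, 1)
        assert r.mean_edge_length() == pytest.approx(
            icosahedron.mean_edge_length() / 2, rel=1e-12)

    def test_mean_edge_length_nearly_halves_bordered(self, sheet):
        white, _ = sheet
        r = bk.refine_mesh(white, 1)
        assert r.mean_edge_length() == pytest.approx(
            white.mean_edge_length() / 2, rel=1e-2)

    def test_original_vertices_untouched(self, sheet):
        white, _ = sheet
        r = bk.refine_mesh(white, 2)
        assert np.array_equal(r.vertices[: white.n_vertices], white.vertices)

    def test_nonmanifold_rejected(self):
        # three faces share edge (0, 1)
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [1, 1, 1]], float)
        faces = [[0, 1, 2], [0, 1, 3], [0, 1, 4]]
        with pytest.raises(ValueError):
            bk.refine_mesh(bk.TriangleMesh(verts, faces), 1)

    def test_label_refinement_preserves_disjointness(self, small_sheet):
        white, _ = small_sheet
        a, b = bk.make_stripe_phantom(white, bk.StripeSpec(stripe_width=4.0))
        ra = refine_labels(a.values, white, 1)
        rb = refine_labels(b.values, white, 1)
        assert not np.any(ra & rb)
        assert len(ra) == bk.refine_mesh(white, 1).n_vertices


class TestEquidistantFamily:
    def test_step_01_gives_11_surfaces(self, sheet):
        fam = bk.equidistant_family(*sheet, 0.1)
        assert len(fam) == 11
        assert np.allclose(fam.depths, np.arange(11) / 10)

    def test_middle_surface_is_mean(self, sheet):
        white, pial = sheet
        fam = bk.equidistant_family(white, pial, 0.5)
        assert len(fam) == 3
        assert np.allclose(fam.meshes[1].vertices,
                           0.5 * (white.vertices + pial.vertices))

    def test_identical_boundaries(self, sheet):
        white, _ = sheet
        fam = bk.equidistant_family(white, white, 0.1)
        for m in fam.meshes:
            assert np.array_equal(m.vertices, white.vertices)

    def test_topology_mismatch_rejected(self, sheet, icosahedron):
        with pytest.raises(ValueError):
            bk.equidistant_family(sheet[0], icosahedron, 0.1)


class TestVol2Surf:
    def _flat_mesh_at_voxel_centers(self, grid):
        # vertices exactly at the voxel centers of the middle slice
        k = grid.dims[2] // 2
        ii = np.array([[i, j, k] for i in range(grid.dims[0])
                       for j in range(grid.dims[1])], float)
        verts = grid.voxel_to_world(ii)
        n = grid.dims[1]
        faces = []
        for i in range(grid.dims[0] - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n])
                faces.append([a + 1, a + n + 1, a + n])
        return bk.TriangleMesh(verts, faces), ii

    @pytest.mark.parametrize("method", ["nearest", "linear"])
    def test_constant_volume(self, small_grid, small_sheet, method):
        v = bk.Volume(small_grid, np.full(small_grid.dims, 7.5))
        white, _ = small_sheet
        # shrink mesh into the small FOV
        mesh = bk.TriangleMesh(white.vertices * 0.15, white.faces)
        smap = bk.vol2surf(v, mesh, method=method)
        assert np.allclose(smap.values, 7.5)

    @pytest.mark.parametrize("method", ["nearest", "linear"])
    def test_vertex_at_voxel_center(self, rng, method):
        g = bk.VoxelGrid.isotropic(8, 1.0)
        v = bk.Volume(g, rng.normal(size=g.dims))
        mesh, ii = self._flat_mesh_at_voxel_centers(g)
        smap = bk.vol2surf(v, mesh, method=method)
        expected = v.data[tuple(ii.astype(int).T)]
        assert np.allclose(smap.values, expected, atol=1e-12)

    def test_midpoint_linear_is_mean(self, rng):
        g = bk.VoxelGrid.isotropic(6, 1.0)
        v = bk.Volume(g, rng.normal(size=g.dims))
        p0 = g.voxel_to_world([2, 3, 3])
        p1 = g.voxel_to_world([3, 3, 3])
        mesh = bk.TriangleMesh(
            np.array([0.5 * (p0 + p1), p0, p1]), [[0, 1, 2]])
        smap = bk.vol2surf(v, mesh, method="linear")
        assert smap.values[0] == pytest.approx(
            0.5 * (v.data[2, 3, 3] + v.data[3, 3, 3]))

    def test_out_of_fov_flagged(self, small_grid, icosahedron):
        v = bk.Volume(small_grid, np.ones(small_grid.dims))
        mesh = bk.TriangleMesh(icosahedron.vertices * 100, icosahedron.faces)
        smap = bk.vol2surf(v, mesh, method="nearest", fill=-1.0)
        assert smap.metadata["out_of_fov"] == mesh.n_vertices
        assert np.all(smap.values == -1.0)

    def test_composed_identity_trace_matches_vol2surf(self, rng, small_sheet):
        white, _ = small_sheet
        g = bk.VoxelGrid.isotropic(28, 1.0)
        v = bk.Volume(g, rng.normal(size=g.dims + (4,)))
        trace = bk.MotionTrace.from_params(np.zeros((4, 6)), 2)
        a = bk.vol2surf_composed(v, trace, white, method="linear")
        b = bk.vol2surf(v, white, method="linear")
        assert np.allclose(a.values, b.values)

    def test_linear_projection_variance_not_above_nearest(self, rng, small_sheet):
        # trilinear is a convex combination, so its noise variance cannot
        # exceed a single-voxel sample's beyond sampling error
        white, _ = small_sheet
        g = bk.VoxelGrid.isotropic(28, 1.0)
        noise = bk.white_noise_series(g, 300, seed=42)
        t_n = bk.tstd_map(bk.vol2surf(noise, white, method="nearest"))
        t_l = bk.tstd_map(bk.vol2surf(noise, white, method="linear"))
        assert t_l.values.mean() <= t_n.values.mean() + 0.01


class TestUniqueVoxels:
    def test_single_voxel_cluster_of_vertices(self):
        g = bk.VoxelGrid.isotropic(9, 1.0)
        mesh = bk.TriangleMesh(np.zeros((3, 3)) + [[0, 0, 0], [0.1, 0, 0],
                                                   [0, 0.1, 0]], [[0, 1, 2]])
        rep = bk.unique_voxel_report(g, mesh)
        assert rep.unique_voxel_count == 1

    def test_count_nondecreasing_under_refinement(self, small_sheet):
        white, _ = small_sheet
        g = bk.VoxelGrid.isotropic((28, 28, 20), 1.0)
        counts = []
        mesh = white
        for _ in range(4):
            counts.append(bk.unique_voxel_report(g, mesh).unique_voxel_count)
            mesh = bk.refine_mesh(mesh, 1)
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_proportion_bounds(self, small_sheet):
        white, _ = small_sheet
        g = bk.VoxelGrid.isotropic((28, 28, 20), 1.0)
        rep = bk.unique_voxel_report(g, white)
        assert isinstance(rep, ProjectionReport)
        assert 0 <= rep.unique_voxel_count <= rep.total_candidate_voxels
        assert 0.0 <= rep.proportion <= 1.0


class TestIntracorticalSmooth:
    def test_uniform_mean_over_bottom_depths(self, small_sheet, rng):
        white, pial = small_sheet
        fam = bk.equidistant_family(white, pial, 0.1)
        maps = [bk.SurfaceMap(rng.normal(size=white.n_vertices), m)
                for m in fam.meshes]
        out = bk.intracortical_smooth(maps, fam, (0.0, 0.2), "uniform")
        expected = np.mean([maps[i].values for i in range(3)], axis=0)
        assert np.allclose(out.values, expected)

    def test_identical_maps_unchanged(self, small_sheet):
        white, pial = small_sheet
        fam = bk.equidistant_family(white, pial, 0.1)
        vals = np.arange(white.n_vertices, dtype=float)
        maps = [bk.SurfaceMap(vals, m) for m in fam.meshes]
        out = bk.intracortical_smooth(maps, fam, (0.0, 0.3))
        assert np.allclose(out.values, vals)

    def test_no_tangential_mixing(self, small_sheet):
        white, pial = small_sheet
        fam = bk.equidistant_family(white, pial, 0.1)
        vals = np.zeros(white.n_vertices)
        vals[7] = 1.0  # tangential impulse, same vertex at every depth
        maps = [bk.SurfaceMap(vals, m) for m in fam.meshes]
        out = bk.intracortical_smooth(maps, fam, (0.0, 0.2))
        assert out.values[7] > 0
        assert np.all(out.values[np.arange(len(vals)) != 7] == 0)

    def test_empty_range_rejected(self, small_sheet):
        white, pial = small_sheet
        fam = bk.equidistant_family(white, pial, 0.1)
        maps = [bk.SurfaceMap(np.zeros(white.n_vertices), m)
                for m in fam.meshes]
        with pytest.raises(ValueError):
            bk.intracortical_smooth(maps, fam, (0.33, 0.34))


class TestClusters:
    def test_two_singletons(self, small_sheet):
        white, _ = small_sheet
        mask = np.zeros(white.n_vertices, bool)
        # pick two vertices that are not adjacent
        e = white.edges
        mask[0] = True
        far = np.setdiff1d(np.arange(white.n_vertices),
                           np.concatenate([e[e[:, 0] == 0, 1],
                                           e[e[:, 1] == 0, 0], [0]]))[-1]
        mask[far] = True
        comps = vertex_clusters(mask, white)
        assert len(comps) == 2
        assert all(len(c) == 1 for c in comps)
        assert not filter_clusters(mask, white, 2).any()

    def test_all_hot_single_cluster(self, small_sheet):
        white, _ = small_sheet
        comps = vertex_clusters(np.ones(white.n_vertices, bool), white)
        assert len(comps) == 1
        assert len(comps[0]) == white.n_vertices

    def test_bridge_removal_matches_flood_fill(self):
        # 7-vertex path graph as a triangle strip, then cut the bridge
        verts = np.column_stack([np.arange(8), np.zeros(8), np.zeros(8)])
        verts = verts + [[0, 0, 0]] * 8
        verts[1::2, 1] = 1.0
        faces = [[i, i + 1, i + 2] for i in range(6)]
        mesh = bk.TriangleMesh(verts, faces)
        mask = np.ones(8, bool)
        mask[3] = False  # cutting vertex 3 splits the strip
        comps = vertex_clusters(mask, mesh)

        # brute-force flood fill oracle
        adj = {i: set() for i in range(8)}
        for a, b in mesh.edges:
            if mask[a] and mask[b]:
                adj[a].add(b)
                adj[b].add(a)
        seen, oracle = set(), []
        for s in range(8):
            if mask[s] and s not in seen:
                stack, comp = [s], set()
                while stack:
                    x = stack.pop()
                    if x in comp:
                        continue
                    comp.add(x)
                    stack.extend(adj[x] - comp)
                seen |= comp
                oracle.append(frozenset(comp))
        assert {frozenset(c.tolist()) for c in comps} == set(oracle)
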
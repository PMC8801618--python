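import numpy as np
import pytest

from luxtomo import mesh_core as mc
from luxtomo import phantom_factory as pf


class TestMakeAndLoad:
    def test_single_tet_counts(self, single_tet_mesh):
        m = single_tet_mesh
        assert m.n_nodes == 4 and m.n_tets == 1
        assert len(m.boundary_faces) == 4

    def test_degenerate_tet_rejected_with_index(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(ValueError, match="tet 0"):
            mc.make_mesh(nodes, [[0, 1, 2, 3]], [0])

    def test_repeated_vertex_rejected(self):
        nodes = np.eye(4, 3)
        with pytest.raises(ValueError, match="repeated"):
            mc.make_mesh(nodes, [[0, 1, 2, 2]], [0])

    def test_orientation_canonicalized(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        m = mc.make_mesh(nodes, [[0, 2, 1, 3]], [0])  # negatively oriented
        assert (m.tet_volumes() > 0).all()

    @pytest.mark.parametrize("ext", [".vtk", ".msh"])
    def test_io_round_trip(self, tmp_path, ext):
        mesh, _, _ = pf.build_phantom(
            pf.PhantomSpec("cylinder", (5.0, 8.0), 2.0,
                           inclusions=[pf.Inclusion("sphere", (0, 0, 4), (2.0,),
                                                    "core")]))
        path = tmp_path / f"phantom{ext}"
        mc.save_mesh(mesh, path)
        back = mc.load_mesh(path)
        assert np.allclose(back.nodes, mesh.nodes)
        assert np.array_equal(back.tets, mesh.tets)
        assert np.array_equal(back.tissue, mesh.tissue)

    def test_unsupported_format(self, tmp_path):
        p = tmp_path / "mesh.stl"
        p.write_text("")
        with pytest.raises(ValueError, match="unsupported"):
            mc.load_mesh(p)

    def test_missing_tissue_field(self, tmp_path, single_tet_mesh):
        path = tmp_path / "m.vtk"
        mc.save_mesh(single_tet_mesh, path)
        with pytest.raises(ValueError, match="not found"):
            mc.load_mesh(path, tissue_field="nosuch")


class TestBoundary:
    def test_two_tets_share_a_face(self, two_tet_mesh):
        faces, owner = mc.extract_boundary_faces(two_tet_mesh)
        assert len(faces) == 6  # 8 faces total, shared one excluded
        assert owner.shape == (6,)

    def test_closed_surface_normals_sum_to_zero(self):
        mesh, _, _ = pf.build_phantom(pf.PhantomSpec("sphere", (6.0,), 1.5))
        normals, area = mc.boundary_face_normals(mesh)
        resultant = (normals * area[:, None]).sum(axis=0)
        assert np.linalg.norm(resultant) < 1e-9 * area.sum()

    def test_nonmanifold_rejected(self):
        # three tets glued on one face
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [0, 0, -1], [1, 1, 1]], float)
        m = mc.TetMesh(nodes=nodes,
                       tets=np.array([[0, 1, 2, 3], [0, 1, 2, 4], [0, 1, 2, 5]]),
                       tissue=np.zeros(3, dtype=np.int64))
        with pytest.raises(ValueError, match="non-manifold"):
            mc.extract_boundary_faces(m)


class TestClassifyRegions:
    def test_by_name_and_degenerate_single_region(self, two_tet_mesh):
        m = mc.classify_regions(two_tet_mesh, {"A": 1, "B": 1})
        assert (m.region == 1).all()

    def test_labels_follow_tissues(self, two_tet_mesh):
        m = mc.classify_regions(two_tet_mesh, {"A": 1, "B": 2})
        assert list(m.region) == [1, 2]

    def test_missing_tissue_errors(self, two_tet_mesh):
        with pytest.raises(ValueError, match="not covered"):
            mc.classify_regions(two_tet_mesh, {"A": 1})


class TestRegroup:
    def test_two_tet_split(self, two_tet_mesh):
        m = mc.classify_regions(two_tet_mesh, {"A": 1, "B": 2})
        rg = mc.regroup_mesh(m)
        assert (rg.n1, rg.n2, rg.t1, rg.t2) == (4, 4, 1, 1)
        assert len(rg.interface_pairs) == 3  # the shared face's vertices
        # interface coordinates agree bitwise
        p1 = rg.mesh1.nodes[rg.interface_pairs[:, 0]]
        p2 = rg.mesh2.nodes[rg.interface_pairs[:, 1]]
        assert np.array_equal(p1, p2)

    def test_single_region_limit(self, two_tet_mesh):
        m = mc.classify_regions(two_tet_mesh, {"A": 2, "B": 2})
        rg = mc.regroup_mesh(m)
        assert rg.t1 == 0 and rg.t2 == 2
        assert len(rg.interface_pairs) == 0
        assert np.array_equal(rg.mesh2.nodes, m.nodes)

    def test_conservation_on_phantom(self):
        mesh, _, _ = pf.build_phantom(pf.PhantomSpec(
            "cylinder", (6.0, 10.0), 1.5,
            inclusions=[pf.Inclusion("sphere", (0, 0, 5), (2.5,), "core")]))
        mesh = mc.classify_regions(mesh, {"adipose": 1, "core": 2})
        rg = mc.regroup_mesh(mesh)
        assert rg.t1 + rg.t2 == mesh.n_tets
        v = rg.mesh1.total_volume() + rg.mesh2.total_volume()
        assert v == pytest.approx(mesh.total_volume(), rel=1e-12)
        # every original node maps to one or two regrouped nodes; exactly the
        # interface nodes map to two
        both = (rg.orig_in_mesh1 >= 0) & (rg.orig_in_mesh2 >= 0)
        assert both.sum() == len(rg.interface_pairs)
        assert ((rg.orig_in_mesh1 >= 0) | (rg.orig_in_mesh2 >= 0)).all()

    def test_determinism(self, two_tet_mesh):
        m = mc.classify_regions(two_tet_mesh, {"A": 1, "B": 2})
        a = mc.regroup_mesh(m)
        b = mc.regroup_mesh(m)
        assert np.array_equal(a.interface_pairs, b.interface_pairs)
        assert np.array_equal(a.mesh1.tets, b.mesh1.tets)

    def test_unregroup_is_isomorphic(self):
        from luxtomo.experiments import _isomorphic

        mesh, _, _ = pf.build_phantom(pf.PhantomSpec(
            "sphere", (6.0,), 1.5,
            inclusions=[pf.Inclusion("sphere", (0, 0, 0), (3.0,), "core")]))
        mesh = mc.classify_regions(mesh, {"adipose": 1, "core": 2})
        merged = mc.merge_regrouped(mc.regroup_mesh(mesh))
        assert _isomorphic(mesh, merged)


class TestInterfaceDuplicates:
    def test_disjoint_meshes_empty(self, single_tet_mesh):
        other = mc.make_mesh(single_tet_mesh.nodes + 10.0,
                             single_tet_mesh.tets, single_tet_mesh.tissue)
        assert len(mc.find_interface_duplicates(single_tet_mesh, other)) == 0

    def test_matches_regroup_bookkeeping(self, two_tet_mesh):
        m = mc.classify_regions(two_tet_mesh, {"A": 1, "B": 2})
        rg = mc.regroup_mesh(m)
        pairs = mc.find_interface_duplicates(rg.mesh1, rg.mesh2)
        assert np.array_equal(np.sort(pairs, axis=0),
                              np.sort(rg.interface_pairs, axis=0))

    def test_tolerance_mode(self, two_tet_mesh):
        m = mc.classify_regions(two_tet_mesh, {"A": 1, "B": 2})
        rg = mc.regroup_mesh(m)
        shifted = mc.make_mesh(rg.mesh2.nodes + 1e-9, rg.mesh2.tets,
                               rg.mesh2.tissue)
        assert len(mc.find_interface_duplicates(rg.mesh1, shifted)) == 0
        pairs = mc.find_interface_duplicates(rg.mesh1, shifted, tol=1e-6)
        assert len(pairs) == 3
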
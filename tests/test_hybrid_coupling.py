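import numpy as np
import pytest

from luxtomo import fem_assembly as fa
from luxtomo import hybrid_coupling as hc
from luxtomo import mesh_core as mc
from luxtomo import pipeline as pl
from luxtomo.optical_props import OpticalProperties


@pytest.fixture
def two_tet_hybrid(two_tet_mesh, mouse_table_610):
    mesh = mc.classify_regions(two_tet_mesh, {"A": 1, "B": 2})
    rg = mc.regroup_mesh(mesh)
    props1 = fa.props_per_tet(rg.mesh1, {"A": mouse_table_610["adipose"],
                                         "B": mouse_table_610["liver"]})
    props2 = fa.props_per_tet(rg.mesh2, {"A": mouse_table_610["adipose"],
                                         "B": mouse_table_610["liver"]})
    de = fa.assemble_de(rg.mesh1, props1)
    sp3 = fa.assemble_sp3(rg.mesh2, props2)
    return rg, de, sp3


class TestBuildHybrid:
    def test_block_diagonal_layout(self, two_tet_hybrid):
        rg, de, sp3 = two_tet_hybrid
        hy = hc.build_hybrid_system(rg, de, sp3)
        assert hy.dimension == rg.n1 + 2 * rg.n2
        M = hy.M.toarray()
        n1 = rg.n1
        assert np.array_equal(M[:n1, :n1], de.M.toarray())
        assert np.array_equal(M[n1:, n1:], sp3.M.toarray())
        assert not M[:n1, n1:].any() and not M[n1:, :n1].any()

    def test_F_row_sums_are_nodal_volumes(self, two_tet_hybrid):
        rg, de, sp3 = two_tet_hybrid
        hy = hc.build_hybrid_system(rg, de, sp3)
        rows = np.asarray(hy.F.sum(axis=1)).ravel()
        v1 = np.asarray(de.F.sum(axis=1)).ravel()
        v2 = np.asarray(sp3.F.sum(axis=1)).ravel()
        assert np.allclose(rows, np.concatenate([v1, v2]))

    def test_dimension_mismatch_rejected(self, two_tet_hybrid):
        rg, de, sp3 = two_tet_hybrid
        with pytest.raises(ValueError, match="dimension"):
            hc.build_hybrid_system(rg, sp3, de)

    def test_empty_region_passthrough(self, two_tet_mesh, mouse_table_610):
        mesh = mc.classify_regions(two_tet_mesh, {"A": 2, "B": 2})
        rg = mc.regroup_mesh(mesh)
        props = fa.props_per_tet(rg.mesh2, {"A": mouse_table_610["adipose"],
                                            "B": mouse_table_610["liver"]})
        sp3 = fa.assemble_sp3(rg.mesh2, props)
        hy = hc.build_hybrid_system(rg, None, sp3)
        assert np.array_equal(hy.M.toarray(), sp3.M.toarray())


class TestCoupling:
    def test_no_pairs_identity(self, two_tet_mesh, mouse_table_610):
        mesh = mc.classify_regions(two_tet_mesh, {"A": 1, "B": 1})
        rg = mc.regroup_mesh(mesh)
        props = fa.props_per_tet(rg.mesh1, {"A": mouse_table_610["adipose"],
                                            "B": mouse_table_610["liver"]})
        de = fa.assemble_de(rg.mesh1, props)
        hy = hc.build_hybrid_system(rg, de, None)
        coupled = hc.couple_interface_nodes(hy)
        assert np.array_equal(coupled.M.toarray(), hy.M.toarray())

    def test_replaced_rows_encode_fluence_relation(self, two_tet_hybrid):
        rg, de, sp3 = two_tet_hybrid
        coupled = hc.couple_interface_nodes(hc.build_hybrid_system(rg, de, sp3))
        M = coupled.M.toarray()
        Mun = coupled.uncoupled_M.toarray()
        n1, n2 = rg.n1, rg.n2
        for d, s in rg.interface_pairs:
            row = M[n1 + s]
            expect = np.zeros(coupled.dimension)
            expect[n1 + s] = 1.0
            expect[d] = -1.0
            expect[n1 + n2 + s] = -2.0 / 3.0
            assert np.array_equal(row, expect)
            # the diffusion row accumulated the eliminated phi1 row
            assert np.allclose(M[d], Mun[d] + Mun[n1 + s])
            # F row of the constraint is zero
            assert not coupled.F[n1 + s].toarray().any()

    def test_pair_out_of_range_rejected(self, two_tet_hybrid):
        rg, de, sp3 = two_tet_hybrid
        bad = mc.RegroupedMesh(
            mesh1=rg.mesh1, mesh2=rg.mesh2,
            interface_pairs=np.array([[99, 0]]),
            orig_in_mesh1=rg.orig_in_mesh1, orig_in_mesh2=rg.orig_in_mesh2,
            boundary_node_order=rg.boundary_node_order)
        hy = hc.build_hybrid_system(bad, de, sp3)
        with pytest.raises(ValueError, match="out of range"):
            hc.couple_interface_nodes(hy)


class TestSourceWeights:
    def test_zero_source_zero_rhs(self, two_tet_hybrid):
        rg, de, sp3 = two_tet_hybrid
        hy = hc.couple_interface_nodes(hc.build_hybrid_system(rg, de, sp3))
        rhs = hc.merge_source_weights(hy, np.zeros(5))
        assert not rhs.any()

    def test_uniform_source_integrates_to_volume(self, two_tet_hybrid):
        """F rows integrate a unit-density source to the domain volume in the
        phi block (and -2/3 of it in the phi2 block), interface rows excepted."""
        rg, de, sp3 = two_tet_hybrid
        hy = hc.build_hybrid_system(rg, de, sp3)  # uncoupled: clean bookkeeping
        rhs = hc.merge_source_weights(hy, np.ones(5))
        n1, n2 = rg.n1, rg.n2
        v1 = rg.mesh1.total_volume()
        v2 = rg.mesh2.total_volume()
        assert rhs[:n1].sum() == pytest.approx(v1, rel=1e-12)
        assert rhs[n1:n1 + n2].sum() == pytest.approx(v2, rel=1e-12)
        assert rhs[n1 + n2:].sum() == pytest.approx(-2 / 3 * v2, rel=1e-12)

    def test_length_mismatch_rejected(self, two_tet_hybrid):
        rg, de, sp3 = two_tet_hybrid
        hy = hc.build_hybrid_system(rg, de, sp3)
        with pytest.raises(ValueError, match="length"):
            hc.merge_source_weights(hy, np.ones(7))


class TestLimitEquivalence:
    """The hybrid must contain both pure models as special cases."""

    def test_all_region1_equals_pure_de(self, two_region_sphere):
        mesh, S, table = two_region_sphere
        m_de, _, _ = pl.forward_surface(mesh, table, S, model="de")
        m_h, _, _ = pl.forward_surface(mesh, table, S, model="mrhm",
                                       region_map={"adipose": 1, "liver": 1})
        diff = np.abs(m_h.values - m_de.values).max() / np.abs(m_de.values).max()
        assert diff < 1e-10

    def test_all_region2_equals_pure_sp3(self, two_region_sphere):
        mesh, S, table = two_region_sphere
        m_sp, _, _ = pl.forward_surface(mesh, table, S, model="sp3")
        m_h, _, _ = pl.forward_surface(mesh, table, S, model="mrhm",
                                       region_map={"adipose": 2, "liver": 2})
        diff = np.abs(m_h.values - m_sp.values).max() / np.abs(m_sp.values).max()
        assert diff < 1e-10


class TestInterfacePhysics:
    def test_continuity_after_solve(self, two_region_sphere):
        mesh, S, table = two_region_sphere
        meas, x, tm = pl.forward_surface(mesh, table, S, model="mrhm",
                                         region_map={"adipose": 1, "liver": 2})
        rg = tm.regrouped
        assert len(rg.interface_pairs) > 0
        d = rg.interface_pairs[:, 0]
        s = rg.interface_pairs[:, 1]
        jump = np.abs(x[d] - (x[rg.n1 + s] - 2 / 3 * x[rg.n1 + rg.n2 + s]))
        assert jump.max() < 1e-10 * np.abs(meas.values).max()

    def test_homogeneous_split_tracks_pure_models(self, two_region_sphere,
                                                  mouse_table_610):
        """With identical optics in both regions the hybrid should stay close
        to the pure diffusion solution (the coupling must not distort a
        physically homogeneous problem)."""
        mesh, S, _ = two_region_sphere
        ad = mouse_table_610["adipose"]
        table = {"adipose": ad, "liver": ad}
        m_de, _, _ = pl.forward_surface(mesh, table, S, model="de")
        m_h, _, _ = pl.forward_surface(mesh, table, S, model="mrhm",
                                       region_map={"adipose": 1, "liver": 2})
        diff = np.abs(m_h.values - m_de.values).max() / m_de.values.max()
        assert diff < 0.05
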
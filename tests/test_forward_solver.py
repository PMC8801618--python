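import numpy as np
import pytest

from luxtomo import forward_solver as fs
from luxtomo import pipeline as pl


@pytest.fixture(scope="module")
def solved_hybrid():
    from luxtomo.experiments import two_tissue_sphere

    mesh, S, table = two_tissue_sphere(1.8)
    tm = pl.build_transport_system(mesh, table, "mrhm",
                                   {"adipose": 1, "liver": 2})
    x = tm.solve(S)
    return mesh, S, tm, x


class TestSolveForward:
    def test_zero_rhs_zero_solution(self, solved_hybrid):
        mesh, _, tm, _ = solved_hybrid
        x = fs.solve_forward(tm.system, np.zeros(tm.system.dimension))
        assert not x.any()

    def test_residual_contract(self, solved_hybrid):
        mesh, S, tm, x = solved_hybrid
        rhs = tm.rhs(S)
        res = np.linalg.norm(tm.system.M @ x - rhs) / np.linalg.norm(rhs)
        assert res < 1e-10

    def test_nonnegative_fluence_de_phantom(self, two_region_sphere):
        """Discrete-maximum-principle spot check on a well-shaped diffusive
        phantom (not guaranteed by P1 elements, hence a single benign case)."""
        mesh, S, table = two_region_sphere
        ad = table["adipose"]
        m, x, _ = pl.forward_surface(mesh, {"adipose": ad, "liver": ad}, S,
                                     model="de")
        assert (x > -1e-12 * x.max()).all()


class TestSurfaceFluence:
    def test_all_boundary_nodes(self, solved_hybrid):
        mesh, _, tm, x = solved_hybrid
        meas = tm.surface(x)
        assert len(meas.values) == mesh.boundary_nodes().size
        assert np.array_equal(meas.node_indices, mesh.boundary_nodes())

    def test_fov_selection_geometry(self, solved_hybrid):
        mesh, _, tm, x = solved_hybrid
        bn = mesh.boundary_nodes()
        sel = fs.select_fov_nodes(mesh.nodes, bn, axis=(0, 0, 1),
                                  half_angle_deg=60.0, center=(0, 0, 0))
        assert 0 < sel.size < bn.size
        d = mesh.nodes[sel]
        cosang = d[:, 2] / np.linalg.norm(d, axis=1)
        assert (cosang >= np.cos(np.deg2rad(60.0)) - 1e-12).all()

    def test_empty_selection_rejected(self, solved_hybrid):
        mesh, _, tm, x = solved_hybrid
        with pytest.raises(ValueError, match="empty"):
            tm.surface(x, measurable=np.array([], dtype=int))

    def test_non_boundary_selection_rejected(self, solved_hybrid):
        mesh, _, tm, x = solved_hybrid
        interior = np.setdiff1d(np.arange(mesh.n_nodes), mesh.boundary_nodes())
        with pytest.raises(ValueError, match="non-boundary"):
            tm.surface(x, measurable=interior[:3])

    def test_csv_round_trip(self, solved_hybrid, tmp_path):
        mesh, _, tm, x = solved_hybrid
        meas = tm.surface(x, wavelength=610)
        p = tmp_path / "meas.csv"
        meas.to_csv(p, mesh.nodes)
        back = fs.SurfaceMeasurement.from_csv(p)
        assert back.wavelength == 610
        assert np.allclose(back.values, meas.values)
        assert np.array_equal(back.node_indices, meas.node_indices)


class TestSensitivity:
    def test_forward_consistency_random_sources(self, solved_hybrid):
        mesh, _, tm, _ = solved_hybrid
        sens = tm.sensitivity()
        rng = np.random.default_rng(11)
        for _ in range(4):
            S = rng.random(mesh.n_nodes)
            meas = tm.surface(tm.solve(S))
            assert np.abs(sens.A @ S - meas.values).max() < \
                1e-8 * np.abs(meas.values).max()

    def test_single_row_unit_source_column(self, solved_hybrid):
        mesh, _, tm, _ = solved_hybrid
        node = mesh.boundary_nodes()[5:6]
        sens = tm.sensitivity(measurable=node)
        assert sens.A.shape[0] == 1
        k = mesh.n_nodes // 2
        S = np.zeros(mesh.n_nodes)
        S[k] = 1.0
        val = tm.surface(tm.solve(S), measurable=node).values[0]
        assert sens.A[0, k] == pytest.approx(val, rel=1e-8)

    def test_finite_difference_linearity(self, solved_hybrid):
        mesh, _, tm, _ = solved_hybrid
        sens = tm.sensitivity()
        rng = np.random.default_rng(4)
        S0 = rng.random(mesh.n_nodes)
        dS = rng.random(mesh.n_nodes) * 1e-3
        f0 = tm.surface(tm.solve(S0)).values
        f1 = tm.surface(tm.solve(S0 + dS)).values
        assert np.abs((f1 - f0) - sens.A @ dS).max() < 1e-6 * np.abs(f0).max()


class TestMultispectralStacking:
    def _dummy(self, nrows, ncols, wl, seed):
        rng = np.random.default_rng(seed)
        A = fs.SensitivityMatrix(A=rng.random((nrows, ncols)),
                                 node_indices=np.arange(nrows),
                                 wavelengths=(wl,))
        m = fs.SurfaceMeasurement(wl, np.arange(nrows), rng.random(nrows))
        return A, m

    def test_single_wavelength_passthrough(self):
        A, m = self._dummy(5, 8, 610, 0)
        stacked, phi = fs.stack_multispectral([A], [m])
        assert np.array_equal(stacked.A, A.A)
        assert np.array_equal(phi, m.values)

    def test_two_wavelengths_block_order(self):
        A2, m2 = self._dummy(5, 8, 630, 1)
        A1, m1 = self._dummy(7, 8, 610, 2)
        stacked, phi = fs.stack_multispectral([A2, A1], [m2, m1])
        assert stacked.A.shape == (12, 8)
        assert np.array_equal(stacked.A[:5], A2.A)
        assert np.array_equal(phi[5:], m1.values)
        assert stacked.wavelengths == (630, 610)

    def test_column_mismatch_rejected(self):
        A2, m2 = self._dummy(5, 8, 630, 1)
        A1, m1 = self._dummy(5, 9, 610, 2)
        with pytest.raises(ValueError, match="differ"):
            fs.stack_multispectral([A2, A1], [m2, m1])

    def test_redundant_stack_recovers_single_solution(self):
        """Identical blocks with consistent data: stacked least squares equals
        the single-block solution."""
        rng = np.random.default_rng(3)
        A = rng.random((12, 6))
        S = rng.random(6)
        b = A @ S
        single, *_ = np.linalg.lstsq(A, b, rcond=None)
        double, *_ = np.linalg.lstsq(np.vstack([A, A]),
                                     np.concatenate([b, b]), rcond=None)
        assert np.allclose(single, double)
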
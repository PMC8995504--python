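import numpy as np
import pytest
from scipy.sparse import linalg as spla

from femstrength.fe_solver import (ConvergenceError, PipelineConfig, _b_matrices,
                                   _c_unit, assemble, run_pipeline,
                                   solve_compression)
from femstrength.calibration import CalibrationLine
from femstrength.material_model import MaterialTable, bin_materials
from femstrength.volume import CTVolume


def _uniform_table(n, E, sigma_y=np.inf, poisson=0.3):
    return MaterialTable(n_bins=1, bin_edges=np.array([0.0, 2.0]),
                         rho_mid=np.array([1.0]), E=np.array([float(E)]),
                         sigma_y=np.array([float(sigma_y)]),
                         poisson=float(poisson),
                         element_to_bin=np.zeros(n, dtype=int))


class TestAssemble:
    def test_single_element_symmetric_with_zero_row_sums(self, column_model_factory):
        model, _ = column_model_factory(column_shape=(1, 1, 1))
        K = assemble(model, _uniform_table(1, E=1.0, poisson=0.0)).toarray()
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        # translation = zero strain: rows sum to zero per component
        for comp in range(3):
            t = np.zeros(24)
            t[comp::3] = 1.0
            np.testing.assert_allclose(K @ t, 0.0, atol=1e-12)

    def test_six_rigid_body_modes(self, column_model_factory):
        model, _ = column_model_factory(column_shape=(2, 2, 2))
        K = assemble(model, _uniform_table(8, E=1.0, poisson=0.25)).toarray()
        eig = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(eig) < 1e-9 * eig.max()) == 6

    def test_material_size_mismatch_rejected(self, column_model_factory):
        model, _ = column_model_factory(column_shape=(2, 2, 2))
        with pytest.raises(ValueError, match="bone elements"):
            assemble(model, _uniform_table(5, E=1.0))


class TestPatchTest:
    def test_affine_boundary_displacement_gives_exact_uniform_strain(
            self, column_model_factory):
        model, _ = column_model_factory(column_shape=(2, 2, 2))
        mats = _uniform_table(8, E=3000.0, poisson=0.3)
        K = assemble(model, mats).tocsr()
        A = np.array([[1e-3, 2e-4, -1e-4],
                      [2e-4, -5e-4, 3e-4],
                      [-1e-4, 3e-4, 4e-4]])   # symmetric strain field
        u_exact = model.nodes @ A.T
        interior = np.all((model.nodes > model.nodes.min(0))
                          & (model.nodes < model.nodes.max(0)), axis=1)
        dofs = np.arange(3 * model.n_nodes).reshape(-1, 3)
        free = dofs[interior].ravel()
        pres = dofs[~interior].ravel()
        u = u_exact.ravel().copy()
        rhs = -K[free][:, pres] @ u[pres]
        u[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
        np.testing.assert_allclose(u.reshape(-1, 3), u_exact, atol=1e-12)

        # The recovered strain at every Gauss point equals the imposed field.
        B, _ = _b_matrices(model.element_size)
        eps_exact = np.array([A[0, 0], A[1, 1], A[2, 2],
                              2 * A[0, 1], 2 * A[1, 2], 2 * A[0, 2]])
        for e in range(model.n_elements):
            ue = u.reshape(-1, 3)[model.elements[e]].ravel()
            eps = np.einsum("gck,k->gc", B, ue)
            np.testing.assert_allclose(eps, np.tile(eps_exact, (8, 1)),
                                       atol=1e-12)


class TestColumnOracles:
    def test_elastic_reaction_matches_closed_form(self, column_model_factory):
        model, mats = column_model_factory(column_shape=(4, 4, 8), E=5000.0,
                                           poisson=0.0)
        sol = solve_compression(model, mats, target_deformation=0.04, n_steps=1)
        h = model.element_size
        expected = 5000.0 * 0.04 * (4 * h) ** 2
        assert sol.femoral_strength == pytest.approx(expected, rel=5e-3)
        assert sol.equilibrium_residual < 1e-6

    def test_two_element_series_compliance(self, column_model_factory):
        # Halving the column height doubles the stiffness: series springs.
        m1, t1 = column_model_factory(column_shape=(1, 1, 1), E=2000.0, poisson=0.0)
        m2, t2 = column_model_factory(column_shape=(1, 1, 2), E=2000.0, poisson=0.0)
        delta = 0.01  # mm, same end displacement for both columns
        r1 = solve_compression(m1, t1, target_deformation=delta / m1.femoral_height,
                               n_steps=1).femoral_strength
        r2 = solve_compression(m2, t2, target_deformation=delta / m2.femoral_height,
                               n_steps=1).femoral_strength
        assert r2 == pytest.approx(r1 / 2, rel=1e-9)

    def test_plastic_limit_load_matches_sigma_a(self, column_model_factory):
        model, mats = column_model_factory(column_shape=(4, 4, 16), E=5000.0,
                                           sigma_y=20.0, poisson=0.0)
        sol = solve_compression(model, mats, target_deformation=0.04, n_steps=20)
        h = model.element_size
        assert sol.femoral_strength == pytest.approx(20.0 * (4 * h) ** 2, rel=0.01)
        # reaction history is monotone under monotone loading
        forces = [f for _, f in sol.reaction_history]
        assert np.all(np.diff(forces) > -1e-9 * forces[-1])
        # return mapping leaves no stress above the yield surface
        assert sol.max_overshoot < 1e-10

    def test_dense_direct_solve_equivalence(self, column_model_factory):
        model, mats = column_model_factory(column_shape=(4, 4, 8), E=4000.0,
                                           poisson=0.35)
        sol = solve_compression(model, mats, target_deformation=0.01, n_steps=1,
                                linear_solver="cg", rtol=1e-12)
        # Independent route: dense direct solve of the constrained system.
        K = assemble(model, mats).toarray()
        ndof = 3 * model.n_nodes
        fixed = (3 * model.bottom_surface_nodes[:, None] + np.arange(3)).ravel()
        driven = 3 * model.top_surface_nodes + 2
        u = np.zeros(ndof)
        u[driven] = -0.01 * model.femoral_height
        free = np.setdiff1d(np.arange(ndof), np.union1d(fixed, driven))
        u[free] = np.linalg.solve(K[np.ix_(free, free)],
                                  -K[np.ix_(free, np.union1d(fixed, driven))]
                                  @ u[np.union1d(fixed, driven)])
        scale = np.abs(u).max()
        np.testing.assert_allclose(sol.displacements.ravel(), u,
                                   atol=1e-8 * scale)

    def test_elastic_energy_consistency(self, column_model_factory):
        model, mats = column_model_factory(column_shape=(3, 3, 6), E=6000.0,
                                           poisson=0.4)
        delta_frac = 0.01
        sol = solve_compression(model, mats, target_deformation=delta_frac,
                                n_steps=1, rtol=1e-12)
        K = assemble(model, mats)
        u = sol.displacements.ravel()
        strain_energy = 0.5 * u @ (K @ u)
        work = 0.5 * sol.femoral_strength * delta_frac * model.femoral_height
        assert work == pytest.approx(strain_energy, rel=1e-6)


class TestPipeline:
    def test_strength_stable_under_step_doubling(self, femur_bundle):
        cfg8 = PipelineConfig(element_size=6.0, n_steps=8)
        cfg16 = PipelineConfig(element_size=6.0, n_steps=16)
        s8, _ = run_pipeline(femur_bundle["volume"], femur_bundle["phantom"], cfg8)
        s16, _ = run_pipeline(femur_bundle["volume"], femur_bundle["phantom"], cfg16)
        assert abs(s16.femoral_strength - s8.femoral_strength) \
            / s16.femoral_strength < 0.005

    def test_report_contents(self, femur_bundle):
        _, rep = run_pipeline(femur_bundle["volume"], femur_bundle["phantom"],
                              PipelineConfig(element_size=6.0, n_steps=4))
        assert rep["femoral_strength_N"] > 0
        assert rep["n_materials"] <= 120
        assert rep["calibration"]["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert rep["equilibrium_residual"] < 1e-6

    def test_zero_density_volume_rejected_with_empty_mask(self):
        from femstrength.synthetic_data import default_phantom

        phantom = default_phantom((16, 16, 16), roi_size=3)
        vol = CTVolume(np.zeros((16, 16, 16)))
        line = CalibrationLine(0.001, 0.0, 1.0, 3)
        with pytest.raises(ValueError, match="empty bone mask"):
            run_pipeline(vol, phantom, PipelineConfig(calibration_line=line))
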
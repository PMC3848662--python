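"""Implicit-Euler stepping: initialization, steady states, scalar-oracle
equivalence, conservation and determinism."""

import dataclasses

import numpy as np
import pytest

from ionfem.kinetics import BasicParams, SpeciesSpec, basic_model, custom_model
from ionfem.mesh import generate_ellipse_mesh
from ionfem.stepper import SolverConfig, initialize, simulate

from oracles import scalar_backward_euler


def zero_kinetics(n):
    return custom_model([[] for _ in range(n)])


@pytest.fixture(scope="module")
def small_mesh():
    return generate_ellipse_mesh(2.0, 1.0, 0.35)


class TestInitialize:
    def test_zero_potential_keeps_concentrations(self, small_mesh):
        species = [SpeciesSpec("a", 1e-3, 1, 2.5), SpeciesSpec("b", 1e-3, 0, 7.0)]
        cfg = SolverConfig(dt=1e-3, t_end=1e-3)
        st = initialize(small_mesh, species, cfg, 0.0)
        assert np.allclose(st.xi[0], 2.5)
        assert np.allclose(st.xi[1], 7.0)

    def test_zero_concentration_stays_zero(self, small_mesh):
        species = [SpeciesSpec("a", 1e-3, 1, 0.0)]
        cfg = SolverConfig(dt=1e-3, t_end=1e-3)
        st = initialize(small_mesh, species, cfg, -80.0)
        assert np.all(st.xi[0] == 0.0)

    def test_resting_potential_slotboom_factor(self, small_mesh):
        # m/d = 1: interior p0 = exp(phi0/V_T) = exp(-80/25.693)
        species = [SpeciesSpec("a", 1e-3, 1, 1.0)]
        cfg = SolverConfig(dt=1e-3, t_end=1e-3, v_thermal=25.693)
        st = initialize(small_mesh, species, cfg, -80.0)
        interior = small_mesh.interior_nodes
        p0 = st.xi[0][interior]  # C0 = 1, so xi = p0
        assert np.allclose(p0, np.exp(-80.0 / 25.693), rtol=1e-12)
        assert np.allclose(st.xi[0][small_mesh.boundary_nodes], 1.0)

    def test_boundary_potential_zeroed(self, small_mesh):
        species = [SpeciesSpec("a", 1e-3, 1, 1.0)]
        cfg = SolverConfig(dt=1e-3, t_end=1e-3)
        st = initialize(small_mesh, species, cfg, -80.0)
        assert np.all(st.phi[small_mesh.boundary_nodes] == 0.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SpeciesSpec("a", 1e-3, 1, -1.0)
        with pytest.raises(ValueError):
            SolverConfig(dt=-1.0, t_end=1.0)
        with pytest.raises(ValueError):
            SolverConfig(dt=1e-3, t_end=1.0, eps=0.0)


class TestSteadyStates:
    def test_uniform_neutral_reaction_free_state_is_fixed(self, small_mesh):
        """No reactions, no charge, uniform data: pure diffusion with no-flux
        boundaries keeps the uniform field exactly."""
        species = [SpeciesSpec("a", 1e-3, 0, 3.0), SpeciesSpec("b", 2e-3, 0, 1.0)]
        cfg = SolverConfig(dt=1e-2, t_end=5e-2, fixed_charge=0.0)
        traj = simulate(small_mesh, species, zero_kinetics(2), cfg, phi0=0.0)
        assert np.allclose(traj.probe_concentrations[-1, 0], [3.0, 1.0], rtol=1e-10)
        assert np.all(np.abs(traj.probe_potential) < 1e-10)


class TestWellMixedOracle:
    def test_basic_model_matches_scalar_backward_euler(self, small_mesh):
        """With z = 0, f = 0 and uniform data the nodal trajectories reduce to
        the scalar backward-Euler recursion with the same lagged denominator."""
        species = [
            SpeciesSpec("enzyme", 1e-3, 0, 1.0),
            SpeciesSpec("substrate", 2e-3, 0, 800.0),
            SpeciesSpec("product", 5e-3, 0, 0.0),
        ]
        model = basic_model(BasicParams(k2=1.4e4, km=90.0, c1_0=1.0))
        cfg = SolverConfig(dt=1e-3, t_end=6e-3, eps=1e-4, fixed_charge=0.0)
        traj = simulate(small_mesh, species, model, cfg, phi0=0.0)
        oracle = scalar_backward_euler(
            [1.0, 800.0, 0.0], 6, 1e-3, model, cfg.eps, small_mesh.area()
        )
        probe = traj.probe_concentrations[:, 0, :]
        dev = np.abs(probe - oracle) / np.maximum(np.abs(oracle), 1e-12)
        assert dev.max() < 1e-8

    def test_suicide_model_matches_scalar_backward_euler(self, small_mesh, suicide_setup):
        _cfg, setup = suicide_setup
        species = [dataclasses.replace(s, z=0) for s in setup.species]
        cfg = SolverConfig(dt=1e-2, t_end=5e-2, eps=1e-4, fixed_charge=0.0)
        traj = simulate(small_mesh, species, setup.kinetics, cfg, phi0=0.0)
        oracle = scalar_backward_euler(
            [s.c0 for s in species], 5, 1e-2, setup.kinetics, cfg.eps, small_mesh.area()
        )
        probe = traj.probe_concentrations[:, 0, :]
        dev = np.abs(probe - oracle) / np.maximum(np.abs(oracle), 1e-12)
        assert dev.max() < 1e-8


class TestConservation:
    def test_total_enzyme_integral_constant(self, small_mesh, basic_setup):
        """1' A^n xi^n is invariant for the enzyme (no reaction term), an exact
        identity of the scheme even with drift switched on."""
        import ionfem.fem as fem
        from ionfem.electro import PoissonSolver
        from ionfem.stepper import advance

        _cfg, setup = basic_setup
        cfg = dataclasses.replace(setup.solver, t_end=0.01)
        st = initialize(small_mesh, setup.species, cfg, -80.0)
        ps = PoissonSolver(small_mesh, cfg.epsilon, cfg.quad_degree)
        ones = np.ones(small_mesh.n_nodes)
        rho = setup.species[0].ratio / cfg.v_thermal
        m0 = ones @ (st._A[rho] @ st.xi[0])
        for _ in range(10):
            st = advance(st, small_mesh, setup.species, setup.kinetics, cfg, _poisson=ps)
            m = ones @ (st._A[rho] @ st.xi[0])
            assert abs(m - m0) <= 1e-10 * abs(m0)

    def test_substrate_plus_product_conserved_without_drift(self, small_mesh):
        species = [
            SpeciesSpec("enzyme", 1e-3, 0, 1.0),
            SpeciesSpec("substrate", 2e-3, 0, 800.0),
            SpeciesSpec("product", 5e-3, 0, 0.0),
        ]
        model = basic_model(BasicParams(k2=1.4e4, km=90.0, c1_0=1.0))
        cfg = SolverConfig(dt=1e-3, t_end=0.05, eps=1e-4, fixed_charge=0.0)
        traj = simulate(small_mesh, species, model, cfg, phi0=0.0)
        total = traj.probe_concentrations[:, 0, 1] + traj.probe_concentrations[:, 0, 2]
        assert np.all(np.abs(total - 800.0) <= 0.01 * 800.0)


class TestTrajectoryShape:
    def test_step_count_is_ceiling(self, small_mesh):
        species = [SpeciesSpec("a", 1e-3, 0, 1.0)]
        cfg = SolverConfig(dt=3e-3, t_end=1e-2, fixed_charge=0.0)
        traj = simulate(small_mesh, species, zero_kinetics(1), cfg)
        assert len(traj.times) == 4 + 1  # ceil(0.01/0.003) = 4 steps plus t=0

    def test_deterministic_repeat(self, small_mesh):
        species = [SpeciesSpec("a", 1e-3, 1, 1.0)]
        cfg = SolverConfig(dt=1e-3, t_end=5e-3, fixed_charge=0.1)
        t1 = simulate(small_mesh, species, zero_kinetics(1), cfg, phi0=-80.0)
        t2 = simulate(small_mesh, species, zero_kinetics(1), cfg, phi0=-80.0)
        assert np.array_equal(t1.probe_concentrations, t2.probe_concentrations)
        assert np.array_equal(t1.probe_potential, t2.probe_potential)

    def test_picard_increments_nonnegative_and_converged(self, basic_run):
        _mesh, setup, traj = basic_run
        for diag in traj.diagnostics:
            assert np.all(diag.increments >= 0.0)
            if diag.converged:
                assert diag.increments[-1].sum() < setup.solver.eps


class TestReferenceRunBehaviour:
    def test_substrate_monotone_decreasing_product_increasing(self, basic_run):
        """Substrate decay mirrors product appearance at the cell center."""
        _mesh, _setup, traj = basic_run
        sub = traj.probe_concentrations[:, 0, 1]
        prod = traj.probe_concentrations[:, 0, 2]
        assert np.all(np.diff(sub) <= 1e-9)
        # product rises while substrate lasts; late-time drift may shed a little
        rise_phase = sub > 1.0
        assert np.all(np.diff(prod[rise_phase]) >= -1e-9)

    def test_concentrations_never_meaningfully_negative(self, basic_run):
        _mesh, _setup, traj = basic_run
        assert traj.min_concentration >= -1e-8
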
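import numpy as np
import pytest
from scipy.special import j0, jn_zeros

from npcable import (PhysicalConstants, Simulator, SolverSettings,
                     SpeciesTable, StimulusProtocol, SuicideSubstrateParams,
                     generate_ellipse_mesh, simulate_well_mixed)

UNIFORM_REST = dict(constants=PhysicalConstants(phi0=0.0), stimulus=None)


@pytest.fixture(scope="module")
def small_mesh():
    return generate_ellipse_mesh(2.0, 1.0, 0.3)


class TestFixedPointsAndConservation:
    def test_chemical_equilibrium_is_a_fixed_point(self, small_mesh):
        """All mass in P and Ei gives F = 0; with phi = 0 and no stimulus the
        state must not move."""
        species = SpeciesTable(c0=(0.0, 0.0, 0.0, 0.0, 0.3, 0.2))
        sim = Simulator(small_mesh, species=species,
                        settings=SolverSettings(T=20e-5), **UNIFORM_REST)
        res = sim.run()
        s = res.final_state
        assert np.abs(s.phi).max() < 1e-12
        for i, c in enumerate(species.c0):
            np.testing.assert_allclose(s.C[i], c, atol=1e-11)

    def test_moiety_conservation_per_step_with_stimulus(self, small_mesh):
        """No-flux transport plus stoichiometry keep both moiety integrals
        constant to solver tolerance at every step, stimulus on."""
        sim = Simulator(small_mesh, settings=SolverSettings(T=1.5e-3),
                        stimulus=StimulusProtocol(onset=5e-5))
        state = sim.initial_state()
        m0 = sim.moiety_totals(state)
        for _ in range(sim.settings.n_steps):
            state = sim.step(state)
            m = sim.moiety_totals(state)
            assert abs(m["enzyme"] - m0["enzyme"]) <= 1e-10 * m0["enzyme"]
            assert abs(m["substrate"] - m0["substrate"]) \
                <= 1e-10 * m0["substrate"]

    def test_species_mass_conserved_without_reaction(self, small_mesh):
        """Pure transport (reaction off via equilibrium composition, stimulus
        shaping phi) moves no total mass: 1^T M C_i is invariant even with
        drift active."""
        species = SpeciesTable(c0=(0.0, 0.0, 0.0, 0.0, 0.4, 0.1))
        sim = Simulator(small_mesh, species=species,
                        settings=SolverSettings(T=5e-4),
                        stimulus=StimulusProtocol(onset=1e-5))
        state = sim.initial_state()   # phi0=-80: strong gradients at boundary
        m0 = sim.moiety_totals(state)["per_species"]
        for _ in range(sim.settings.n_steps):
            state = sim.step(state)
        mT = sim.moiety_totals(state)["per_species"]
        np.testing.assert_allclose(mT, m0, rtol=1e-10, atol=1e-12)


class TestUniformLimit:
    def test_matches_well_mixed_rk4_oracle(self, small_mesh):
        """Spatially uniform start, phi(0) = 0, no stimulus: every node must
        follow the 0-D kinetics; backward Euler at dt=1e-5 stays within 1e-4
        relative of the RK4 reference."""
        sim = Simulator(small_mesh, settings=SolverSettings(T=0.006),
                        **UNIFORM_REST)
        res = sim.run()
        ref = simulate_well_mixed(SuicideSubstrateParams(),
                                  np.array([0.5, 0.5, 0, 0, 0, 0.0]),
                                  T=0.006, dt=1e-6)
        cT = res.final_state.C
        scale = 0.5                       # moiety concentration scale e0 = s0
        assert np.abs(cT - ref.final()[:, None]).max() / scale < 1e-4

    def test_uniform_state_stays_uniform(self, small_mesh):
        sim = Simulator(small_mesh, settings=SolverSettings(T=1e-3),
                        **UNIFORM_REST)
        res = sim.run()
        C = res.final_state.C
        # the mV-scale ionic potential induces only sub-nM drift nonuniformity
        assert np.abs(C - C.mean(axis=1, keepdims=True)).max() < 1e-6


class TestPotentialStep:
    def test_heat_mode_decay_rate(self):
        """Ionic coupling off, no stimulus: the potential solves the heat
        equation.  A fundamental disc mode J0(j01 r) must decay like
        exp(-D j01^2 t) (separation of variables)."""
        mesh = generate_ellipse_mesh(1.0, 1.0, 0.08)
        cst = PhysicalConstants(faraday_model=0.0, phi0=0.0)
        lam1 = jn_zeros(0, 1)[0] ** 2                  # ~5.783
        T, dt = 0.02, 2e-5
        sim = Simulator(mesh, constants=cst, stimulus=None,
                        settings=SolverSettings(dt=dt, T=T))
        state = sim.initial_state()
        r = np.linalg.norm(mesh.nodes, axis=1)
        state.phi = j0(jn_zeros(0, 1)[0] * np.clip(r, 0, 1.0))
        state.phi[mesh.boundary_nodes] = 0.0
        c0 = state.phi[mesh.nearest_node((0, 0))]
        for _ in range(sim.settings.n_steps):
            state = sim.step(state)
        decay = state.phi[mesh.nearest_node((0, 0))] / c0
        assert decay == pytest.approx(np.exp(-sim.D * lam1 * T), rel=0.05)

    def test_rest_until_onset_then_response(self, small_mesh):
        """The stimulated run is bit-identical to the unstimulated one before
        onset and departs after it."""
        settings = SolverSettings(T=3e-3)
        on = Simulator(small_mesh, settings=settings).run()
        off = Simulator(small_mesh, stimulus=None, settings=settings).run()
        onset = StimulusProtocol().onset
        pre = on.t <= onset
        np.testing.assert_array_equal(on.probe_phi[0][pre],
                                      off.probe_phi[0][pre])
        assert np.abs(on.probe_phi[0] - off.probe_phi[0]).max() > 0.0

    def test_blowup_reports_step(self, small_mesh):
        sim = Simulator(small_mesh, settings=SolverSettings(T=1e-4))
        state = sim.initial_state()
        state.phi = state.phi * np.inf
        state.phi[np.isnan(state.phi)] = 0.0
        with pytest.raises(RuntimeError, match="blow-up"):
            sim.rk2_potential_step(state, 1e-5)


class TestSchemes:
    def test_newton_matches_picard(self, small_mesh):
        runs = {}
        for scheme in ("picard", "newton"):
            sim = Simulator(small_mesh,
                            settings=SolverSettings(T=2e-4, scheme=scheme))
            runs[scheme] = sim.run().final_state
        np.testing.assert_allclose(runs["newton"].C, runs["picard"].C,
                                   atol=1e-10)

    def test_picard_nonconvergence_reports_history(self, small_mesh):
        sim = Simulator(small_mesh,
                        settings=SolverSettings(T=2e-5, picard_max=1,
                                                picard_tol=1e-14))
        with pytest.raises(RuntimeError, match="residual history"):
            sim.run()

    def test_time_refinement_self_consistency(self, small_mesh):
        """Halving dt changes the final fields by well under 1% (the time
        discretization is in its convergent regime)."""
        finals = []
        for dt in (2e-5, 1e-5):
            sim = Simulator(small_mesh,
                            settings=SolverSettings(dt=dt, T=3e-3))
            finals.append(sim.run().final_state)
        dphi = np.abs(finals[0].phi - finals[1].phi).max()
        assert dphi < 0.01 * np.abs(finals[1].phi).max()


class TestRunBookkeeping:
    def test_step_count_and_zero_horizon(self, small_mesh):
        assert SolverSettings().n_steps == 600
        sim = Simulator(small_mesh, settings=SolverSettings(T=0.0))
        res = sim.run()
        assert res.summary["n_steps"] == 0
        np.testing.assert_array_equal(res.final_state.C,
                                      sim.initial_state().C)

    def test_determinism_bitwise(self, small_mesh):
        a = Simulator(small_mesh, settings=SolverSettings(T=1e-3)).run()
        b = Simulator(small_mesh, settings=SolverSettings(T=1e-3)).run()
        np.testing.assert_array_equal(a.final_state.phi, b.final_state.phi)
        np.testing.assert_array_equal(a.final_state.C, b.final_state.C)

    def test_snapshot_count(self, small_mesh):
        sim = Simulator(small_mesh, settings=SolverSettings(T=1e-4))  # 10 steps
        res = sim.run(snapshot_stride=3)
        assert len(res.snapshots) == 10 // 3 + 1

    def test_boundary_potential_pinned(self, small_mesh):
        sim = Simulator(small_mesh, settings=SolverSettings(T=5e-4))
        res = sim.run()
        assert np.abs(res.final_state.phi[small_mesh.boundary_nodes]).max() \
            == 0.0
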
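import numpy as np
import pytest
from scipy.linalg import expm

from rdconnectome import (
    Connectome,
    GMParams,
    IntegrationError,
    ModulationSchedule,
    OUNoise,
    SolverConfig,
    build_coupling,
    insert_distance_nodes,
    integrate,
    ou_step,
    schedule_multiplier,
)
from rdconnectome.stability import gm_params_for


class _NoReaction:
    """Pure-diffusion model used for conservation checks."""

    species = ("U", "V")
    diffusion = (1.0, 1.0)

    @staticmethod
    def reaction(u, v):
        return np.zeros_like(u), np.zeros_like(v)


def _relay_chain():
    c = Connectome.from_edges([("A", "B", 1.0)])
    expanded, _ = insert_distance_nodes(c, D=0.1, theta=1.0, relay_counts=1)
    return expanded


class TestIntegrate:
    def test_gm_fixed_point_is_stationary(self):
        p = gm_params_for(0.01, 0.01)
        traj = integrate(p, np.zeros((1, 1)), np.array([[2.0], [4.0]]),
                         SolverConfig(method="rk4", dt=2.0, n_steps=1000))
        assert np.abs(traj.states[:, 0, :] - [[2.0], [4.0]]).max() < 1e-6

    @pytest.mark.parametrize("method", ["euler", "rk4", "implicit_euler"])
    def test_pure_diffusion_conserves_mass(self, fixture_connectome, method):
        n = fixture_connectome.n_nodes
        rng = np.random.default_rng(0)
        init = rng.uniform(0, 1, (2, n))
        traj = integrate(_NoReaction(), fixture_connectome, init,
                         SolverConfig(method=method, dt=0.01, n_steps=200))
        totals = traj.states.sum(axis=1)
        assert np.abs(totals - totals[:, :1]).max() < 1e-8

    def test_symmetric_pair_equilibrates(self, symmetric_pair):
        traj = integrate(_NoReaction(), symmetric_pair,
                         np.array([[1.0, 0.0], [0.0, 1.0]]),
                         SolverConfig(method="rk4", dt=0.05, n_steps=400))
        np.testing.assert_allclose(traj.states[:, :, -1], 0.5, atol=1e-6)

    def test_euler_vs_rk4_agree_on_relay_chain(self):
        """Cross-solver oracle on the linear three-node relay system."""
        chain = _relay_chain()
        init = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        t_end = 10.0
        fine = integrate(_NoReaction(), chain, init,
                         SolverConfig(method="euler", dt=1e-4, n_steps=100000))
        coarse = integrate(_NoReaction(), chain, init,
                           SolverConfig(method="rk4", dt=1e-2, n_steps=1000))
        assert fine.times[-1] == pytest.approx(t_end)
        assert np.abs(fine.states[0, :, -1] - coarse.states[0, :, -1]).max() < 1e-4
        L = build_coupling(chain).matrix
        exact = expm(L * t_end) @ init[0]
        assert np.abs(coarse.states[0, :, -1] - exact).max() < 1e-6

    def test_euler_first_order_convergence(self):
        p = gm_params_for(0.002, 0.02)
        init = np.array([[1.0], [1.0]])
        ref = integrate(p, np.zeros((1, 1)), init,
                        SolverConfig(method="rk4", dt=0.01, n_steps=40000))
        errs = []
        for dt, n in [(0.4, 1000), (0.2, 2000)]:
            e = integrate(p, np.zeros((1, 1)), init,
                          SolverConfig(method="euler", dt=dt, n_steps=n))
            errs.append(abs(e.states[0, 0, -1] - ref.states[0, 0, -1]))
        assert errs[1] == pytest.approx(errs[0] / 2, rel=0.25)

    def test_dopri_matches_rk4(self):
        p = gm_params_for(0.01, 0.01)
        init = np.array([[2.1], [4.0]])
        cfg = dict(dt=1.0, n_steps=2000)
        a = integrate(p, np.zeros((1, 1)), init,
                      SolverConfig(method="rk4", **cfg))
        b = integrate(p, np.zeros((1, 1)), init,
                      SolverConfig(method="dopri_adaptive", rel_tol=1e-8,
                                   abs_tol=1e-10, **cfg))
        assert np.abs(a.states[0, 0, -1] - b.states[0, 0, -1]) < 1e-5

    def test_constant_schedule_is_bitwise_identical(self, fixture_connectome):
        p = GMParams()
        n = fixture_connectome.n_nodes
        init = np.ones((2, n))
        cfg = SolverConfig(method="euler", dt=0.5, n_steps=50, seed=9)
        plain = integrate(p, fixture_connectome, init, cfg)
        sched = integrate(p, fixture_connectome, init, cfg,
                          schedule=ModulationSchedule(kind="constant"))
        assert np.array_equal(plain.states, sched.states)

    def test_same_seed_reproduces_noise_path(self, fixture_connectome):
        p = GMParams()
        init = np.ones((2, fixture_connectome.n_nodes))
        cfg = SolverConfig(method="euler", dt=0.1, n_steps=100, seed=5)
        noise = OUNoise(theta=1.0, sigma=0.3)
        a = integrate(p, fixture_connectome, init, cfg, noise=noise)
        b = integrate(p, fixture_connectome, init, cfg, noise=noise)
        assert np.array_equal(a.states, b.states)
        c = integrate(p, fixture_connectome, init,
                      SolverConfig(method="euler", dt=0.1, n_steps=100, seed=6),
                      noise=noise)
        assert not np.array_equal(a.states, c.states)

    def test_blowup_reports_step_index(self):
        p = GMParams(rateA=5.0, muI=0.01)
        with pytest.raises(IntegrationError) as err:
            integrate(p, np.zeros((1, 1)), np.array([[1e3], [1e-3]]),
                      SolverConfig(method="euler", dt=100.0, n_steps=50))
        assert err.value.step is not None

    def test_init_shape_checked(self, symmetric_pair):
        with pytest.raises(ValueError, match="init"):
            integrate(GMParams(), symmetric_pair, np.ones((2, 3)),
                      SolverConfig(n_steps=2))


class TestSchedule:
    def test_step_reduction(self):
        s = ModulationSchedule(kind="step", factor=0.1, onset=100)
        assert schedule_multiplier(s, 99) == 1.0
        assert schedule_multiplier(s, 100) == 0.1
        assert schedule_multiplier(s, 10_000) == 0.1

    def test_constant_is_identity(self):
        s = ModulationSchedule(kind="constant")
        assert all(schedule_multiplier(s, k) == 1.0 for k in (0, 1, 500))

    def test_damped_cosine_stays_in_band(self):
        s = ModulationSchedule(kind="damped_cosine", amplitude=10.0, floor=0.1,
                               period=1000.0, damping=5e-4)
        vals = np.array([schedule_multiplier(s, k) for k in range(10000)])
        assert vals.min() >= 0.1
        assert vals.max() <= 1.0
        assert vals.min() == pytest.approx(0.1)  # amplitude 10 saturates the floor

    def test_invalid_floor_rejected(self):
        with pytest.raises(ValueError):
            ModulationSchedule(kind="damped_cosine", floor=0.0)

    def test_step_schedule_alters_downstream_dynamics(self, fixture_connectome):
        """Reducing DRG->Cu weights changes the cuneate trajectory but leaves
        the isolated DRG source series untouched."""
        p = gm_params_for(0.001, 0.02)
        n = fixture_connectome.n_nodes
        init = np.ones((2, n)) * [[0.5], [0.5]]
        edges = [(f"DRGC{i}_L", "Cu_L") for i in (1, 2, 3)]
        cfg = SolverConfig(method="rk4", dt=2.0, n_steps=500, v_floor=1e-9)
        plain = integrate(p, fixture_connectome, init, cfg)
        lesioned = integrate(p, fixture_connectome, init, cfg,
                             schedule=ModulationSchedule(kind="step", factor=0.3,
                                                         onset=0, edges=edges))
        i_cu = fixture_connectome.index_of("Cu_L")
        i_drg = fixture_connectome.index_of("DRGC1_R")
        assert not np.allclose(plain.states[0, i_cu], lesioned.states[0, i_cu])
        np.testing.assert_allclose(plain.states[0, i_drg],
                                   lesioned.states[0, i_drg], atol=1e-12)


class TestOUNoise:
    def test_noiseless_limit_decays_exponentially(self):
        p = OUNoise(theta=1.0, sigma=0.0, mu=0.0)
        rng = np.random.default_rng(0)
        x, dt = 1.0, 0.001
        for _ in range(1000):
            x = ou_step(x, dt, p, rng)
        assert x == pytest.approx(np.exp(-1.0), rel=1e-2)

    def test_stationary_variance(self):
        """Long-run variance matches sigma^2 / (2 theta)."""
        p = OUNoise(theta=1.0, sigma=0.5)
        rng = np.random.default_rng(12345)
        x, dt = 0.0, 0.01
        samples = np.empty(100_000)
        for i in range(samples.size):
            x = ou_step(x, dt, p, rng)
            samples[i] = x
        var = samples[5000:].var()
        assert var == pytest.approx(0.5**2 / 2.0, rel=0.1)

    def test_identical_seeds_identical_paths(self):
        p = OUNoise(theta=0.5, sigma=0.2)
        a = np.random.default_rng(7)
        b = np.random.default_rng(7)
        xa = xb = 0.3
        for _ in range(100):
            xa = ou_step(xa, 0.01, p, a)
            xb = ou_step(xb, 0.01, p, b)
        assert xa == xb
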
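"""Movement rules, branching gate, anastomosis and reproducibility."""

import math

import numpy as np
import pytest

from angiotop import (DomainConfig, ModelParams, SimulatorSettings, TipCell,
                      ac_move_probabilities, anastomosis_check, branch_check,
                      make_environment, ps_turn_step, simulate,
                      sl_velocity_step)
from angiotop.simulators import _ps_turn_rates


@pytest.fixture
def config():
    return DomainConfig(lattice_resolution=17, n_initial_tips=3,
                        n_timesteps=60)


def uniform_env(config):
    env = make_environment(config, "linear")
    env.vegf[:] = 0.5
    env.fibronectin[:] = 0.5
    return env


def ac_params(chi=0.0, rho=0.0, abr=1e9, cbr=1.0):
    return ModelParams("ac", (chi, rho, abr, min(cbr, 1.0)))


class TestACMoves:
    def test_uniform_fields_symmetric(self, config):
        env = uniform_env(config)
        tip = TipCell(position=np.array([8, 8]))
        p = ac_move_probabilities(tip, env, ac_params(), config)
        assert p[1] == p[2] == p[3] == p[4]
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("chi,rho", [(0.3, 0.0), (1.2, 0.5), (0.0, 0.9)])
    def test_normalization(self, config, chi, rho):
        env = make_environment(config, "exponential")
        for site in [(1, 1), (8, 8), (15, 15), (0, 8)]:
            tip = TipCell(position=np.array(site))
            p = ac_move_probabilities(tip, env, ac_params(chi, rho), config)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p >= 0) and np.all(p <= 1)

    def test_chemotactic_bias_monotone_in_chi(self, config):
        env = make_environment(config, "linear")
        tip = TipCell(position=np.array([8, 8]))
        gaps = []
        for chi in np.arange(0.1, 1.05, 0.1):
            p = ac_move_probabilities(tip, env, ac_params(chi=chi), config)
            gaps.append(p[3] - p[4])  # up minus down
        assert all(g > 0 for g in gaps)
        assert all(b >= a - 1e-12 for a, b in zip(gaps, gaps[1:]))

    def test_haptotactic_bias(self, config):
        env = uniform_env(config)
        # fibronectin increasing in x only
        env.fibronectin[:] = np.linspace(0, 1, 17)[:, None]
        tip = TipCell(position=np.array([8, 8]))
        p = ac_move_probabilities(tip, env, ac_params(rho=0.8), config)
        assert p[1] > p[2]          # +x beats -x
        assert p[3] == pytest.approx(p[4])  # y unaffected

    def test_boundary_moves_blocked(self, config):
        env = uniform_env(config)
        tip = TipCell(position=np.array([0, 0]))
        p = ac_move_probabilities(tip, env, ac_params(), config)
        assert p[2] == 0.0 and p[4] == 0.0
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_weights_stay(self, config):
        env = uniform_env(config)
        tip = TipCell(position=np.array([8, 8]))
        settings = SimulatorSettings(ac_diffusion=0.0, ac_stay_weight=0.0)
        p = ac_move_probabilities(tip, env, ac_params(), config, settings)
        assert p[0] == 1.0 and p[1:].sum() == 0.0


class TestSLVelocity:
    def test_pure_drag_decays(self, config):
        env = uniform_env(config)
        params = ModelParams("sl", (0.0, 0.0, 1e9, 1.0))
        rng = np.random.default_rng(0)
        tip = TipCell(position=np.array([0.5, 0.5]),
                      velocity=np.array([0.3, 0.2]))
        norms = [np.linalg.norm(tip.velocity)]
        for _ in range(30):
            tip = sl_velocity_step(tip, env, params, 0.05, rng)
            norms.append(np.linalg.norm(tip.velocity))
        assert all(b < a for a, b in zip(norms, norms[1:]))
        # explicit Euler relaxation: the norm contracts by (1 - beta dt)/step
        assert norms[-1] == pytest.approx(norms[0] * 0.95 ** 30)

    def test_driftless_noise_has_zero_mean_velocity(self, config):
        env = uniform_env(config)  # zero gradient
        params = ModelParams("sl", (0.0, 0.3, 1e9, 1.0))
        rng = np.random.default_rng(1)
        tip = TipCell(position=np.array([0.5, 0.5]),
                      velocity=np.array([0.0, 0.0]))
        vs = np.empty((10_000, 2))
        for i in range(len(vs)):
            tip = sl_velocity_step(tip, env, params, 0.05, rng)
            vs[i] = tip.velocity
            tip.position[:] = (0.5, 0.5)  # keep away from boundaries
        # OU stationary sd = sigma / sqrt(2 beta); account for autocorrelation
        # (integrated autocorrelation time ~ 2/(beta dt) steps)
        sd = 0.3 / math.sqrt(2.0)
        se = sd / math.sqrt(len(vs) * 0.05 / 2)
        assert abs(vs[:, 0].mean()) < 3 * se
        assert abs(vs[:, 1].mean()) < 3 * se

    def test_chemotactic_drift_matches_ode_oracle(self, config):
        env = make_environment(config, "linear")  # grad c = (0, 1)
        dt, n = 0.05, 100
        for kappa in (0.05, 0.1, 0.2):
            params = ModelParams("sl", (kappa, 0.0, 1e9, 1.0))
            rng = np.random.default_rng(2)
            tip = TipCell(position=np.array([0.5, 0.0]),
                          velocity=np.array([0.0, 0.0]))
            # oracle: integrate dv = (-v + kappa) dt, dy = v dt
            v = y = 0.0
            for _ in range(n):
                v += dt * (-v + kappa)
                y += v * dt
            for _ in range(n):
                tip = sl_velocity_step(tip, env, params, dt, rng)
            assert tip.position[1] == pytest.approx(y, rel=1e-9)
        # displacement increases with kappa (linear ODE: proportional)
        assert y > 0


class TestPSTurning:
    def test_unbiased_turning_symmetric(self):
        grad = np.tile([0.0, 1.0], (12, 1))
        for h in range(-5, 6):
            tp, tm = _ps_turn_rates(np.array([h]), grad[:1], 0.0, 0.3, 1.0,
                                    math.pi / 6)
            assert tp[0] == pytest.approx(tm[0])

    def test_speed_conserved_exactly(self, config):
        env = make_environment(config, "linear")
        params = ModelParams("ps", (1.0, 0.3, 1e9, 1.0))
        settings = SimulatorSettings(ps_speed=0.004)
        rng = np.random.default_rng(3)
        tip = TipCell(position=np.array([0.5, 0.5]), heading=2)
        for _ in range(200):
            old = tip.position.copy()
            tip = ps_turn_step(tip, env, params, 1.0, rng, settings)
            step = np.linalg.norm(tip.position - old)
            assert step == pytest.approx(0.004, abs=1e-12)
            tip.position[:] = (0.5, 0.5)  # stay interior

    def test_tumourward_turns_favoured(self):
        """Heading 90 degrees right of vertical: the turn back toward the
        tumour (decreasing angle) must be more frequent."""
        phi = math.pi / 6
        grad = np.array([[0.0, 1.0]])
        tp, tm = _ps_turn_rates(np.array([3]), grad, 1.0, 0.4, 1.0, phi)
        assert tm[0] > tp[0]
        rng = np.random.default_rng(4)
        n = 100_000
        u = rng.random(n)
        left = np.sum((u >= tp[0]) & (u < tp[0] + tm[0]))
        right = np.sum(u < tp[0])
        p = (tp[0] + tm[0]) / 2
        assert left > right + 3 * math.sqrt(n * p)

    def test_too_fast_turning_rejected(self, config):
        env = make_environment(config, "linear")
        params = ModelParams("ps", (5.0, 0.9, 1e9, 1.0))
        tip = TipCell(position=np.array([0.5, 0.5]), heading=0)
        with pytest.raises(ValueError, match="smaller dt"):
            ps_turn_step(tip, env, params, 1.0, np.random.default_rng(0))


class TestBranchingGate:
    def test_quadrant_exactness(self, config):
        """Branches fire exactly in the quadrant age > abr and c > cbr."""
        env = make_environment(config, "linear")  # c(x, y) = y
        abr, cbr = 10.0, 0.5
        params = ModelParams("ac", (0.5, 0.1, abr, cbr))
        rng = np.random.default_rng(5)
        for age in (8.0, 9.9, 10.0, 10.1, 12.0):
            for y in (0.3, 0.49, 0.5, 0.51, 0.7):
                tip = TipCell(position=np.array([0.5, y]), age=age)
                daughter = branch_check(tip, env, params, rng)
                should = age > abr and y > cbr
                assert (daughter is not None) == should

    def test_degenerate_always_on(self, config):
        env = make_environment(config, "linear")
        params = ModelParams("ac", (0.5, 0.1, 0.0, 0.0))
        rng = np.random.default_rng(6)
        tip = TipCell(position=np.array([0.5, 0.5]), age=0.5)
        assert branch_check(tip, env, params, rng) is not None

    def test_inactive_tip_never_branches(self, config):
        env = make_environment(config, "linear")
        params = ModelParams("ac", (0.5, 0.1, 0.0, 0.0))
        tip = TipCell(position=np.array([0.5, 0.9]), age=5.0, active=False)
        assert branch_check(tip, env, params,
                            np.random.default_rng(0)) is None


class TestAnastomosis:
    def test_no_other_trails_never_fuses(self):
        grid = -np.ones((9, 9), dtype=int)
        grid[4, 4] = 0
        tip = TipCell(position=np.array([0.5, 0.5]), lineage=0)
        assert not anastomosis_check(tip, grid, {(4, 4), (4, 5)})

    def test_foreign_trail_fuses(self):
        grid = -np.ones((9, 9), dtype=int)
        grid[4, 5] = 3
        tip = TipCell(position=np.array([0.5, 0.5]), lineage=0)
        assert anastomosis_check(tip, grid, {(4, 5)})

    def test_forced_collision_recorded(self):
        """Two strongly chemotactic AC tips started adjacently must fuse."""
        config = DomainConfig(lattice_resolution=17, n_initial_tips=8,
                              n_timesteps=60)
        params = ModelParams("ac", (1.5, 0.0, 1e6, 1.0))
        result = simulate("ac", params, config, seed=12)
        assert result.n_anastomoses >= 1


class TestSimulate:
    @pytest.mark.parametrize("model,theta", [
        ("ac", (0.8, 0.2, 20.0, 0.3)),
        ("sl", (0.1, 0.2, 2.0, 0.3)),
        ("ps", (1.0, 0.2, 20.0, 0.3)),
    ])
    def test_reproducible_from_seed(self, model, theta):
        config = DomainConfig(lattice_resolution=17, n_initial_tips=3,
                              n_timesteps=80,
                              dt=0.05 if model == "sl" else 1.0)
        settings = SimulatorSettings(max_tips=32)
        params = ModelParams(model, theta)
        r1 = simulate(model, params, config, 99, settings)
        r2 = simulate(model, params, config, 99, settings)
        assert np.array_equal(r1.trail_cells, r2.trail_cells)
        assert r1.n_branches == r2.n_branches
        assert r1.n_anastomoses == r2.n_anastomoses
        if r1.polylines is not None:
            for a, b in zip(r1.polylines, r2.polylines):
                assert np.array_equal(a, b)

    def test_chemotaxis_raises_trail_height(self):
        config = DomainConfig(lattice_resolution=17, n_initial_tips=3,
                              n_timesteps=60)
        settings = SimulatorSettings(max_tips=16)
        mean_y = {}
        for chi in (0.0, 1.2):
            ys = []
            for seed in range(25):
                r = simulate("ac", ModelParams("ac", (chi, 0.0, 1e6, 1.0)),
                             config, seed, settings)
                ys.append(r.trail_cells[:, 1].mean())
            mean_y[chi] = np.mean(ys)
        assert mean_y[1.2] > mean_y[0.0] + 1.0

    def test_trail_geometry_in_domain(self):
        config = DomainConfig(lattice_resolution=17, n_initial_tips=3,
                              n_timesteps=120, dt=0.05)
        r = simulate("sl", ModelParams("sl", (0.2, 0.3, 1.0, 0.2)), config, 5,
                     SimulatorSettings(max_tips=32))
        for line in r.polylines:
            assert np.all(line >= -1e-9)
            assert np.all(line <= 1.0 + 1e-9)

    def test_counters_nonnegative(self):
        config = DomainConfig(lattice_resolution=17, n_initial_tips=3,
                              n_timesteps=40)
        r = simulate("ps", ModelParams("ps", (0.5, 0.2, 5.0, 0.2)), config, 7,
                     SimulatorSettings(max_tips=32))
        assert r.n_branches >= 0 and r.n_anastomoses >= 0
        assert r.n_tips_total >= config.n_initial_tips
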
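import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoculture import (
    ModelParameters,
    ModelState,
    deterministic_drift,
    draw_innovations,
    equilibrium_fixed_point,
    euler_step,
    simulate,
    standard_parameters,
)
from ecoculture.errors import DegenerateStateError, ParameterError


class TestDrift:
    @pytest.mark.parametrize(
        "rho, c, K, expected_drho",
        [
            (1.0, 0.0, 1.0, 0.0),  # logistic factor vanishes at rho = K
            (0.5, 1.0, 1.0, 0.01 * 0.5 * (1 - 0.25)),  # direct substitution
        ],
    )
    def test_drift_examples(self, rho, c, K, expected_drho):
        params = standard_parameters(sigma=0.0)
        state = ModelState(t=0.0, rho=rho, c=c, K=K)
        drho, dc, dK = deterministic_drift(state, 1.0, params)
        assert drho == pytest.approx(expected_drho, abs=1e-15)
        assert dc == pytest.approx(-params.lam * c)
        assert dK == pytest.approx(-params.eta * (K - 1.0) - params.mu * rho)

    def test_extinction_is_absorbing(self):
        params = standard_parameters()
        state = ModelState(t=0.0, rho=0.0, c=3.0, K=-0.5)
        drho, dc, dK = deterministic_drift(state, 1.0, params)
        assert drho == 0.0  # no growth or decline without a population
        assert dK == pytest.approx(-params.eta * (-0.5 - 1.0))

    def test_degenerate_capacity_raises(self):
        params = standard_parameters()
        state = ModelState(t=0.0, rho=1.0, c=2.0, K=-0.1)
        with pytest.raises(DegenerateStateError, match="K\\(1\\+c\\)"):
            deterministic_drift(state, 1.0, params)


class TestInnovations:
    def test_exponential_limit_mean(self, rng):
        # Weibull with shape 1 is Exponential; closed-form mean = scale
        draws = draw_innovations(rng, shape=1.0, scale=1.0, n=1_000_000)
        assert draws.mean() == pytest.approx(1.0, abs=0.01)

    def test_heavy_tail_median(self, rng):
        # closed-form median: scale * (ln 2)^(1/shape)
        draws = draw_innovations(rng, shape=0.1, scale=1.0, n=1_000_000)
        expected = math.log(2) ** 10
        assert np.median(draws) == pytest.approx(expected, rel=0.05)

    def test_positive_support(self, rng):
        draws = draw_innovations(rng, shape=0.3, scale=2.0, n=10_000)
        assert np.all(draws >= 0.0)

    @pytest.mark.parametrize("shape, scale, n", [(0, 1, 5), (1, -2, 5), (1, 1, 0)])
    def test_invalid_parameters(self, rng, shape, scale, n):
        with pytest.raises(ParameterError):
            draw_innovations(rng, shape=shape, scale=scale, n=n)


class TestEulerStep:
    def test_culture_decay_map(self):
        # sigma = 0 and rho = 0 reduce the step to c -> c (1 - lam dt)
        params = standard_parameters(sigma=0.0, lam=0.01, dt=1.0)
        state = ModelState(t=0.0, rho=0.0, c=2.0, K=1.0)
        for _ in range(50):
            state, _ = euler_step(state, 0.0, 1.0, params)
        assert state.c == pytest.approx(2.0 * (1 - 0.01) ** 50, rel=1e-12)

    def test_matches_compiled_integrator_bitwise(self):
        params = standard_parameters(n_steps=300, seed=5)
        traj = simulate(params)
        state = ModelState(
            t=0.0, rho=params.rho0, c=params.c0, K=params.K_init
        )
        for i in range(params.n_steps):
            state, _ = euler_step(state, traj.xi[i], traj.K0_t[i], params)
            assert state.rho == traj.rho[i + 1]
            assert state.c == traj.c[i + 1]
            assert state.K == traj.K[i + 1]

    def test_negativity_clipping_counted(self):
        # lam*dt > 1 forces a culture overshoot below zero
        params = standard_parameters(sigma=0.0, lam=1.5, dt=1.0)
        state = ModelState(t=0.0, rho=0.5, c=1.0, K=1.0)
        state, events = euler_step(state, 0.0, 1.0, params)
        assert state.c == 0.0
        assert events.clips == 1

    def test_exhausted_resources_guard(self):
        # negative cultural capacity switches growth to intrinsic decline
        params = standard_parameters(sigma=0.0)
        state = ModelState(t=0.0, rho=2.0, c=0.5, K=-1.0)
        new, events = euler_step(state, 0.0, 1.0, params)
        assert events.exhausted
        assert new.rho == pytest.approx(2.0 * (1 - params.alpha))


class TestSimulate:
    def test_trajectory_shapes_and_per_capita(self, stochastic_traj):
        n = stochastic_traj.params.n_steps
        for arr in (
            stochastic_traj.t,
            stochastic_traj.rho,
            stochastic_traj.c,
            stochastic_traj.K,
            stochastic_traj.K0_t,
            stochastic_traj.per_capita,
        ):
            assert len(arr) == n + 1
        assert len(stochastic_traj.xi) == n
        alive = stochastic_traj.rho > 0
        np.testing.assert_allclose(
            stochastic_traj.per_capita[alive],
            stochastic_traj.K[alive] / stochastic_traj.rho[alive],
        )

    def test_seed_determinism(self):
        params = standard_parameters(n_steps=5_000, seed=42)
        a, b = simulate(params), simulate(params)
        np.testing.assert_array_equal(a.rho, b.rho)
        np.testing.assert_array_equal(a.c, b.c)
        np.testing.assert_array_equal(a.K, b.K)
        np.testing.assert_array_equal(a.xi, b.xi)

    def test_noise_off_is_seed_independent(self):
        a = simulate(standard_parameters(sigma=0.0, n_steps=2_000, seed=1))
        b = simulate(standard_parameters(sigma=0.0, n_steps=2_000, seed=999))
        np.testing.assert_array_equal(a.rho, b.rho)
        np.testing.assert_array_equal(a.c, b.c)
        np.testing.assert_array_equal(a.K, b.K)

    def test_no_culture_per_capita_approaches_one(self, no_culture_traj):
        assert abs(no_culture_traj.per_capita[-1] - 1.0) < 1e-6
        assert no_culture_traj.warnings == 0

    def test_monotone_culture_decay_without_innovation(self, no_culture_traj):
        c = no_culture_traj.c
        assert np.all(np.diff(c) < 0)
        assert c[-1] < 1e-10

    def test_positivity_of_density_and_culture(self, stochastic_traj):
        assert np.all(stochastic_traj.rho >= 0.0)
        assert np.all(stochastic_traj.c >= 0.0)
        assert stochastic_traj.warnings == 0

    def test_runaway_growth_without_loss_or_depletion(self):
        # mu = 0 and lam = 0: innovations accumulate without bound and the
        # population grows at an accelerating pace
        params = standard_parameters(mu=0.0, lam=0.0, n_steps=50_000, seed=2)
        traj = simulate(params)
        third = len(traj.c) // 3
        assert traj.c[-1] > 10 * traj.c[2 * third] > 100 * traj.c[third]
        assert traj.rho[-1] > 10 * traj.rho[third]
        assert np.all(np.diff(traj.c) >= 0)  # no loss: culture never shrinks

    def test_slow_recovery_collapse(self):
        params = standard_parameters(eta=1e-5, n_steps=100_000, seed=3)
        traj = simulate(params)
        peak_idx = int(traj.rho.argmax())
        peak = traj.rho[peak_idx]
        assert peak_idx < 0.1 * params.n_steps  # single early boom
        # after the bust the population never rebounds
        bust = peak_idx + int(np.argmax(traj.rho[peak_idx:] < 0.1 * peak))
        assert traj.rho[bust:].max() < 0.1 * peak

    def test_exhausted_steps_counted_in_depleted_regime(self):
        # strong grazing drives K(1+c) below zero during booms; the guard
        # replaces growth by intrinsic decline and counts the steps
        params = standard_parameters(mu=0.01, n_steps=200_000, seed=0)
        traj = simulate(params)
        assert traj.exhausted_steps > 0
        assert np.all(np.isfinite(traj.rho))
        assert traj.rho[-1] > 0.0

    @settings(deadline=None, max_examples=20)
    @given(
        lam=st.floats(0.0, 0.1),
        mu=st.floats(0.0, 0.01),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_positivity_property(self, lam, mu, seed):
        params = standard_parameters(lam=lam, mu=mu, n_steps=2_000, seed=seed)
        traj = simulate(params)
        assert np.all(traj.rho >= 0.0)
        assert np.all(traj.c >= 0.0)


class TestFixedPoint:
    def test_standard_rates(self):
        params = standard_parameters(sigma=0.0)
        rho_star, K_star, c_star = equilibrium_fixed_point(params)
        assert rho_star == pytest.approx(1.0 / 1.01)
        assert K_star == rho_star
        assert c_star == 0.0

    def test_no_depletion_reaches_baseline(self):
        params = standard_parameters(sigma=0.0, mu=0.0, K0_star=2.0)
        rho_star, _, _ = equilibrium_fixed_point(params)
        assert rho_star == 2.0

    def test_strong_depletion_limit(self):
        params = standard_parameters(sigma=0.0, mu=10.0, eta=1e-4)
        rho_star, _, _ = equilibrium_fixed_point(params)
        assert rho_star < 1e-4

    def test_requires_deterministic_model(self):
        with pytest.raises(ParameterError):
            equilibrium_fixed_point(standard_parameters(sigma=1e-8))

    def test_simulation_attracted_to_fixed_point(self, no_culture_traj):
        rho_star, K_star, _ = equilibrium_fixed_point(
            no_culture_traj.params
        )
        assert abs(no_culture_traj.rho[-1] - rho_star) < 1e-4
        assert abs(no_culture_traj.K[-1] - K_star) < 1e-4


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"lam": -0.1},
            {"kappa": 1.0},
            {"dt": 0.0},
            {"n_steps": 0},
            {"rho0": -1.0},
            {"K_init": 0.0},
            {"weibull_shape": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ModelParameters(**kwargs)

    def test_derived_defaults(self):
        params = ModelParameters(K0_star=2.0)
        assert params.rho0 == pytest.approx(0.02)
        assert params.K_init == 2.0
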
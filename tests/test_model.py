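"""Core model: repression kinetics, integration, fixed point, stability."""

import math
from dataclasses import replace

import numpy as np
import pytest

from hes7clock import (
    WILD_TYPE,
    ClockParameters,
    DelayBudget,
    InvalidInputError,
    InvalidParameterError,
    critical_delay,
    integrate,
    repression,
    steady_state,
)


def make_params(**overrides):
    """Simple valid parameter set for unit tests (delay-free by default)."""
    defaults = dict(
        mrna_synthesis_max=1.0,
        mrna_degradation=1.0,
        protein_synthesis=1.0,
        protein_degradation=1.0,
        repression_threshold=1.0,
        hill_coefficient=1.0,
        delay=DelayBudget(0.0, 0.0, 0.0),
    )
    defaults.update(overrides)
    return ClockParameters(**defaults)


class TestRepression:
    def test_no_repressor_gives_full_activity(self):
        assert repression(0.0, 1.0, 2.0) == 1.0

    @pytest.mark.parametrize("n", [1.0, 2.0, 4.0])
    def test_half_maximal_at_threshold(self, n):
        assert repression(3.7, 3.7, n) == pytest.approx(0.5, rel=1e-15)

    def test_strong_repression_value(self):
        # P = 10 P0 at n = 2: 1/(1 + 100)
        assert repression(10.0, 1.0, 2.0) == pytest.approx(1.0 / 101.0, rel=1e-12)

    def test_monotone_non_increasing_in_protein(self):
        levels = np.linspace(0.0, 10.0, 50)
        vals = [repression(p, 1.0, 3.0) for p in levels]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            repression(-0.1, 1.0, 2.0)
        with pytest.raises(InvalidParameterError):
            repression(1.0, 0.0, 2.0)
        with pytest.raises(InvalidParameterError):
            repression(1.0, 1.0, 0.5)


class TestIntegrate:
    def test_decay_only_matches_closed_form(self):
        # transcription off: M(t) = M0 exp(-mu_m t)
        mu = 0.2
        params = make_params(mrna_synthesis_max=0.0, mrna_degradation=mu)
        t_star = 3.0 / mu
        traj = integrate(params, t_end=t_star + 1.0, dt=0.01, history=(2.0, 0.0))
        i = int(round(t_star / 0.01))
        expected = 2.0 * math.exp(-mu * t_star)
        assert traj.mrna[i] == pytest.approx(expected, rel=1e-3)
        # RK4 at this step size is far inside the 0.1% band
        assert traj.mrna[i] == pytest.approx(expected, rel=1e-8)

    def test_delay_free_weak_cooperativity_converges_to_fixed_point(self):
        params = make_params()
        m_star, p_star = steady_state(params)
        rng = np.random.default_rng(42)
        for _ in range(10):
            hist = tuple(rng.uniform(0.0, 3.0, size=2))
            traj = integrate(params, t_end=40.0, dt=0.01, history=hist)
            assert traj.mrna[-1] == pytest.approx(m_star, abs=1e-4)
            assert traj.protein[-1] == pytest.approx(p_star, abs=1e-4)

    def test_fixed_point_history_stays_at_fixed_point(self):
        params = WILD_TYPE
        m_star, p_star = steady_state(params)
        traj = integrate(params, t_end=100.0, dt=0.05, history=(m_star, p_star))
        assert np.max(np.abs(traj.mrna - m_star)) < 1e-6
        assert np.max(np.abs(traj.protein - p_star)) < 1e-6

    def test_non_negative_from_non_negative_history(self):
        traj = integrate(WILD_TYPE, t_end=1200.0, dt=0.05, history=(0.0, 0.0))
        assert traj.mrna.min() >= 0.0
        assert traj.protein.min() >= 0.0

    def test_dt_too_large_for_delay_is_refused(self):
        with pytest.raises(InvalidParameterError, match="dt"):
            integrate(WILD_TYPE, t_end=1200.0, dt=WILD_TYPE.delay.total_min / 2)

    def test_negative_history_is_refused(self):
        with pytest.raises(InvalidInputError):
            integrate(WILD_TYPE, t_end=1200.0, dt=0.05, history=(-1.0, 0.0))

    def test_horizon_must_exceed_delay(self):
        with pytest.raises(InvalidParameterError):
            integrate(WILD_TYPE, t_end=WILD_TYPE.delay.total_min / 2, dt=0.05)

    def test_trajectory_grid_and_fingerprint(self):
        traj = integrate(WILD_TYPE, t_end=60.0, dt=0.05)
        steps = np.diff(traj.times)
        assert np.allclose(steps, 0.05)
        assert traj.params_fingerprint == WILD_TYPE.fingerprint()


class TestSteadyState:
    def test_quadratic_closed_form(self):
        # n = 1, all rates 1: P(1+P) = 1 so P* = (sqrt(5)-1)/2
        params = make_params()
        m_star, p_star = steady_state(params)
        golden = (math.sqrt(5.0) - 1.0) / 2.0
        assert p_star == pytest.approx(golden, rel=1e-12)
        assert m_star == pytest.approx(golden, rel=1e-12)

    def test_residuals_are_negligible(self):
        for params in (WILD_TYPE, make_params(hill_coefficient=4.0)):
            m_star, p_star = steady_state(params)
            r1 = (params.mrna_synthesis_max
                  * repression(p_star, params.repression_threshold,
                               params.hill_coefficient)
                  - params.mrna_degradation * m_star)
            r2 = params.protein_synthesis * m_star - params.protein_degradation * p_star
            scale = max(abs(m_star), abs(p_star), 1e-30)
            assert abs(r1) / scale < 1e-10
            assert abs(r2) / scale < 1e-10

    def test_monotone_in_mrna_synthesis(self):
        prev = (0.0, 0.0)
        for c in (0.5, 1.0, 2.0, 4.0):
            cur = steady_state(make_params(mrna_synthesis_max=c))
            assert cur[0] > prev[0] and cur[1] > prev[1]
            prev = cur

    def test_zero_translation_limit(self):
        params = make_params(mrna_synthesis_max=0.7, protein_synthesis=0.0,
                             mrna_degradation=0.35)
        m_star, p_star = steady_state(params)
        assert p_star == 0.0
        assert m_star == pytest.approx(2.0, rel=1e-12)


class TestCriticalDelay:
    def test_weak_gain_has_no_finite_threshold(self):
        # K < mu_m mu_p: fixed point stable for every delay
        params = make_params(mrna_synthesis_max=0.01, hill_coefficient=1.0)
        assert critical_delay(params) == math.inf

    def test_crossing_condition_is_satisfied(self):
        params = WILD_TYPE
        tau_c = critical_delay(params)
        assert 0.0 < tau_c < params.delay.total_min  # wild type oscillates
        # check the characteristic equation at lambda = i omega directly
        mu_m, mu_p = params.mrna_degradation, params.protein_degradation
        _, p_star = steady_state(params)
        p0, n = params.repression_threshold, params.hill_coefficient
        u = (p_star / p0) ** n
        K = (params.mrna_synthesis_max * params.protein_synthesis
             * (n / p0) * (p_star / p0) ** (n - 1.0) / (1.0 + u) ** 2)
        # |(-i w + mu_m)(i w + mu_p)| = K at the crossing frequency
        omega_sq = 0.5 * (-(mu_m**2 + mu_p**2)
                          + math.sqrt((mu_m**2 - mu_p**2) ** 2 + 4 * K**2))
        omega = math.sqrt(omega_sq)
        lhs = complex(mu_m, omega) * complex(mu_p, omega)
        rhs = -K * complex(math.cos(-omega * tau_c), math.sin(-omega * tau_c))
        assert abs(lhs - rhs) / abs(lhs) < 1e-9

    def test_stronger_repression_never_raises_threshold(self):
        # sweep the gain upward through the synthesis rate
        taus = []
        for c in (1.2, 1.6, 2.4, 4.0, 8.0):
            params = make_params(mrna_synthesis_max=c, hill_coefficient=2.0)
            taus.append(critical_delay(params))
        assert all(a >= b for a, b in zip(taus, taus[1:]))

    def test_symmetric_decays_crossing_frequency(self):
        # mu_m = mu_p = mu: omega^2 = K - mu^2 from the magnitude condition
        params = make_params(mrna_synthesis_max=6.0, mrna_degradation=0.5,
                             protein_degradation=0.5, hill_coefficient=3.0)
        tau_c = critical_delay(params)
        assert math.isfinite(tau_c)
        mu = 0.5
        _, p_star = steady_state(params)
        u = p_star ** params.hill_coefficient
        K = (params.mrna_synthesis_max * params.hill_coefficient
             * p_star ** (params.hill_coefficient - 1.0) / (1.0 + u) ** 2)
        omega = math.sqrt(K - mu * mu)
        expected = (math.pi - 2.0 * math.atan2(omega, mu)) / omega
        assert tau_c == pytest.approx(expected, rel=1e-9)
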
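import numpy as np
import pytest
from scipy import integrate

from decoychoice.race import (
    DualRouteParams,
    FFIParams,
    SimSettings,
    choice_probability,
    choice_rt_likelihood,
    drift_rates,
    dual_route_drifts,
    dual_route_likelihood,
    fpt_cdf,
    fpt_density,
    mean_rt,
    simulate_paths,
    simulate_race,
)

GRID = SimSettings(dt=0.001, tmax=50.0, npaths=1)


class TestDrifts:
    def test_equal_utilities_give_equal_drifts(self):
        p = FFIParams(k=3.0, theta=1.0, c=0.7, I0=0.2)
        mu = drift_rates([0.6, 0.6, 0.6], p)
        assert np.allclose(mu, 3.0 * 0.6 * (1 - 0.7) + 0.2)

    def test_hand_substitution(self):
        p = FFIParams(k=2.0, theta=1.0, c=1.0, I0=0.1)
        assert np.allclose(drift_rates([1.0, 0.5], p), [1.1, -0.9])

    def test_zero_inhibition_is_pure_race(self):
        p = FFIParams(k=2.0, theta=1.0, c=0.0, I0=0.1)
        assert np.allclose(drift_rates([1.0, 0.5], p), [2.1, 1.1])

    def test_single_alternative_raises(self):
        with pytest.raises(ValueError):
            drift_rates([1.0], FFIParams(k=1, theta=1))


class TestFirstPassage:
    def test_density_closed_form_value(self):
        assert fpt_density(1.0, 1.0, 1.0) == pytest.approx(1 / np.sqrt(2 * np.pi))

    def test_density_zero_outside_support(self):
        assert fpt_density(0.0, 1.0, 1.0) == 0.0
        assert fpt_density(-0.5, 1.0, 1.0) == 0.0

    def test_density_integrates_to_one_for_positive_drift(self):
        t = np.arange(0.0005, 60, 0.0005)
        for mu, theta in [(0.8, 1.0), (2.0, 0.5), (1.5, 2.0)]:
            mass = np.trapezoid(fpt_density(t, mu, theta), t)
            assert mass == pytest.approx(1.0, abs=1e-4)

    def test_cdf_boundary_values(self):
        assert fpt_cdf(0.0, 1.0, 1.0) == 0.0
        assert fpt_cdf(1e4, 1.0, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_cdf_hand_value(self):
        # 0.5 + e^2 * Phi(-2)
        from scipy.stats import norm

        expected = norm.cdf(0.0) + np.exp(2.0) * norm.cdf(-2.0)
        assert fpt_cdf(1.0, 1.0, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.6681, abs=1e-4)

    def test_cdf_is_integral_of_density(self):
        t = np.arange(0.0005, 5, 0.0005)
        dens = fpt_density(t, 1.2, 0.9)
        cdf_num = integrate.cumulative_trapezoid(dens, t, initial=0)
        assert np.max(np.abs(cdf_num - (fpt_cdf(t, 1.2, 0.9) - fpt_cdf(t[0], 1.2, 0.9)))) < 1e-6

    def test_cdf_stable_at_large_drift_times_bound(self):
        val = fpt_cdf(10.0, 50.0, 20.0)
        assert 0.0 <= val <= 1.0
        assert np.isfinite(val)


class TestChoiceLikelihood:
    def test_symmetry_under_equal_utilities(self):
        p = FFIParams(k=3.0, theta=1.0, c=0.5, I0=0.5, tnd=0.2)
        for rt in (0.5, 0.8, 1.3):
            l1 = choice_rt_likelihood(0, rt, [0.5, 0.5], p)
            l2 = choice_rt_likelihood(1, rt, [0.5, 0.5], p)
            assert l1 == pytest.approx(l2)
            assert l1 > 0

    def test_integral_equals_choice_probability(self):
        p = FFIParams(k=3.0, theta=1.0, c=0.6, I0=0.8, tnd=0.0)
        u = [0.7, 0.4, 0.55]
        t = np.arange(0.001, 50, 0.001)
        probs = choice_probability(u, p, GRID)
        sub = t[::20]
        for i in range(3):
            li = np.array([choice_rt_likelihood(i, ti, u, p) for ti in sub])
            mass = np.trapezoid(li, sub)
            assert mass == pytest.approx(probs[i], abs=2e-3)

    def test_rt_before_nondecision_time_floors_to_zero(self):
        p = FFIParams(k=3.0, theta=1.0, tnd=0.4)
        with pytest.warns(UserWarning, match="tnd"):
            assert choice_rt_likelihood(0, 0.3, [0.5, 0.4], p) == 0.0

    def test_probabilities_sum_to_one_and_monotone_in_utility(self):
        p = FFIParams(k=4.0, theta=1.0, c=0.5, I0=1.0)
        last = 0.0
        for u_h in (0.4, 0.55, 0.7):
            probs = choice_probability([u_h, 0.4], p, GRID)
            assert probs.sum() == pytest.approx(1.0, abs=1e-3)
            assert probs[0] > last
            last = probs[0]


class TestMeanRT:
    def test_symmetric_alternatives_have_equal_conditional_rts(self):
        p = FFIParams(k=3.0, theta=1.0, c=0.5, I0=1.0, tnd=0.3)
        assert mean_rt([0.5, 0.5], p, 0, GRID) == pytest.approx(
            mean_rt([0.5, 0.5], p, 1, GRID)
        )

    def test_mean_rt_increases_with_bound(self):
        rts = [
            mean_rt([0.7, 0.4], FFIParams(k=3.0, theta=th, c=0.5, I0=1.0), 0, GRID)
            for th in (0.5, 1.0, 1.5)
        ]
        assert rts[0] < rts[1] < rts[2]

    def test_hopeless_competitor_recovers_inverse_gaussian_mean(self):
        # competitor with hugely negative drift: E[t] -> theta / mu_winner
        p = FFIParams(k=1.0, theta=1.2, c=0.0, I0=0.0, tnd=0.25)
        got = mean_rt([2.0, -50.0], p, 0, GRID)
        assert got == pytest.approx(1.2 / 2.0 + 0.25, rel=1e-3)


class TestDualRoute:
    def test_equal_utilities_zero_inhibition_symmetric(self):
        p = DualRouteParams(k=3.0, theta=1.0, fMI=0.0, I0=0.5, tnd=0.0)
        for rt in (0.4, 0.9):
            assert dual_route_likelihood(0, rt, [0.5, 0.5], p) == pytest.approx(
                dual_route_likelihood(1, rt, [0.5, 0.5], p)
            )

    def test_total_mass_binary_and_ternary(self):
        p = DualRouteParams(k=4.0, theta=1.0, fMI=0.5, I0=1.0, tnd=0.0)
        for u in ([0.6, 0.3], [0.6, 0.3, 0.45]):
            probs = choice_probability(u, p, GRID)
            assert probs.sum() == pytest.approx(1.0, abs=1e-3)

    def test_dn_route_scale_invariant_vanilla_route_not(self):
        p = DualRouteParams(k=4.0, theta=1.0, fMI=0.5, I0=0.2)
        u = np.array([0.6, 0.3, 0.45])
        mu_v1, mu_dn1 = dual_route_drifts(u, p)
        mu_v2, mu_dn2 = dual_route_drifts(10 * u, p)
        assert np.allclose(mu_dn1, mu_dn2)
        assert not np.allclose(mu_v1, mu_v2)


class TestSimulator:
    def test_same_seed_identical_output(self):
        p = FFIParams(k=3.0, theta=1.0, c=0.5, I0=1.0, tnd=0.3)
        s = SimSettings(dt=0.005, tmax=10, npaths=2000, seed=9)
        c1, r1 = simulate_race([0.6, 0.4], p, s)
        c2, r2 = simulate_race([0.6, 0.4], p, s)
        assert np.array_equal(c1, c2)
        assert np.array_equal(r1, r2, equal_nan=True)

    def test_equal_utilities_near_half_split(self):
        p = FFIParams(k=3.0, theta=1.0, c=0.5, I0=1.0)
        s = SimSettings(dt=0.005, tmax=20, npaths=20000, seed=2)
        choices, _ = simulate_race([0.5, 0.5], p, s)
        freq = (choices == 0).mean()
        se = np.sqrt(0.25 / len(choices))
        assert abs(freq - 0.5) < 3 * se + (choices < 0).mean()

    def test_matches_independent_stepwise_simulator(self):
        """Cross-check against a plain per-step two-accumulator loop."""
        p = FFIParams(k=3.0, theta=1.0, c=1.0, I0=1.0)
        mu = drift_rates(np.array([0.7, 0.4]), p)
        dt, n = 0.002, 4000
        rng = np.random.default_rng(11)
        wins = []
        for _ in range(n):
            x = np.zeros(2)
            for _step in range(int(10 / dt)):
                x += mu * dt + np.sqrt(dt) * rng.normal(size=2)
                if (x >= p.theta).any():
                    wins.append(int(np.argmax(x)))
                    break
        f_oracle = np.mean(np.array(wins) == 0)
        rng2 = np.random.default_rng(12)
        winner, _ = simulate_paths(np.tile(mu, (20000, 1)), p.theta, dt, 10, rng2,
                                   bridge=False)
        f_pkg = (winner == 0).mean()
        se = np.sqrt(f_oracle * (1 - f_oracle) * (1 / n + 1 / 20000))
        assert abs(f_pkg - f_oracle) < 4 * se

    def test_censored_paths_reported(self):
        p = FFIParams(k=1.0, theta=5.0, c=0.0, I0=0.0)
        s = SimSettings(dt=0.01, tmax=0.5, npaths=500, seed=3)
        choices, rts = simulate_race([0.1, 0.1], p, s)
        assert (choices == -1).any()
        assert np.isnan(rts[choices == -1]).all()
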
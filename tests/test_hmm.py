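import numpy as np
import pytest

from ruttrack.hmm import (
    StepAngleSeries,
    emission_logprobs,
    fit_hmm,
    forward_loglik,
    make_series,
    stationary_distribution,
    viterbi_decode,
)
from ruttrack.regularize import interpolate_hourly
from ruttrack.synthetic import simulate_hmm_series

from conftest import make_track
from oracles import exhaustive_loglik, exhaustive_viterbi, turning_angles

TRUE = dict(
    mu=np.array([50.0, 300.0]),
    sigma=np.array([25.0, 150.0]),
    zero_mass=np.array([0.05, 0.01]),
    angle_mean=np.array([0.0, 0.1]),
    kappa=np.array([0.5, 2.0]),
    tpm=np.array([[0.9, 0.1], [0.1, 0.9]]),
)


def _fit_like(params):
    """HMMFit-shaped object from raw parameters (for likelihood/decoding)."""
    from ruttrack.hmm import HMMFit

    return HMMFit(
        n_states=len(params["mu"]),
        mu=params["mu"],
        sigma=params["sigma"],
        zero_mass=params["zero_mass"],
        angle_mean=params["angle_mean"],
        kappa=params["kappa"],
        tpm=params["tpm"],
        stationary=stationary_distribution(params["tpm"]),
        log_likelihood=np.nan,
        converged=True,
    )


class TestMakeSeries:
    def _reg(self, xy):
        return interpolate_hourly(make_track(xy), delta=0.0)

    def test_collinear_equal_spacing(self):
        reg = self._reg([[0, 0], [10, 0], [20, 0], [30, 0]])
        s = make_series(reg)
        np.testing.assert_allclose(s.steps, 10.0)
        assert np.isnan(s.angles[0])
        np.testing.assert_allclose(s.angles[1:], 0.0, atol=1e-12)

    def test_left_turn_is_positive(self):
        reg = self._reg([[0, 0], [10, 0], [10, 10]])
        s = make_series(reg)
        assert s.angles[1] == pytest.approx(np.pi / 2)

    def test_zero_step_blanks_adjacent_angles(self):
        reg = self._reg([[0, 0], [10, 0], [10, 0], [20, 0]])
        s = make_series(reg)
        assert s.steps[1] == 0.0
        assert np.isnan(s.angles[1]) and np.isnan(s.angles[2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_trigonometry_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.normal(0, 50, (10, 2)), axis=0)
        s = make_series(self._reg(xy))
        expected = turning_angles(xy)
        np.testing.assert_allclose(
            np.hypot(*np.diff(xy, axis=0).T), s.steps, atol=1e-9
        )
        np.testing.assert_allclose(s.angles, expected, atol=1e-9, equal_nan=True)

    def test_too_short(self):
        with pytest.raises(ValueError):
            make_series(self._reg([[0, 0], [1, 1]]))


class TestForwardAlgorithm:
    @pytest.mark.parametrize("seed", range(3))
    def test_equals_exhaustive_path_sum(self, seed):
        """Scaled forward log-likelihood equals the brute-force sum over all
        2^6 state paths, zero steps and missing angles included."""
        series, _ = simulate_hmm_series(**TRUE, n_steps=6, seed=seed)
        series.steps[2] = 0.0
        series.angles[3] = np.nan
        fit = _fit_like(TRUE)
        got = forward_loglik(fit, series)
        expected = exhaustive_loglik(
            series.steps, series.angles, TRUE["mu"], TRUE["sigma"],
            TRUE["zero_mass"], TRUE["angle_mean"], TRUE["kappa"], TRUE["tpm"],
            stationary_distribution(TRUE["tpm"]),
        )
        assert got == pytest.approx(expected, abs=1e-8)

    def test_invariant_under_state_relabeling(self):
        series, _ = simulate_hmm_series(**TRUE, n_steps=50, seed=9)
        fit = _fit_like(TRUE)
        perm = {k: v[::-1] if k != "tpm" else v[::-1, ::-1]
                for k, v in TRUE.items()}
        assert forward_loglik(_fit_like(perm), series) == pytest.approx(
            forward_loglik(fit, series)
        )

    def test_emissions_integrate_to_one(self):
        """Zero-inflated gamma over {0} u (0, inf) and von Mises over
        (-pi, pi] are proper distributions (numerical check)."""
        from scipy.integrate import quad

        mu, sigma, zm, am, kap = 120.0, 80.0, 0.07, 0.3, 1.5
        series = StepAngleSeries("q", np.array([1.0]), np.array([np.nan]))

        def step_density(x):
            series.steps[0] = x
            return np.exp(emission_logprobs(
                series, np.array([mu]), np.array([sigma]), np.array([zm]),
                np.array([am]), np.array([kap]))[0, 0])

        cont, _ = quad(step_density, 1e-9, np.inf, limit=200)
        assert cont + zm == pytest.approx(1.0, abs=1e-6)

        series.steps[0] = 0.0
        assert step_density(0.0) == pytest.approx(zm, rel=1e-9)

        def angle_density(a):
            s = StepAngleSeries("q", np.array([50.0]), np.array([a]))
            logb = emission_logprobs(
                s, np.array([mu]), np.array([sigma]), np.array([zm]),
                np.array([am]), np.array([kap]))
            return np.exp(logb[0, 0]) / step_density_at_50
        step_density_at_50 = step_density(50.0)
        series.steps[0] = 50.0
        ang, _ = quad(angle_density, -np.pi, np.pi)
        assert ang == pytest.approx(1.0, abs=1e-8)


class TestStationary:
    def test_fixed_point(self):
        delta = stationary_distribution(TRUE["tpm"])
        np.testing.assert_allclose(delta @ TRUE["tpm"], delta, atol=1e-10)
        assert delta.sum() == pytest.approx(1.0)

    def test_asymmetric_matrix(self):
        tpm = np.array([[0.95, 0.05], [0.4, 0.6]])
        delta = stationary_distribution(tpm)
        np.testing.assert_allclose(delta, [8 / 9, 1 / 9], atol=1e-10)


class TestViterbi:
    @pytest.mark.parametrize("seed", range(3))
    def test_equals_exhaustive_argmax(self, seed):
        """Viterbi path equals the brute-force argmax over all 2^8 paths."""
        series, _ = simulate_hmm_series(**TRUE, n_steps=8, seed=100 + seed)
        fit = _fit_like(TRUE)
        got = viterbi_decode(fit, series).states[:-1] - 1
        expected = exhaustive_viterbi(
            series.steps, series.angles, TRUE["mu"], TRUE["sigma"],
            TRUE["zero_mass"], TRUE["angle_mean"], TRUE["kappa"], TRUE["tpm"],
            stationary_distribution(TRUE["tpm"]),
        )
        np.testing.assert_array_equal(got, expected)

    def test_tie_breaks_to_lower_state(self):
        """Identical emission parameters and a symmetric transition matrix
        leave every path equally likely: the decoder returns state 1."""
        params = dict(
            mu=np.array([100.0, 100.0]),
            sigma=np.array([50.0, 50.0]),
            zero_mass=np.array([0.01, 0.01]),
            angle_mean=np.array([0.0, 0.0]),
            kappa=np.array([1.0, 1.0]),
            tpm=np.array([[0.5, 0.5], [0.5, 0.5]]),
        )
        series, _ = simulate_hmm_series(**params, n_steps=20, seed=0)
        states = viterbi_decode(_fit_like(params), series).states
        assert (states == 1).all()

    def test_decoding_accuracy_on_separated_states(self):
        series, states = simulate_hmm_series(**TRUE, n_steps=2000, seed=4)
        decoded = viterbi_decode(_fit_like(TRUE), series).states[:-1]
        assert (decoded == states).mean() >= 0.9


class TestFitHMM:
    def test_recovery_and_optimization_contract(self):
        """2-state fit at 2,000 steps recovers the generating parameters and
        the chosen optimum dominates every restart; restarting from the truth
        cannot beat the multi-start result."""
        series, _ = simulate_hmm_series(**TRUE, n_steps=2000, seed=7)
        fit = fit_hmm(series, 2, n_restarts=6, seed=0)
        assert fit.converged
        for name, tol in (("mu", 0.15), ("sigma", 0.15), ("kappa", 0.3)):
            # kappa has much higher single-realization sampling noise than the
            # step moments; the multi-seed average is checked elsewhere
            got, true = getattr(fit, name), TRUE[name]
            assert np.all(np.abs(got - true) / true < tol), (name, got)
        assert np.abs(fit.tpm - TRUE["tpm"]).max() < 0.05
        assert fit.log_likelihood >= max(fit.restart_logliks) - 1e-6
        warm = fit_hmm(series, 2, n_restarts=0, seed=0,
                       x0=(TRUE["mu"], TRUE["sigma"], TRUE["zero_mass"],
                           TRUE["angle_mean"], TRUE["kappa"], TRUE["tpm"]))
        assert fit.log_likelihood >= warm.log_likelihood - 1e-3

    def test_canonical_state_order(self):
        series, _ = simulate_hmm_series(**TRUE, n_steps=800, seed=8)
        fit = fit_hmm(series, 2, n_restarts=4, seed=1)
        assert fit.mu[0] < fit.mu[1]
        np.testing.assert_allclose(fit.tpm.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(fit.stationary @ fit.tpm, fit.stationary,
                                   atol=1e-10)

    def test_joint_fit_pools_series(self):
        parts = [simulate_hmm_series(**TRUE, n_steps=700, seed=s)[0]
                 for s in (20, 21, 22)]
        fit = fit_hmm(parts, 2, n_restarts=4, seed=2)
        assert np.all(np.abs(fit.mu - TRUE["mu"]) / TRUE["mu"] < 0.15)

    def test_small_sample_warns(self):
        series, _ = simulate_hmm_series(**TRUE, n_steps=30, seed=3)
        with pytest.warns(UserWarning, match="pooled steps"):
            fit_hmm(series, 2, n_restarts=2, seed=0)

    def test_bad_state_count(self):
        series, _ = simulate_hmm_series(**TRUE, n_steps=100, seed=3)
        with pytest.raises(ValueError):
            fit_hmm(series, 5)
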
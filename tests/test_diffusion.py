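import numpy as np
import pytest

from meddiffusion.diffusion import (
    mu_theta_from_eps,
    p_sample_loop,
    p_sample_step,
    predicted_x0_from_eps,
    q_posterior,
    q_sample,
    q_sample_stepwise,
)
from meddiffusion.schedules import posterior_coefficients

from conftest import FixedEpsilonPredictor, OracleEpsilonPredictor, ZeroPredictor


class TestQSample:
    def test_zero_noise(self, toy_schedule):
        x0 = np.full((4, 4), 0.5)
        xt = q_sample(x0, 3, np.zeros_like(x0), toy_schedule)
        np.testing.assert_allclose(xt, np.sqrt(toy_schedule.alpha_bar(3)) * x0)

    def test_zero_signal(self, toy_schedule):
        eps = np.arange(16.0).reshape(4, 4)
        xt = q_sample(np.zeros((4, 4)), 5, eps, toy_schedule)
        np.testing.assert_allclose(xt, np.sqrt(1 - toy_schedule.alpha_bar(5)) * eps)

    def test_shape_mismatch(self, toy_schedule):
        with pytest.raises(ValueError):
            q_sample(np.zeros((4, 4)), 1, np.zeros((4, 5)), toy_schedule)

    def test_monte_carlo_marginal(self, small_schedule):
        # 1e5 iid draws (as pixels); mean -> sqrt(ab) x0, var -> 1 - ab, 3 SE
        rng = np.random.default_rng(42)
        n = 100_000
        x0 = np.full((250, 400), 0.6)
        t = 120
        xt = q_sample(x0, t, rng.standard_normal(x0.shape), small_schedule)
        ab = small_schedule.alpha_bar(t)
        sd = np.sqrt(1 - ab)
        se_mean = sd / np.sqrt(n)
        assert abs(xt.mean() - np.sqrt(ab) * 0.6) < 3 * se_mean
        se_var = (1 - ab) * np.sqrt(2.0 / (n - 1))
        assert abs(xt.var() - (1 - ab)) < 3 * se_var

    def test_per_example_timesteps(self, toy_schedule):
        x0 = np.stack([np.full((4, 4), 0.5), np.full((4, 4), -0.5)])
        eps = np.zeros_like(x0)
        xt = q_sample(x0, np.array([1, 7]), eps, toy_schedule)
        np.testing.assert_allclose(xt[0], np.sqrt(toy_schedule.alpha_bar(1)) * 0.5)
        np.testing.assert_allclose(xt[1], -np.sqrt(toy_schedule.alpha_bar(7)) * 0.5)


class TestQSampleStepwise:
    def test_t1_matches_closed_form_formula(self, toy_schedule):
        # at t=1 both paths are the same affine map of one draw
        x0 = np.full((2, 2), 0.3)
        out = q_sample_stepwise(x0, 1, toy_schedule, rng_seed=0)
        eps = np.random.default_rng(0).standard_normal(x0.shape)
        expect = np.sqrt(1 - toy_schedule.beta(1)) * x0 + np.sqrt(toy_schedule.beta(1)) * eps
        np.testing.assert_allclose(out, expect, rtol=1e-12)

    def test_stepwise_matches_marginal_distribution(self, toy_schedule):
        # each pixel is an independent chain: 1e5 chains at t=5
        x0 = np.full((250, 400), 0.8)
        t = 5
        out = q_sample_stepwise(x0, t, toy_schedule, rng_seed=7)
        ab = toy_schedule.alpha_bar(t)
        n = x0.size
        se_mean = np.sqrt(1 - ab) / np.sqrt(n)
        assert abs(out.mean() - np.sqrt(ab) * 0.8) < 3 * se_mean
        se_var = (1 - ab) * np.sqrt(2.0 / (n - 1))
        assert abs(out.var() - (1 - ab)) < 3 * se_var

    def test_zero_signal_marginal(self, toy_schedule):
        out = q_sample_stepwise(np.zeros((250, 400)), 8, toy_schedule, rng_seed=3)
        ab = toy_schedule.alpha_bar(8)
        n = out.size
        assert abs(out.mean()) < 3 * np.sqrt((1 - ab) / n)
        assert abs(out.var() - (1 - ab)) < 3 * (1 - ab) * np.sqrt(2.0 / (n - 1))

    def test_range_error(self, toy_schedule):
        with pytest.raises(IndexError):
            q_sample_stepwise(np.zeros((2, 2)), 11, toy_schedule, rng_seed=0)


class TestQPosterior:
    def test_constant_image_linearity(self, toy_schedule):
        c = 0.4
        img = np.full((3, 3), c)
        mean, _ = q_posterior(img, img, 4, toy_schedule)
        cx0, cxt1, _ = posterior_coefficients(toy_schedule, 4)
        np.testing.assert_allclose(mean, c * (cx0 + cxt1), rtol=1e-12)

    def test_var_matches_schedule_bitwise(self, toy_schedule):
        for t in range(0, toy_schedule.T - 1):
            _, var = q_posterior(np.zeros((2, 2)), np.zeros((2, 2)), t, toy_schedule)
            assert var == posterior_coefficients(toy_schedule, t)[2]

    def test_against_grid_bayes_oracle(self, toy_schedule):
        # brute-force Bayes: q(x_t | x_{t+1}, x0) ∝ q(x_{t+1}|x_t) q(x_t|x0) on a grid
        s = toy_schedule
        x0v, xt1v = 0.3, -0.2
        for t in [1, 4, 8]:
            grid = np.linspace(-8, 8, 200_001)
            ab_t = s.alpha_bar(t)
            like = np.exp(
                -0.5 * (xt1v - np.sqrt(s.alpha(t + 1)) * grid) ** 2 / s.beta(t + 1)
            )
            prior = np.exp(-0.5 * (grid - np.sqrt(ab_t) * x0v) ** 2 / (1 - ab_t))
            post = like * prior
            post /= post.sum()
            o_mean = float((grid * post).sum())
            o_var = float(((grid - o_mean) ** 2 * post).sum())
            mean, var = q_posterior(
                np.full((1, 1), x0v), np.full((1, 1), xt1v), t, s
            )
            assert mean[0, 0] == pytest.approx(o_mean, abs=1e-6)
            assert var == pytest.approx(o_var, abs=1e-6)


class TestMuTheta:
    def test_zero_eps_hat(self, toy_schedule):
        xt = np.full((2, 2), 0.5)
        mu = mu_theta_from_eps(xt, np.zeros_like(xt), 3, toy_schedule)
        np.testing.assert_allclose(mu, xt / np.sqrt(toy_schedule.alpha(3)), rtol=1e-12)

    def test_consistency_with_posterior(self, toy_schedule):
        # with the true eps, mu_theta equals the forward-posterior mean
        rng = np.random.default_rng(1)
        x0 = rng.uniform(-1, 1, (8, 8))
        for t in [1, 5, 10]:
            eps = rng.standard_normal(x0.shape)
            xt = q_sample(x0, t, eps, toy_schedule)
            mu = mu_theta_from_eps(xt, eps, t, toy_schedule)
            mean, _ = q_posterior(x0, xt, t - 1, toy_schedule)
            np.testing.assert_allclose(mu, mean, rtol=1e-6, atol=1e-9)

    def test_predicted_x0_inversion(self, toy_schedule):
        rng = np.random.default_rng(2)
        x0 = rng.uniform(-1, 1, (8, 8))
        eps = rng.standard_normal(x0.shape)
        xt = q_sample(x0, 6, eps, toy_schedule)
        np.testing.assert_allclose(
            predicted_x0_from_eps(xt, eps, 6, toy_schedule), x0, atol=1e-12
        )

    def test_shape_mismatch(self, toy_schedule):
        with pytest.raises(ValueError):
            mu_theta_from_eps(np.zeros((2, 2)), np.zeros((3, 3)), 1, toy_schedule)


class TestPSampleStep:
    def test_zero_sigma_mode(self, toy_schedule):
        s = toy_schedule.with_sigma_mode("zero")
        model = ZeroPredictor()
        xt = np.full((4, 4), 0.2)
        res = p_sample_step(xt, np.zeros_like(xt), 5, model, s, rng_seed=0)
        np.testing.assert_array_equal(res.sample, res.mean)

    def test_no_noise_at_final_step(self, toy_schedule):
        model = ZeroPredictor()
        xt = np.full((4, 4), 0.2)
        res = p_sample_step(xt, np.zeros_like(xt), 1, model, toy_schedule, rng_seed=0)
        np.testing.assert_array_equal(res.sample, res.mean)

    def test_fixed_seed_bit_identical(self, toy_schedule):
        model = ZeroPredictor()
        xt = np.full((4, 4), 0.2)
        a = p_sample_step(xt, np.zeros_like(xt), 5, model, toy_schedule, rng_seed=9)
        b = p_sample_step(xt, np.zeros_like(xt), 5, model, toy_schedule, rng_seed=9)
        np.testing.assert_array_equal(a.sample, b.sample)

    def test_model_shape_contract_error(self, toy_schedule):
        class BadModel:
            def predict(self, xt, y, t):
                return np.zeros((2, 2))

        with pytest.raises(ValueError, match="BadModel"):
            p_sample_step(np.zeros((4, 4)), np.zeros((4, 4)), 1, BadModel(), toy_schedule)

    def test_oracle_round_trip(self, small_schedule, phantom16):
        # sigma=0 reverse pass with the state-consistent cheating predictor
        s = small_schedule.with_sigma_mode("zero")
        rng = np.random.default_rng(4)
        eps = rng.standard_normal(phantom16.shape)
        x = q_sample(phantom16, s.T, eps, s)
        model = OracleEpsilonPredictor(phantom16, s)
        y = np.zeros_like(phantom16)
        for t in range(s.T, 0, -1):
            x = p_sample_step(x, y, t, model, s).sample
        assert np.abs(x - phantom16).max() < 1e-3


class TestPSampleLoop:
    def test_determinism(self, toy_schedule):
        model = FixedEpsilonPredictor(np.zeros((8, 8)))
        y = np.zeros((8, 8))
        a = p_sample_loop(y, model, toy_schedule, rng_seed=3)
        b = p_sample_loop(y, model, toy_schedule, rng_seed=3)
        np.testing.assert_array_equal(a, b)

    def test_trajectory_length(self, toy_schedule):
        model = ZeroPredictor()
        y = np.zeros((8, 8))
        _, traj = p_sample_loop(y, model, toy_schedule, rng_seed=0, keep_trajectory=True)
        assert len(traj) == toy_schedule.T + 1

    def test_final_output_clipped(self, toy_schedule):
        model = ZeroPredictor()
        out = p_sample_loop(np.zeros((8, 8)), model, toy_schedule, rng_seed=1)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_nan_abort_names_timestep(self, toy_schedule):
        class NaNModel:
            def predict(self, xt, y, t):
                out = np.zeros_like(xt)
                if int(np.atleast_1d(t)[0]) == 7:
                    out[0, 0] = np.nan
                return out

        with pytest.raises((FloatingPointError, ValueError), match="t=7|timestep"):
            p_sample_loop(np.zeros((4, 4)), NaNModel(), toy_schedule, rng_seed=0)
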
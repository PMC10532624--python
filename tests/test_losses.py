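"""Oracle and property tests for the objective terms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import expit

from medvdm import (GammaSchedule, LossWeights, antithetic_times,
                    differential_loss, diffusion_loss_continuous,
                    diffusion_loss_discrete, latent_loss, marginal_params,
                    reconstruction_loss, total_loss)


def perfect_predictor(x):
    """Test double that recovers the exact injected noise from z_t and x."""

    def predict(z_t, g_t):
        mp = marginal_params(g_t)
        a = mp.alpha.reshape(mp.alpha.shape + (1,) * (z_t.ndim - 1))
        s = mp.sigma.reshape(mp.sigma.shape + (1,) * (z_t.ndim - 1))
        return (z_t - a * x) / s

    return predict


class TestReconstruction:
    def test_maximum_entropy_pixel(self):
        assert reconstruction_loss(np.array(0.5), np.array(0.0)) == pytest.approx(
            np.log(2.0), abs=1e-12)

    def test_perfect_certainty_limit(self):
        x = np.array([1.0, 0.0])
        logits = np.array([500.0, -500.0])
        assert reconstruction_loss(x, logits) == pytest.approx(0.0, abs=1e-12)

    def test_matches_per_pixel_loop_oracle(self, rng):
        x = rng.uniform(size=(4, 4))
        logits = rng.normal(scale=2.0, size=(4, 4))
        loop = 0.0
        for i in range(4):
            for j in range(4):
                p = expit(logits[i, j])
                loop -= x[i, j] * np.log(p) + (1 - x[i, j]) * np.log(1 - p)
        assert reconstruction_loss(x, logits) == pytest.approx(loop, abs=1e-10)

    def test_out_of_range_pixels_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.array([1.5]), np.array([0.0]))

    def test_batch_averaging(self, rng):
        x = rng.uniform(size=(3, 4, 4))
        logits = rng.normal(size=(3, 4, 4))
        per = [reconstruction_loss(x[i], logits[i]) for i in range(3)]
        assert reconstruction_loss(x, logits) == pytest.approx(np.mean(per), abs=1e-12)


class TestLatent:
    def test_identical_distributions_give_zero(self):
        # alpha_1 ~ 0, sigma_1 ~ 1 at a large terminal gamma
        sch = GammaSchedule(gamma_min=0.0, gamma_max=40.0)
        assert latent_loss(np.array([2.0]), sch) == pytest.approx(0.0, abs=1e-8)

    def test_zero_signal_closed_form(self):
        # sigma_1^2 = logistic(0) = 1/2; KL per dim = (0.5 - 1 - ln 0.5) / 2
        sch = GammaSchedule(gamma_min=-1.0, gamma_max=0.0)
        expected = 0.5 * (0.5 - 1.0 - np.log(0.5))
        assert latent_loss(np.zeros(1), sch) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.09657359, abs=1e-7)

    def test_matches_numerical_kl_integration(self, schedule):
        x = 0.8
        mp = marginal_params(schedule.gamma(1.0))
        m, s = float(mp.alpha) * x, float(mp.sigma)

        def integrand(z):
            logp = -0.5 * ((z - m) / s) ** 2 - np.log(s * np.sqrt(2 * np.pi))
            logq = -0.5 * z**2 - 0.5 * np.log(2 * np.pi)
            return np.exp(logp) * (logp - logq)

        numeric, _ = quad(integrand, m - 12 * s, m + 12 * s, limit=200)
        assert latent_loss(np.array([x]), schedule) == pytest.approx(numeric, abs=1e-6)

    def test_strictly_positive_under_default_schedule(self, schedule, rng):
        for x in rng.normal(size=(10, 5)):
            assert latent_loss(x, schedule) > 0


class TestAntitheticTimes:
    @pytest.mark.parametrize("n,u0,expected", [
        (4, 0.0, [0.0, 0.25, 0.5, 0.75]),
        (2, 0.1, [0.1, 0.6]),
    ])
    def test_direct_formula(self, n, u0, expected):
        assert antithetic_times(n, u0) == pytest.approx(expected, abs=1e-15)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            antithetic_times(0, 0.5)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 1, exclude_max=True), st.integers(1, 20))
    def test_exactly_one_sample_per_stratum(self, u0, n):
        t = antithetic_times(n, u0)
        bins = np.floor(t * n).astype(int)
        assert sorted(bins) == list(range(n))


class TestDiffusionLoss:
    def test_perfect_predictor_gives_zero(self, schedule, rng):
        x = rng.normal(size=(64, 3))
        pred = perfect_predictor(x)
        assert diffusion_loss_discrete(x, pred, 8, schedule, seed=0) == pytest.approx(
            0.0, abs=1e-18)
        assert diffusion_loss_continuous(x, pred, schedule, seed=0) == pytest.approx(
            0.0, abs=1e-18)

    def test_flat_schedule_kills_discrete_loss(self, rng):
        flat = GammaSchedule(kind="learned", fn=lambda t: np.full(np.shape(t), 0.5))
        x = rng.normal(size=(16, 2))
        loss = diffusion_loss_discrete(x, lambda z, g: np.zeros_like(z), 4, flat, seed=1)
        assert loss == pytest.approx(0.0, abs=1e-15)

    def test_invalid_step_count(self, schedule):
        with pytest.raises(ValueError):
            diffusion_loss_discrete(np.zeros((2, 2)), lambda z, g: z, 0, schedule)

    def test_zero_predictor_continuous_expectation(self, schedule):
        """eps_hat = 0 with d dims: E = d * (gamma_max - gamma_min) / 2."""
        d, n = 4, 100_000
        x = np.zeros((n, d))
        loss = diffusion_loss_continuous(x, lambda z, g: np.zeros_like(z),
                                         schedule, seed=3)
        expected = 0.5 * 0.9 * d
        se = 0.5 * 0.9 * np.sqrt(2 * d / n)  # chi-square variance
        assert abs(loss - expected) < 4 * se

    def test_nonnegative_for_arbitrary_predictors(self, schedule, rng):
        x = rng.normal(size=(32, 2))
        for k in range(5):
            r = np.random.default_rng(k)
            a, b = r.normal(), r.normal()
            pred = lambda z, g: a * z + b
            assert diffusion_loss_discrete(x, pred, 6, schedule, seed=k) >= 0
            assert diffusion_loss_continuous(x, pred, schedule, seed=k) >= 0


from oracles import exact_chain_kl


class TestDiscreteLossJointKL:
    A, B_COEF, X = 0.3, 0.1, 0.7

    def _mc_loss(self, T, schedule, n=200_000, seed=11):
        x = np.full((n, 1), self.X)
        pred = lambda z, g: self.A * z + self.B_COEF
        return float(diffusion_loss_discrete(x, pred, T, schedule, seed=seed))

    @pytest.mark.parametrize("T", [1, 2, 4, 8])
    def test_matches_exact_gaussian_chain_kl(self, schedule, T):
        exact = exact_chain_kl(self.X, self.A, self.B_COEF, T, schedule)
        mc = self._mc_loss(T, schedule)
        assert mc == pytest.approx(exact, rel=0.03)

    def test_nonincreasing_in_T_and_converges_to_continuous(self, schedule):
        losses = [self._mc_loss(T, schedule, seed=11) for T in (2, 8, 32, 128, 512)]
        for lo, hi in zip(losses[1:], losses[:-1]):
            assert lo <= hi * 1.02 + 1e-4  # nonincreasing within MC slack
        n = 200_000
        x = np.full((n, 1), self.X)
        pred = lambda z, g: self.A * z + self.B_COEF
        cont = float(diffusion_loss_continuous(x, pred, schedule, seed=11))
        assert losses[-1] == pytest.approx(cont, rel=0.03)
        # exact oracle converges to the closed-form continuous integral too
        integrand = lambda t: 0.5 * 0.9 * (
            (1 - self.A * np.sqrt(expit(0.1 + 0.9 * t))) ** 2
            + (self.A * np.sqrt(expit(-(0.1 + 0.9 * t))) * self.X + self.B_COEF) ** 2)
        closed, _ = quad(integrand, 0, 1)
        assert exact_chain_kl(self.X, self.A, self.B_COEF, 4096, schedule) == \
            pytest.approx(closed, rel=1e-3)


class TestDifferential:
    def test_identical_images(self, rng):
        x = rng.uniform(size=(5, 5))
        assert differential_loss(x, x) == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-2, 2))
    def test_constant_shift_invariance(self, c):
        x = np.random.default_rng(0).uniform(size=(6, 6))
        assert differential_loss(x, np.clip(x + c, -10, 10) * 0 + (x + c)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_by_two(self):
        x = np.array([[0.0, 1.0], [0.0, 1.0]])
        x_hat = np.zeros((2, 2))
        # single interior cell: horizontal diff error (1-0)^2, vertical 0
        assert differential_loss(x, x_hat) == pytest.approx(1.0, abs=1e-15)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            differential_loss(np.zeros((1, 2)), np.zeros((1, 2)))


class TestTotalLoss:
    def test_breakdown_additivity(self, tiny_cfg, tiny_params, schedule, rng):
        x = rng.uniform(size=(4, 16, 16))
        w = LossWeights(reconstruction=1.0, diffusion=0.5, latent=2.0, differential=0.25)
        bd = total_loss(x, tiny_params, tiny_cfg, schedule, weights=w, seed=42)
        manual = (w.reconstruction * bd.reconstruction + w.diffusion * bd.diffusion
                  + w.latent * bd.latent + w.differential * bd.differential)
        assert bd.total == pytest.approx(manual, abs=1e-10)

    def test_unit_weights_sum(self, tiny_cfg, tiny_params, schedule, rng):
        x = rng.uniform(size=(2, 16, 16))
        bd = total_loss(x, tiny_params, tiny_cfg, schedule, seed=1)
        assert bd.total == pytest.approx(
            bd.reconstruction + bd.diffusion + bd.latent + bd.differential, abs=1e-10)

    def test_zero_weights_keep_breakdown(self, tiny_cfg, tiny_params, schedule, rng):
        x = rng.uniform(size=(2, 16, 16))
        w = LossWeights(0.0, 0.0, 0.0, 0.0)
        bd = total_loss(x, tiny_params, tiny_cfg, schedule, weights=w, seed=1)
        assert bd.total == 0.0
        assert bd.reconstruction > 0 and bd.latent > 0

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(reconstruction=-1.0)

    def test_seeded_determinism(self, tiny_cfg, tiny_params, schedule, rng):
        x = rng.uniform(size=(2, 16, 16))
        bd1 = total_loss(x, tiny_params, tiny_cfg, schedule, seed=9)
        bd2 = total_loss(x, tiny_params, tiny_cfg, schedule, seed=9)
        assert bd1.as_dict() == bd2.as_dict()
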
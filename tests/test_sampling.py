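"""Predictor-corrector sampler: forced examples, Langevin physics, invariants."""

import numpy as np
import pytest

from scoredose import (
    ConfigError,
    ParameterError,
    SamplerConfig,
    ShapeError,
    apply_data_consistency,
    corrector_step,
    corrector_step_size,
    make_schedule,
    predictor_step,
    sample,
)


def analytic_gaussian_score(mu, sd):
    """Exact score of N(mu, sd^2) after perturbation to noise level sigma."""

    def model(stack, sigma):
        x = stack[:, 0]
        return (-(x - mu) / (sd**2 + float(sigma) ** 2))[:, None]

    return model


class TestPredictorStep:
    def test_forced_numeric_example(self):
        # x=1, sigma_{i+1}=2, sigma_i=1, score=-0.25, z=0 -> 1 + 3*(-0.25)
        sch = make_schedule("ve", 2, sigma_min=1.0, sigma_max=4.0)  # sigmas 1,2,4
        x = np.ones((2, 2))
        out = predictor_step(x, 0, np.full((2, 2), -0.25), sch, np.zeros((2, 2)))
        np.testing.assert_allclose(out, 0.25)

    def test_identity_when_score_and_noise_vanish(self, ve_schedule, rng):
        x = rng.random((4, 4))
        out = predictor_step(x, 3, np.zeros((4, 4)), ve_schedule, np.zeros((4, 4)))
        np.testing.assert_array_equal(out, x)

    def test_index_out_of_range_rejected(self, ve_schedule):
        z = np.zeros((2, 2))
        with pytest.raises(Exception):
            predictor_step(z, ve_schedule.N, z, ve_schedule, z)

    def test_shape_mismatch_rejected(self, ve_schedule):
        with pytest.raises(ShapeError):
            predictor_step(np.zeros((2, 2)), 0, np.zeros((3, 3)), ve_schedule,
                           np.zeros((2, 2)))


class TestCorrectorStep:
    def test_zero_step_size_is_identity(self, rng):
        x = rng.random((3, 3))
        out = corrector_step(x, 0, rng.random((3, 3)), 0.0, np.zeros((3, 3)))
        np.testing.assert_array_equal(out, x)

    def test_forced_numeric_example(self):
        out = corrector_step(np.zeros((2, 2)), 0, np.full((2, 2), 2.0), 0.01,
                             np.zeros((2, 2)))
        np.testing.assert_allclose(out, 0.02)

    def test_negative_step_size_rejected(self):
        z = np.zeros((2, 2))
        with pytest.raises(ParameterError):
            corrector_step(z, 0, z, -0.1, z)


class TestCorrectorStepSize:
    def test_equal_norms_give_two_r_squared(self, rng):
        z = rng.standard_normal((8, 8))
        score = z.copy()
        assert corrector_step_size(score, z, 0.5) == pytest.approx(0.5)

    def test_quadratic_in_snr(self, rng):
        score = rng.standard_normal((8, 8))
        z = rng.standard_normal((8, 8))
        e1 = corrector_step_size(score, z, 0.16)
        e2 = corrector_step_size(score, z, 0.32)
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_matches_direct_formula(self, rng):
        score = rng.standard_normal((8, 8))
        z = rng.standard_normal((8, 8))
        direct = 2.0 * (0.16 * np.linalg.norm(z) / np.linalg.norm(score)) ** 2
        assert corrector_step_size(score, z, 0.16) == pytest.approx(direct, abs=1e-12)

    def test_zero_score_uses_fallback_with_warning(self, rng, caplog):
        z = rng.standard_normal((4, 4))
        with caplog.at_level("WARNING", logger="scoredose.sampling"):
            eps = corrector_step_size(np.zeros((4, 4)), z, 0.16, fallback_eps=1e-6)
        assert eps == pytest.approx(1e-6)
        assert any("fallback" in r.message for r in caplog.records)

    def test_zero_score_without_fallback_rejected(self, rng):
        with pytest.raises(ParameterError):
            corrector_step_size(np.zeros((4, 4)), rng.standard_normal((4, 4)), 0.16)


class TestDataConsistency:
    def test_conditioning_channels_overwritten_exactly(self, rng):
        stack = rng.random((2, 3, 8, 8))
        cond = rng.random((2, 2, 8, 8))
        out = apply_data_consistency(stack, cond)
        np.testing.assert_array_equal(out[:, 1:], cond)
        np.testing.assert_array_equal(out[:, 0], stack[:, 0])

    def test_idempotent(self, rng):
        stack = rng.random((3, 8, 8))
        cond = rng.random((2, 8, 8))
        once = apply_data_consistency(stack, cond)
        twice = apply_data_consistency(once, cond)
        np.testing.assert_array_equal(once, twice)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            apply_data_consistency(rng.random((2, 3, 8, 8)), rng.random((2, 3, 8, 8)))


class TestLangevin:
    def test_corrector_chain_reaches_stationary_variance(self, rng):
        # corrector-only chain at fixed sigma: stationary variance of the
        # noised marginal is sd^2 + sigma^2 (within 5%)
        mu, sd, sigma = 0.0, 0.2, 0.3
        target_var = sd**2 + sigma**2
        model = analytic_gaussian_score(mu, sd)
        x = 0.5 * rng.standard_normal((4, 32, 32))
        vals = []
        for k in range(800):
            stack = x[:, None]
            score = model(stack, sigma)[:, 0]
            z = rng.standard_normal(x.shape)
            eps = corrector_step_size(score, z, 0.16)
            x = corrector_step(x, 0, score, eps, z)
            if k >= 300:
                vals.append(x.var())
        assert np.mean(vals) == pytest.approx(target_var, rel=0.05)


class TestSample:
    def test_seeded_runs_are_identical(self, tiny_model, rng):
        sch = make_schedule("ve", 20, sigma_min=0.01, sigma_max=0.6)
        cfg = SamplerConfig(N_steps=20, M_corrector=1, seed=3)
        cond = rng.random((2, 1, 16, 16))
        a = sample(tiny_model, cond, cfg, sch)
        b = sample(tiny_model, cond, cfg, sch)
        np.testing.assert_array_equal(a, b)

    def test_predictor_only_returns_finite_field(self, tiny_model, rng):
        sch = make_schedule("ve", 20, sigma_min=0.01, sigma_max=0.6)
        cfg = SamplerConfig(N_steps=20, M_corrector=0, seed=3)
        out = sample(tiny_model, rng.random((1, 16, 16)), cfg, sch)
        assert out.shape == (16, 16)
        assert np.isfinite(out).all()

    def test_step_count_mismatch_rejected(self, tiny_model, rng):
        sch = make_schedule("ve", 20, sigma_min=0.01, sigma_max=0.6)
        with pytest.raises(ConfigError):
            sample(tiny_model, rng.random((1, 16, 16)),
                   SamplerConfig(N_steps=30, seed=0), sch)

    def test_conditioning_bit_identical_at_every_iteration(self, tiny_model, rng):
        sch = make_schedule("ve", 15, sigma_min=0.01, sigma_max=0.6)
        cond = rng.random((2, 1, 16, 16))
        seen = []
        sample(tiny_model, cond, SamplerConfig(N_steps=15, M_corrector=1, seed=1),
               sch, callback=lambda i, stack: seen.append(stack[:, 1:].copy()))
        assert len(seen) > 15
        for stack_cond in seen:
            np.testing.assert_array_equal(stack_cond, cond)

    def test_scale_index_strictly_decreases(self, tiny_model, rng):
        sch = make_schedule("ve", 12, sigma_min=0.01, sigma_max=0.6)
        order = []
        sample(tiny_model, rng.random((1, 1, 16, 16)),
               SamplerConfig(N_steps=12, M_corrector=1, seed=1), sch,
               callback=lambda i, stack: order.append(i))
        assert np.all(np.diff(order) <= 0)  # annealing never goes back up
        assert sorted(set(order), reverse=True) == list(range(12, -1, -1))

    @pytest.mark.parametrize("n_steps", [100, 500])
    def test_analytic_score_recovers_target_moments(self, n_steps):
        # with the exact Gaussian score substituted for the network the
        # sampler must reproduce the target mean (3 SE) and variance (10%)
        mu, sd = 0.3, 0.1
        sch = make_schedule("ve", n_steps, sigma_min=0.01, sigma_max=6.0)
        cfg = SamplerConfig(N_steps=n_steps, M_corrector=1, snr_r=0.16, seed=11,
                            clip=None)
        out = sample(analytic_gaussian_score(mu, sd), np.zeros((64, 1, 16, 16)),
                     cfg, sch)
        se = sd / np.sqrt(out.size)
        assert abs(out.mean() - mu) < 3 * se
        assert out.var() == pytest.approx(sd**2, rel=0.10)

    def test_corrector_not_inferior_at_coarse_discretization(self):
        # at small N both modes must converge; the corrector should not
        # increase the moment error
        mu, sd = 0.3, 0.1
        n_steps = 60
        sch = make_schedule("ve", n_steps, sigma_min=0.01, sigma_max=6.0)
        cond = np.zeros((48, 1, 16, 16))
        model = analytic_gaussian_score(mu, sd)
        out_pc = sample(model, cond, SamplerConfig(N_steps=n_steps, M_corrector=1,
                                                   seed=2, clip=None), sch)
        out_p = sample(model, cond, SamplerConfig(N_steps=n_steps, M_corrector=0,
                                                  seed=2, clip=None), sch)
        err_pc = abs(out_pc.var() - sd**2)
        err_p = abs(out_p.var() - sd**2)
        assert abs(out_pc.mean() - mu) < 0.01
        assert err_pc <= err_p + 0.1 * sd**2
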
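"""Noise schedules and Gaussian perturbation kernels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from scoredose import (
    DegenerateTimeError,
    ParameterError,
    RangeError,
    ShapeError,
    make_schedule,
    perturb,
    perturbation_kernel,
    score_target,
)


class TestMakeSchedule:
    def test_geometric_scales_match_interpolation_oracle(self):
        sch = make_schedule("ve", 3, sigma_min=0.01, sigma_max=0.6)
        expected = [0.01 * (0.6 / 0.01) ** (i / 3) for i in range(4)]
        np.testing.assert_allclose(sch.sigmas, expected, rtol=1e-12)
        np.testing.assert_allclose(sch.sigmas, [0.01, 0.039149, 0.153262, 0.6],
                                   rtol=1e-4)

    def test_default_experiment_schedule_has_exact_endpoints(self):
        sch = make_schedule("ve", 1500, sigma_min=0.01, sigma_max=0.6)
        assert len(sch.sigmas) == 1501
        assert sch.sigmas[-1] == 0.6
        assert sch.sigmas[0] == 0.01

    @pytest.mark.parametrize(
        "kind,N,kw",
        [
            ("ve", 1, {}),
            ("ve", 10, {"sigma_min": 0.6, "sigma_max": 0.01}),
            ("ve", 10, {"sigma_min": -1.0, "sigma_max": 0.6}),
            ("vp", 10, {"beta_min": 20.0, "beta_max": 0.1}),
            ("bogus", 10, {}),
        ],
    )
    def test_invalid_parameters_rejected(self, kind, N, kw):
        with pytest.raises(ParameterError):
            make_schedule(kind, N, **kw)

    @given(N=st.integers(2, 400), lo=st.floats(1e-3, 0.5), ratio=st.floats(1.5, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_log_sigma_affine_in_index(self, N, lo, ratio):
        sch = make_schedule("ve", N, sigma_min=lo, sigma_max=lo * ratio)
        logs = np.log(sch.sigmas)
        diffs = np.diff(logs)
        assert np.max(np.abs(diffs - diffs[0])) < 1e-10
        assert np.all(np.diff(sch.sigmas) > 0)

    def test_vp_beta_monotone_and_bounded_in_unit_interval(self):
        sch = make_schedule("vp", 1000, beta_min=0.1, beta_max=20.0)
        ts = np.linspace(0, 1, 50)
        betas = np.array([sch.beta(t) for t in ts])
        assert np.all(np.diff(betas) > 0)
        # per-step noise scales beta(t)/N stay inside (0, 1)
        assert np.all((betas / sch.N > 0) & (betas / sch.N < 1))


class TestPerturbationKernel:
    def test_ve_preserves_mean_with_sigma_std(self, ve_schedule):
        kp = perturbation_kernel(ve_schedule, i=ve_schedule.N)
        assert kp.mean_coeff == 1.0
        assert kp.std == pytest.approx(0.6)

    def test_vp_identity_at_time_zero(self, vp_schedule):
        kp = perturbation_kernel(vp_schedule, t=0.0)
        assert kp.mean_coeff == pytest.approx(1.0)
        assert kp.std == 0.0

    def test_vp_terminal_coeff_matches_beta_integral_oracle(self, vp_schedule):
        # independent oracle: m(t) = exp(-1/2 * int_0^t beta(s) ds) by quadrature
        integral, _ = quad(vp_schedule.beta, 0.0, 1.0)
        kp = perturbation_kernel(vp_schedule, t=1.0)
        assert kp.mean_coeff == pytest.approx(np.exp(-0.5 * integral), rel=1e-9)
        assert kp.std == pytest.approx(np.sqrt(1 - np.exp(-integral)), rel=1e-9)

    def test_vp_signal_diminishes_toward_horizon(self, vp_schedule):
        coeffs = [perturbation_kernel(vp_schedule, t=t).mean_coeff
                  for t in np.linspace(0, 1, 11)]
        assert np.all(np.diff(coeffs) < 0)
        assert coeffs[-1] < 0.01

    def test_time_out_of_range_rejected(self, ve_schedule):
        with pytest.raises(RangeError):
            perturbation_kernel(ve_schedule, t=1.5)
        with pytest.raises(RangeError):
            perturbation_kernel(ve_schedule, i=ve_schedule.N + 1)


class TestPerturb:
    def test_explicit_noise_field(self, ve_schedule):
        x0 = np.zeros((4, 4))
        z = np.ones((4, 4))
        out = perturb(x0, ve_schedule, i=ve_schedule.N, z=z)
        np.testing.assert_allclose(out, 0.6)

    def test_vp_time_zero_identity(self, vp_schedule, rng):
        x0 = rng.random((5, 5))
        out = perturb(x0, vp_schedule, t=0.0, rng=rng)
        np.testing.assert_array_equal(out, x0)

    def test_shape_mismatch_rejected(self, ve_schedule):
        with pytest.raises(ShapeError):
            perturb(np.zeros((3, 3)), ve_schedule, i=0, z=np.zeros((2, 2)))

    def test_requires_noise_source(self, ve_schedule):
        with pytest.raises(ParameterError):
            perturb(np.zeros((3, 3)), ve_schedule, i=0)

    def test_ve_monte_carlo_variance(self, rng):
        # empirical variance of 1e5 scalar draws at sigma = 0.5 within 2%
        sch = make_schedule("ve", 4, sigma_min=0.1, sigma_max=0.5)
        draws = perturb(np.zeros(100_000), sch, i=sch.N, rng=rng)
        assert draws.var() == pytest.approx(0.25, rel=0.02)

    def test_ve_variance_additivity(self, rng):
        # Var[x_t] - Var[x_0] = sigma(t)^2 for deterministic x0 (3 SE)
        sch = make_schedule("ve", 4, sigma_min=0.05, sigma_max=0.4)
        n = 50_000
        x0 = np.full(n, 0.7)
        for i in (0, 2, 4):
            s2 = sch.sigma(i) ** 2
            v = perturb(x0, sch, i=i, rng=rng).var()
            se = s2 * np.sqrt(2.0 / n)
            assert abs(v - s2) < 3 * se

    def test_vp_variance_preserved_for_unit_variance_input(self, vp_schedule, rng):
        # for x0 ~ N(0,1) the total variance stays at 1 for every t (3 SE)
        n = 50_000
        x0 = rng.standard_normal(n)
        for t in (0.1, 0.5, 1.0):
            v = perturb(x0, vp_schedule, t=t, rng=rng).var()
            assert abs(v - 1.0) < 3 * np.sqrt(2.0 / n)


class TestScoreTarget:
    def test_matches_hand_computed_gaussian_score(self):
        sch = make_schedule("ve", 2, sigma_min=2.0, sigma_max=2.0 + 1e-12)
        out = score_target(np.zeros((2, 2)), np.full((2, 2), 2.0), sch, i=0)
        np.testing.assert_allclose(out, -0.5)

    def test_zero_at_kernel_center(self, vp_schedule, rng):
        x0 = rng.random((6, 6))
        kp = perturbation_kernel(vp_schedule, t=0.5)
        out = score_target(x0, kp.mean_coeff * x0, vp_schedule, t=0.5)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_finite_difference_log_density_gradient(self, rng):
        # numeric-gradient oracle of log N(xt; x0, sigma^2) per element
        sch = make_schedule("ve", 4, sigma_min=0.3, sigma_max=0.9)
        x0 = rng.random((3, 3))
        xt = x0 + rng.normal(scale=0.3, size=(3, 3))
        sigma = sch.sigma(0)

        def logp(x):
            return -0.5 * np.sum((x - x0) ** 2) / sigma**2

        analytic = score_target(x0, xt, sch, i=0)
        h = 1e-6
        for idx in np.ndindex(3, 3):
            e = np.zeros((3, 3))
            e[idx] = h
            fd = (logp(xt + e) - logp(xt - e)) / (2 * h)
            assert abs(fd - analytic[idx]) < 1e-4

    def test_degenerate_vp_time_rejected(self, vp_schedule):
        with pytest.raises(DegenerateTimeError):
            score_target(np.zeros((2, 2)), np.zeros((2, 2)), vp_schedule, t=0.0)

    def test_shape_mismatch_rejected(self, ve_schedule):
        with pytest.raises(ShapeError):
            score_target(np.zeros((2, 2)), np.zeros((3, 3)), ve_schedule, i=1)
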
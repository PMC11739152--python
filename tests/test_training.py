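"""Denoising score-matching loss and training loop."""

import numpy as np
import pytest

from scoredose import (
    DataError,
    PairedCase,
    ScoreModelConfig,
    TrainConfig,
    build_score_model,
    make_schedule,
)
from scoredose.exceptions import ConfigError
from scoredose.training import cases_to_arrays, dsm_loss, train


@pytest.fixture
def schedule():
    return make_schedule("ve", 20, sigma_min=0.01, sigma_max=0.6)


def _batch(rng, n=8, size=16):
    x0 = rng.random((n, size, size)).astype(np.float32)
    cond = rng.random((n, 1, size, size)).astype(np.float32)
    return x0, cond


class TestDsmLoss:
    def test_perfect_score_gives_zero_loss(self, schedule, rng):
        x0, cond = _batch(rng)

        def oracle(x_stack, sigma):
            sig = np.asarray(sigma)[:, None, None]
            return (-(x_stack[:, 0] - x0) / sig**2)[:, None]

        loss = dsm_loss(oracle, (x0, cond), schedule, rng)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-10)

    def test_zero_model_sigma_sq_loss_is_unit(self, schedule, rng):
        # with lambda = sigma^2 the zero model's loss is E||z||^2 / n_pixels = 1
        x0, cond = _batch(rng, n=64, size=16)
        zero = lambda x_stack, sigma: np.zeros_like(x_stack[:, :1])
        vals = [float(dsm_loss(zero, (x0, cond), schedule, rng).data)
                for _ in range(4)]
        n = 64 * 16 * 16 * 4
        assert np.mean(vals) == pytest.approx(1.0, abs=4 * np.sqrt(2.0 / n))

    def test_loss_nonnegative_for_arbitrary_model(self, schedule, rng):
        x0, cond = _batch(rng)
        noisy = lambda x_stack, sigma: np.random.default_rng(0).standard_normal(
            x_stack[:, :1].shape)
        assert float(dsm_loss(noisy, (x0, cond), schedule, rng).data) >= 0

    def test_per_scale_contributions_are_order_one(self, rng):
        # balancedness of the sigma^2 weighting: each scale contributes ~1
        # for the zero model (checked scale by scale with a 2-scale schedule)
        for smax in (0.05, 0.5, 5.0):
            sch = make_schedule("ve", 2, sigma_min=0.9 * smax, sigma_max=smax)
            x0, cond = _batch(rng, n=32)
            zero = lambda x_stack, sigma: np.zeros_like(x_stack[:, :1])
            val = float(dsm_loss(zero, (x0, cond), sch, rng).data)
            assert 0.8 < val < 1.2

    def test_missing_target_channel_rejected(self, schedule, rng):
        case = PairedCase("c0", "H&N", np.zeros((8, 8)), np.zeros((8, 8)), None)
        with pytest.raises(DataError):
            dsm_loss(lambda *a: None, [case], schedule, rng)


def _toy_cases(rng, n, size=16):
    """1-D Gaussian toy data: constant-per-case target around 0.5."""
    cases = []
    for k in range(n):
        val = rng.normal(0.5, 0.1)
        fld = np.full((size, size), val, dtype=np.float32)
        cond = np.full((size, size), 0.5, dtype=np.float32)
        cases.append(PairedCase(f"toy_{k:03d}", "H&N", cond, cond, fld))
    return cases


class TestTrain:
    def test_validation_loss_drops_on_toy_gaussian_data(self, rng):
        sch = make_schedule("ve", 20, sigma_min=0.01, sigma_max=0.6)
        cfg = ScoreModelConfig(in_channels=2, base_width=8, depth=2,
                               width_multipliers=(1, 2), time_embed_dim=16)
        model = build_score_model(cfg, seed=1)
        cases = _toy_cases(np.random.default_rng(0), 32)
        tc = TrainConfig(epochs=50, batch_size=8, learning_rate=2e-3, seed=5,
                         ema_decay=None)
        out = train(model, cases[:24], cases[24:], tc, sch)
        first, last = out.trace["val"][0], out.trace["val"][-1]
        assert last < 0.7 * first

    def test_fixed_seed_reproduces_loss_trace(self, tiny_config):
        sch = make_schedule("ve", 10, sigma_min=0.05, sigma_max=0.5)
        cases = _toy_cases(np.random.default_rng(2), 12)
        traces = []
        for _ in range(2):
            model = build_score_model(tiny_config, seed=3)
            tc = TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3, seed=9)
            traces.append(train(model, cases[:8], cases[8:], tc, sch).trace)
        assert traces[0] == traces[1]

    def test_zero_epochs_returns_model_unchanged(self, tiny_model):
        sch = make_schedule("ve", 10, sigma_min=0.05, sigma_max=0.5)
        before = tiny_model.state_dict()
        out = train(tiny_model, _toy_cases(np.random.default_rng(1), 4), [],
                    TrainConfig(epochs=0), sch)
        assert out.trace == {"train": [], "val": []}
        for k, v in before.items():
            np.testing.assert_array_equal(out.model.params[k].data, v)

    def test_empty_dataset_rejected(self, tiny_model):
        sch = make_schedule("ve", 10, sigma_min=0.05, sigma_max=0.5)
        with pytest.raises(DataError):
            train(tiny_model, [], [], TrainConfig(epochs=1), sch)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ConfigError):
            TrainConfig(batch_size=0)
        with pytest.raises(ConfigError):
            TrainConfig(lambda_weighting="cubed")
        with pytest.raises(ConfigError):
            TrainConfig(lr_schedule="step")


class TestCasesToArrays:
    def test_stacks_channels_in_documented_order(self, tiny_dataset):
        x0, cond = cases_to_arrays(tiny_dataset.train[:4], with_ct=True)
        assert x0.shape == (4, 16, 16)
        assert cond.shape == (4, 2, 16, 16)
        np.testing.assert_array_equal(x0[0], tiny_dataset.train[0].mdose.astype(np.float32))
        np.testing.assert_array_equal(cond[0, 0],
                                      tiny_dataset.train[0].rtdose.astype(np.float32))
        np.testing.assert_array_equal(cond[0, 1],
                                      tiny_dataset.train[0].ct.astype(np.float32))
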
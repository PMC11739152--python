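import numpy as np
import pytest

from scoredose import (
    ErrorModel,
    ScoreModelConfig,
    build_score_model,
    make_dataset,
    make_schedule,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ve_schedule():
    return make_schedule("ve", 10, sigma_min=0.01, sigma_max=0.6)


@pytest.fixture
def vp_schedule():
    return make_schedule("vp", 10, beta_min=0.1, beta_max=20.0)


@pytest.fixture
def tiny_config():
    return ScoreModelConfig(in_channels=2, base_width=8, depth=2,
                            width_multipliers=(1, 2), time_embed_dim=16)


@pytest.fixture
def tiny_model(tiny_config):
    return build_score_model(tiny_config, seed=0)


def randomize_model(model, rng, scale=0.05):
    """Give zero-initialized parameter tensors small random values.

    Fresh score networks output exactly zero (zero-init output head), so
    sensitivity tests need non-degenerate weights.
    """
    for p in model.params.values():
        if float(np.abs(p.data).max()) == 0.0:
            p.data = rng.normal(scale=scale, size=p.data.shape).astype(p.data.dtype)
    return model


@pytest.fixture
def tiny_dataset():
    """16 small paired cases with the default error model."""
    return make_dataset(n_cases=16, split_ratio=0.75, seed=7, grid_size=(16, 16))


@pytest.fixture
def identity_dataset():
    """Paired cases where measured dose equals planned dose exactly."""
    err = ErrorModel(blur_sigma=0.0, shift=(0.0, 0.0), calib_amplitude=0.0, noise_sd=0.0)
    return make_dataset(n_cases=8, split_ratio=0.75, error=err, seed=3,
                        grid_size=(16, 16))
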
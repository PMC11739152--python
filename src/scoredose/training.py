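"""Denoising score-matching training loop.

The network is trained to match the analytic score of the Gaussian
perturbation kernel: a scale index is drawn uniformly per sample, the
target channel is perturbed to that scale, the clean conditioning
channels are stacked alongside (conditioning is never noised), and the
weighted squared error

    lambda(sigma_i) * || s_Theta(x_stack, sigma_i) - grad log p(x_t | x_0) ||^2

is minimised over the batch.  With the default weighting
``lambda = sigma^2`` the per-scale targets are unit-scale (the loss of
the zero model is exactly ``E||z||^2 / n_pixels = 1``), which keeps all
noise levels balanced in the objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .autodiff import Adam, Tensor
from .exceptions import ConfigError, DataError, DivergenceError
from .network import EMA, ScoreUNet
from .sde import NoiseSchedule, perturbation_kernel
from .synthetic import PairedCase

__all__ = ["TrainConfig", "TrainOutput", "dsm_loss", "train", "cases_to_arrays"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters for score matching."""

    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 2e-4
    lambda_weighting: str = "sigma_sq"  # "sigma_sq" | "one"
    ema_decay: Optional[float] = 0.999  # None disables EMA
    seed: int = 0
    time_sampling: str = "uniform_discrete"
    grad_clip: Optional[float] = 1.0
    lr_schedule: str = "cosine"  # "cosine" (with warmup) | "constant"
    warmup_steps: int = 100

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if self.lambda_weighting not in ("sigma_sq", "one"):
            raise ConfigError(f"unknown lambda_weighting {self.lambda_weighting!r}")
        if self.time_sampling != "uniform_discrete":
            raise ConfigError(f"unknown time_sampling {self.time_sampling!r}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ConfigError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.warmup_steps < 0:
            raise ConfigError("warmup_steps must be >= 0")


def cases_to_arrays(
    cases: Sequence[PairedCase], with_ct: bool = False
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack cases into ``(x0, cond)`` arrays: (B,H,W) targets, (B,C-1,H,W) conditioning."""
    if len(cases) == 0:
        raise DataError("empty case list")
    if any(c.mdose is None for c in cases):
        raise DataError("case is missing the MDose (target) channel")
    x0 = np.stack([c.mdose for c in cases]).astype(np.float32)
    cond = np.stack([c.stack(with_ct=with_ct) for c in cases]).astype(np.float32)
    return x0, cond


def _kernel_arrays(schedule: NoiseSchedule, idx: np.ndarray):
    mc = np.empty(len(idx))
    std = np.empty(len(idx))
    for j, i in enumerate(idx):
        kp = perturbation_kernel(schedule, i=int(i))
        mc[j], std[j] = kp.mean_coeff, kp.std
    return mc, std


def dsm_loss(
    model,
    batch: Union[Sequence[PairedCase], Tuple[np.ndarray, np.ndarray]],
    schedule: NoiseSchedule,
    rng: np.random.Generator,
    lambda_weighting: str = "sigma_sq",
    with_ct: bool = False,
) -> Tensor:
    """Denoising score-matching loss over one batch (differentiable scalar).

    ``batch`` is either a sequence of :class:`PairedCase` or a pre-stacked
    ``(x0, cond)`` pair.  ``model`` may be any callable
    ``(x_stack, sigma) -> score``; a :class:`ScoreUNet` is called through
    its differentiable ``forward``.
    """
    if isinstance(batch, tuple):
        x0, cond = batch
    else:
        x0, cond = cases_to_arrays(batch, with_ct=with_ct)
    B = x0.shape[0]
    lo = 1 if schedule.kind == "vp" else 0  # VP kernel is degenerate at i=0
    idx = rng.integers(lo, schedule.N + 1, size=B)
    mc, std = _kernel_arrays(schedule, idx)
    z = rng.standard_normal(x0.shape)
    xt = mc[:, None, None] * x0 + std[:, None, None] * z
    target = (-z / std[:, None, None])[:, None]  # == -(xt - mc*x0)/std^2, (B,1,H,W)
    x_stack = np.concatenate([xt[:, None], cond], axis=1).astype(np.float32)

    if hasattr(model, "forward"):
        s = model.forward(x_stack, std)
    else:
        s = Tensor(np.asarray(model(x_stack, std)))
    if s.data.shape != target.shape:
        s = s.reshape(*target.shape)

    lam = std**2 if lambda_weighting == "sigma_sq" else np.ones_like(std)
    w = Tensor(lam[:, None, None, None].astype(x0.dtype))
    diff = s - Tensor(target.astype(np.float32))
    return (diff * diff * w).mean()


def _lr_at(step: int, total_steps: int, config: TrainConfig) -> float:
    """Per-step learning rate: linear warmup then cosine decay (or constant)."""
    base = config.learning_rate
    if config.lr_schedule == "constant":
        return base
    warm = min(config.warmup_steps, max(total_steps // 10, 1))
    if step < warm:
        return base * (step + 1) / warm
    frac = (step - warm) / max(total_steps - warm, 1)
    return base * 0.5 * (1.0 + float(np.cos(np.pi * min(frac, 1.0))))


@dataclass
class TrainOutput:
    """Trained model plus per-epoch loss traces and optional EMA weights."""

    model: ScoreUNet
    trace: dict
    ema: Optional[EMA] = None

    def ema_model(self) -> ScoreUNet:
        """A copy of the model carrying the EMA weights (or raw weights if EMA off)."""
        m = ScoreUNet(self.model.config, seed=self.model.seed)
        m.load_state_dict(self.model.state_dict())
        if self.ema is not None:
            self.ema.copy_to(m)
        return m


def train(
    model: ScoreUNet,
    train_cases: Sequence[PairedCase],
    val_cases: Sequence[PairedCase],
    config: TrainConfig,
    schedule: NoiseSchedule,
    with_ct: bool = False,
    verbose: bool = False,
) -> TrainOutput:
    """Run score-matching training; deterministic given ``config.seed``.

    Returns the trained model (updated in place), per-epoch train and
    validation loss traces, and the EMA tracker when enabled.  Raises
    :class:`DivergenceError` on a non-finite loss.
    """
    if len(train_cases) == 0:
        raise DataError("empty training set")
    if config.epochs == 0:
        return TrainOutput(model=model, trace={"train": [], "val": []}, ema=None)

    x0_tr, cond_tr = cases_to_arrays(train_cases, with_ct=with_ct)
    val_batch = cases_to_arrays(val_cases, with_ct=with_ct) if len(val_cases) else None

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate, grad_clip=config.grad_clip)
    ema = EMA(model, config.ema_decay) if config.ema_decay is not None else None
    n = len(train_cases)
    steps_per_epoch = -(-n // config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    trace = {"train": [], "val": []}

    step = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            opt.lr = _lr_at(step, total_steps, config)
            step += 1
            sel = perm[start : start + config.batch_size]
            batch = (x0_tr[sel], cond_tr[sel])
            loss = dsm_loss(model, batch, schedule, rng, config.lambda_weighting)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, step {start // config.batch_size}: "
                    f"{lval} (lr={config.learning_rate})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            if ema is not None:
                ema.update(model)
            epoch_losses.append(lval)
        trace["train"].append(float(np.mean(epoch_losses)))

        if val_batch is not None:
            vrng = np.random.default_rng(config.seed + 10_000 + epoch)
            vloss = dsm_loss(model, val_batch, schedule, vrng, config.lambda_weighting)
            trace["val"].append(float(vloss.data))
        if verbose:
            msg = f"epoch {epoch + 1}/{config.epochs} train {trace['train'][-1]:.4f}"
            if trace["val"]:
                msg += f" val {trace['val'][-1]:.4f}"
            print(msg)

    return TrainOutput(model=model, trace=trace, ema=ema)
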
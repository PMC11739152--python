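"""Reverse-SDE predictor–corrector sampling with data consistency.

Generation starts from a pure Gaussian noise field at the largest noise
scale and anneals down the schedule.  Each outer iteration applies

* the **predictor** — the discretized reverse-SDE (VE form)

      x_hat_i = x_{i+1} + (sigma_{i+1}^2 - sigma_i^2) * s(x_{i+1}, sigma_{i+1})
                + sqrt(sigma_{i+1}^2 - sigma_i^2) * z,

* then ``M`` **corrector** (annealed Langevin) refinements

      x_tilde_i = x_hat_i + eps_i * s(x_hat_i, sigma_{i+1}) + sqrt(2 eps_i) * z,

re-imposing the clean conditioning channels (data consistency, DC) after
every update so that only the target channel ever evolves.  The corrector
step size ``eps_i`` follows a signal-to-noise rule
``eps = 2 (r ||z|| / ||s||)^2``.  A final noise-free denoising step at the
smallest scale is applied by default, and the output is clipped to a
physical normalized-dose range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Tuple, Union

import numpy as np

from .exceptions import ConfigError, ParameterError, ScheduleError, ShapeError
from .sde import NoiseSchedule, perturbation_kernel

__all__ = [
    "SamplerConfig",
    "predictor_step",
    "corrector_step",
    "corrector_step_size",
    "apply_data_consistency",
    "sample",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    """Predictor–corrector sampler hyperparameters.

    ``N_steps`` must equal the schedule's discretization count; ``M_corrector``
    Langevin refinements run per outer step; ``snr_r`` is the corrector
    signal-to-noise ratio; ``clip`` bounds the returned normalized dose.
    """

    N_steps: int = 1500
    M_corrector: int = 1
    snr_r: float = 0.16
    final_denoise: bool = True
    seed: int = 0
    dc_mode: str = "reimpose_conditioning"
    clip: Optional[Tuple[float, float]] = (0.0, 1.2)

    def __post_init__(self):
        if self.N_steps < 1:
            raise ConfigError("N_steps must be >= 1")
        if self.M_corrector < 0:
            raise ConfigError("M_corrector must be >= 0")
        if self.snr_r <= 0:
            raise ConfigError("snr_r must be positive")
        if self.dc_mode != "reimpose_conditioning":
            raise ConfigError(f"unknown dc_mode {self.dc_mode!r}")


def predictor_step(
    x: np.ndarray,
    i: int,
    score: np.ndarray,
    schedule: NoiseSchedule,
    z: np.ndarray,
) -> np.ndarray:
    """One reverse-SDE discretization step from scale ``i+1`` down to ``i``.

    VE uses the sigma-indexed update above; VP uses the Euler–Maruyama
    discretization of the reverse SDE with the linear beta ramp.
    """
    x = np.asarray(x)
    score = np.asarray(score)
    z = np.asarray(z)
    if x.shape != score.shape or x.shape != z.shape:
        raise ShapeError(f"shape mismatch: x {x.shape}, score {score.shape}, z {z.shape}")
    if not (0 <= i <= schedule.N - 1):
        raise ScheduleError(f"predictor index {i} outside 0..{schedule.N - 1}")
    if schedule.kind == "ve":
        s_next = schedule.sigma(i + 1)
        s_cur = schedule.sigma(i)
        dvar = s_next**2 - s_cur**2
        if dvar <= 0:
            raise ScheduleError(f"sigma_{i + 1} <= sigma_{i}: schedule not increasing")
        return x + dvar * score + np.sqrt(dvar) * z
    # VP: dx = [-beta/2 x - beta * score] dt + sqrt(beta) dw, integrated backwards
    dt = schedule.T / schedule.N
    t = (i + 1) * dt
    beta = schedule.beta(t) * dt
    return x + 0.5 * beta * x + beta * score + np.sqrt(beta) * z


def corrector_step(
    x: np.ndarray,
    i: int,
    score: np.ndarray,
    eps: Union[float, np.ndarray],
    z: np.ndarray,
) -> np.ndarray:
    """One annealed-Langevin refinement: ``x + eps * score + sqrt(2 eps) * z``."""
    x = np.asarray(x)
    score = np.asarray(score)
    z = np.asarray(z)
    if x.shape != score.shape or x.shape != z.shape:
        raise ShapeError(f"shape mismatch: x {x.shape}, score {score.shape}, z {z.shape}")
    eps = np.asarray(eps, dtype=float)
    if np.any(eps < 0):
        raise ParameterError("corrector step size eps must be >= 0")
    if eps.ndim == 1:  # per-sample sizes for a batched field
        eps = eps.reshape((-1,) + (1,) * (x.ndim - 1))
    return x + eps * score + np.sqrt(2.0 * eps) * z


def corrector_step_size(
    score: np.ndarray,
    z: np.ndarray,
    snr_r: float,
    fallback_eps: Optional[float] = None,
) -> Union[float, np.ndarray]:
    """Signal-to-noise Langevin step size ``eps = 2 (r ||z|| / ||score||)^2``.

    Norms are taken over the trailing two (spatial) axes, so batched
    fields get one step size per sample.  A zero score norm falls back to
    ``fallback_eps`` with a logged warning (or raises if none is given).
    """
    score = np.asarray(score)
    z = np.asarray(z)
    if score.shape != z.shape:
        raise ShapeError(f"score shape {score.shape} != z shape {z.shape}")
    axes = tuple(range(score.ndim - 2, score.ndim)) if score.ndim >= 2 else (0,)
    s_norm = np.sqrt((score**2).sum(axis=axes))
    z_norm = np.sqrt((z**2).sum(axis=axes))
    if np.any(s_norm == 0):
        if fallback_eps is None:
            raise ParameterError("zero score norm and no fallback step size")
        logger.warning("zero score norm in corrector; using fallback eps=%g", fallback_eps)
        s_norm = np.where(s_norm == 0, np.inf, s_norm)
        eps = 2.0 * (snr_r * z_norm / s_norm) ** 2
        eps = np.where(np.isinf(s_norm) | (eps == 0), fallback_eps, eps)
    else:
        eps = 2.0 * (snr_r * z_norm / s_norm) ** 2
    return float(eps) if eps.ndim == 0 else eps


def apply_data_consistency(x_stack: np.ndarray, conditioning: np.ndarray) -> np.ndarray:
    """Overwrite channels 1..C of the stack with the clean conditioning fields.

    Channel 0 (the evolving target) is left untouched.  Idempotent.
    """
    x_stack = np.asarray(x_stack)
    conditioning = np.asarray(conditioning)
    batched = x_stack.ndim == 4
    cond_expected = x_stack.shape[1 if batched else 0] - 1
    cond_ch = conditioning.shape[1 if batched else 0]
    if cond_ch != cond_expected or conditioning.shape != (
        x_stack.shape[:1] + (cond_ch,) + x_stack.shape[2:] if batched
        else (cond_ch,) + x_stack.shape[1:]
    ):
        raise ShapeError(
            f"conditioning shape {conditioning.shape} incompatible with stack "
            f"{x_stack.shape}"
        )
    out = x_stack.copy()
    if batched:
        out[:, 1:] = conditioning
    else:
        out[1:] = conditioning
    return out


def sample(
    model: Callable,
    conditioning: np.ndarray,
    config: SamplerConfig,
    schedule: NoiseSchedule,
    rng: Optional[np.random.Generator] = None,
    callback: Optional[Callable[[int, np.ndarray], None]] = None,
) -> np.ndarray:
    """Generate the predicted dose for the given conditioning stack.

    ``conditioning`` is ``(C-1, H, W)`` for one case or ``(B, C-1, H, W)``
    for a batch; the target channel is initialized as
    ``N(0, sigma_max^2)`` noise and annealed down the schedule with
    predictor, data consistency, and ``M_corrector`` corrector/DC rounds
    per outer step.  ``model`` is any callable ``(x_stack, sigma) ->
    score``.  Deterministic given ``config.seed`` (or the supplied
    ``rng``).  ``callback(i, stack)`` is invoked after every data-
    consistency application, for introspection.
    """
    conditioning = np.asarray(conditioning)
    squeeze = conditioning.ndim == 3
    if squeeze:
        conditioning = conditioning[None]
    if conditioning.ndim != 4:
        raise ShapeError(f"conditioning must be (B, C-1, H, W), got {conditioning.shape}")
    if config.N_steps != schedule.N:
        raise ConfigError(
            f"sampler N_steps={config.N_steps} != schedule scale count N={schedule.N}"
        )
    in_ch = getattr(getattr(model, "config", None), "in_channels", None)
    if in_ch is not None and in_ch != conditioning.shape[1] + 1:
        raise ConfigError(
            f"model expects {in_ch} channels but conditioning provides "
            f"{conditioning.shape[1] + 1}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)

    B, _, H, W = conditioning.shape
    sigma_max = perturbation_kernel(schedule, i=schedule.N).std
    x = rng.standard_normal((B, H, W)) * sigma_max

    def eval_score(stack: np.ndarray, sigma: float) -> np.ndarray:
        out = np.asarray(model(stack, sigma))
        return out.reshape(B, H, W)

    def dc(xf: np.ndarray, i: int) -> np.ndarray:
        stack = np.concatenate([xf[:, None], conditioning], axis=1)
        stack = apply_data_consistency(stack, conditioning)
        if callback is not None:
            callback(i, stack)
        return stack

    stack = dc(x, schedule.N)
    for i in range(schedule.N - 1, -1, -1):
        sig_next = perturbation_kernel(schedule, i=i + 1).std
        sig_cur = perturbation_kernel(schedule, i=i).std
        score = eval_score(stack, sig_next)
        x = predictor_step(x, i, score, schedule, rng.standard_normal(x.shape))
        stack = dc(x, i)
        for _ in range(config.M_corrector):
            score = eval_score(stack, sig_next)
            z = rng.standard_normal(x.shape)
            eps = corrector_step_size(score, z, config.snr_r,
                                      fallback_eps=sig_cur**2 * 1e-4)
            x = corrector_step(x, i, score, eps, z)
            stack = dc(x, i)

    if config.final_denoise:
        sig0 = perturbation_kernel(schedule, i=0).std
        x = x + sig0**2 * eval_score(stack, sig0)
    if config.clip is not None:
        x = np.clip(x, config.clip[0], config.clip[1])
    return x[0] if squeeze else x
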
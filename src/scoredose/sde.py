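"""Forward/reverse SDE machinery: noise schedules and Gaussian perturbation kernels.

Two diffusion parameterizations are supported behind one interface:

* **VE** (variance exploding): ``dx = sqrt(d[sigma^2(t)]/dt) dw``.  The
  perturbation kernel is ``p_t(x_t | x_0) = N(x_0, sigma(t)^2 I)`` — the
  signal is untouched while the noise variance grows from ``sigma_min^2``
  to ``sigma_max^2``.  Discrete scales ``sigma_0 < ... < sigma_N`` are
  geometrically spaced, the standard choice for annealed Langevin /
  predictor–corrector samplers.

* **VP** (variance preserving): ``dx = -beta(t)/2 x dt + sqrt(beta(t)) dw``
  with a linear ``beta(t)`` ramp.  The kernel is
  ``N(m(t) x_0, (1 - m(t)^2) I)`` with
  ``m(t) = exp(-t^2 (beta_max - beta_min)/4 - t beta_min / 2)``, so the
  total variance of a unit-variance input is held at one while the signal
  coefficient decays toward zero.

Internally everything is discrete with ``N + 1`` scales indexed
``i = 0..N``; a continuous time ``t in [0, 1]`` maps to the same
quantities through ``t = i / N``.  The VE form is the package default
because the predictor/corrector updates used for dose prediction are
written in terms of sigma-indexed noise scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import (
    DegenerateTimeError,
    ParameterError,
    RangeError,
    ShapeError,
)

__all__ = [
    "NoiseSchedule",
    "PerturbKernelParams",
    "make_schedule",
    "perturbation_kernel",
    "perturb",
    "score_target",
]

#: Fixed diffusion time horizon.
T_HORIZON = 1.0


@dataclass(frozen=True)
class PerturbKernelParams:
    """Closed-form parameters of the Gaussian perturbation kernel.

    ``p_t(x_t | x_0) = N(mean_coeff * x_0, std^2 I)``.
    """

    mean_coeff: float
    std: float


@dataclass(frozen=True)
class NoiseSchedule:
    """Discretized noise schedule of a VE or VP diffusion.

    Parameters
    ----------
    kind
        ``"ve"`` or ``"vp"``.
    N
        Number of discretization intervals; the schedule holds ``N + 1``
        scales indexed ``0..N``.
    sigma_min, sigma_max
        Smallest/largest noise standard deviation (VE only).  ``sigma_max``
        is the "initial noise scale" of the reverse-time sampler.
    beta_min, beta_max
        Bounds of the linear drift ramp ``beta(t)`` (VP only), on the
        (0, 1) scale after dividing by ``N`` in the discrete picture.
    """

    kind: str
    N: int
    sigma_min: float = 0.01
    sigma_max: float = 0.6
    beta_min: float = 0.1
    beta_max: float = 20.0
    T: float = T_HORIZON
    sigmas: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("ve", "vp"):
            raise ParameterError(f"unknown schedule kind {self.kind!r}")
        if self.N < 2:
            raise ParameterError(f"need at least 2 discretization steps, got N={self.N}")
        if self.kind == "ve":
            if not (0.0 < self.sigma_min < self.sigma_max):
                raise ParameterError(
                    f"require 0 < sigma_min < sigma_max, got "
                    f"({self.sigma_min}, {self.sigma_max})"
                )
            i = np.arange(self.N + 1)
            log_s = np.log(self.sigma_min) + (i / self.N) * (
                np.log(self.sigma_max) - np.log(self.sigma_min)
            )
            sig = np.exp(log_s)
            sig[0] = self.sigma_min
            sig[-1] = self.sigma_max
        else:
            if not (0.0 < self.beta_min < self.beta_max):
                raise ParameterError(
                    f"require 0 < beta_min < beta_max, got "
                    f"({self.beta_min}, {self.beta_max})"
                )
            # marginal std at each grid time; kept for introspection/plots
            t = np.arange(self.N + 1) / self.N
            m = self._vp_mean_coeff(t)
            sig = np.sqrt(np.maximum(1.0 - m**2, 0.0))
        object.__setattr__(self, "sigmas", sig)

    # -- time/index plumbing -------------------------------------------------
    def _check_time(self, t: float) -> float:
        if not (0.0 <= t <= self.T):
            raise RangeError(f"t={t} outside [0, {self.T}]")
        return float(t)

    def time_of_index(self, i: int) -> float:
        if not (0 <= i <= self.N):
            raise RangeError(f"scale index {i} outside 0..{self.N}")
        return i / self.N

    def sigma(self, i: int) -> float:
        """Noise std at discrete scale index ``i`` (VE: sigma_i; VP: marginal std)."""
        if not (0 <= i <= self.N):
            raise RangeError(f"scale index {i} outside 0..{self.N}")
        return float(self.sigmas[i])

    def beta(self, t: float) -> float:
        """Linear VP drift ramp ``beta(t)``; monotone increasing on [0, T]."""
        t = self._check_time(t)
        return self.beta_min + t * (self.beta_max - self.beta_min)

    def _vp_mean_coeff(self, t):
        return np.exp(-0.25 * t**2 * (self.beta_max - self.beta_min) - 0.5 * t * self.beta_min)


def make_schedule(kind: str, N: int, **params) -> NoiseSchedule:
    """Build a validated :class:`NoiseSchedule`.

    VE keywords: ``sigma_min``, ``sigma_max``.  VP keywords: ``beta_min``,
    ``beta_max``.  Raises :class:`~scoredose.exceptions.ParameterError` on
    non-positive or inverted bounds or ``N < 2``.
    """
    return NoiseSchedule(kind=kind.lower(), N=N, **params)


def _resolve_time(schedule: NoiseSchedule, t: Optional[float], i: Optional[int]) -> float:
    if (t is None) == (i is None):
        raise ParameterError("pass exactly one of t= or i=")
    if i is not None:
        return schedule.time_of_index(int(i))
    return schedule._check_time(float(t))


def perturbation_kernel(
    schedule: NoiseSchedule, t: Optional[float] = None, i: Optional[int] = None
) -> PerturbKernelParams:
    """Closed-form mean coefficient and std of ``p_t(x_t | x_0)``.

    VE: ``(1, sigma(t))`` with geometric interpolation between the discrete
    scales.  VP (linear beta): ``(m(t), sqrt(1 - m(t)^2))``.
    """
    tt = _resolve_time(schedule, t, i)
    if schedule.kind == "ve":
        log_s = np.log(schedule.sigma_min) + tt / schedule.T * (
            np.log(schedule.sigma_max) - np.log(schedule.sigma_min)
        )
        return PerturbKernelParams(mean_coeff=1.0, std=float(np.exp(log_s)))
    m = float(schedule._vp_mean_coeff(np.asarray(tt)))
    return PerturbKernelParams(mean_coeff=m, std=float(np.sqrt(max(1.0 - m * m, 0.0))))


def perturb(
    x0: np.ndarray,
    schedule: NoiseSchedule,
    t: Optional[float] = None,
    i: Optional[int] = None,
    z: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sample ``x_t = mean_coeff * x_0 + std * z`` from the perturbation kernel.

    ``z`` is a standard-normal field of the same shape as ``x0``; if omitted
    it is drawn from ``rng`` (which must then be provided — there is no
    global random state in this package).
    """
    x0 = np.asarray(x0)
    kp = perturbation_kernel(schedule, t=t, i=i)
    if z is None:
        if rng is None:
            raise ParameterError("either z or rng must be provided")
        z = rng.standard_normal(x0.shape)
    else:
        z = np.asarray(z)
        if z.shape != x0.shape:
            raise ShapeError(f"z shape {z.shape} != x0 shape {x0.shape}")
    return kp.mean_coeff * x0 + kp.std * z


def score_target(
    x0: np.ndarray,
    xt: np.ndarray,
    schedule: NoiseSchedule,
    t: Optional[float] = None,
    i: Optional[int] = None,
) -> np.ndarray:
    """Analytic score of the perturbation kernel, the denoising-score-matching target.

    Returns ``grad_{x_t} log p_t(x_t | x_0) = -(x_t - mean_coeff * x_0) / std^2``,
    the gradient of the Gaussian kernel centered on ``x_0``.
    """
    x0 = np.asarray(x0)
    xt = np.asarray(xt)
    if x0.shape != xt.shape:
        raise ShapeError(f"x0 shape {x0.shape} != xt shape {xt.shape}")
    kp = perturbation_kernel(schedule, t=t, i=i)
    if kp.std == 0.0:
        raise DegenerateTimeError("perturbation kernel has zero variance at t=0 (VP)")
    return -(xt - kp.mean_coeff * x0) / (kp.std**2)
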
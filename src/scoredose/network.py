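"""Time-conditioned U-Net score estimator s_Theta(x, sigma).

The network consumes a channel stack — channel 0 is the noised target
dose, the remaining channels carry clean conditioning (planned dose and
optionally CT) — and returns the estimated score of the target channel
at the given noise scale.  The architecture is the standard score-model
U-Net: residual blocks with group normalization and SiLU, factor-2
down/upsampling, concatenation skip connections, and a sinusoidal
embedding of ``log sigma`` injected into every residual block as a
per-channel scale/shift (FiLM).  The final convolution is zero-initialized
so an untrained model outputs the zero score.

Spatial sizes that are not divisible by ``2**(depth-1)`` are
reflection-padded up to the next multiple and the output is cropped back.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .autodiff import (Tensor, avg_pool2, concat, conv2d, crop2d, group_norm,
                       transpose_nchw, upsample2)
from .exceptions import ConfigError, ShapeError

__all__ = ["ScoreModelConfig", "ScoreUNet", "build_score_model", "EMA"]


@dataclass(frozen=True)
class ScoreModelConfig:
    """Architecture hyperparameters of the score U-Net.

    ``in_channels`` counts the noised target plus conditioning channels, so
    it is at least 2 (dose-only conditioning) and 3 with CT.  ``base_width``
    is the first-layer feature count — 128 by default, with 64 as the
    lighter alternative.  ``width_multipliers`` give the per-level channel
    multiplier and implicitly the encoder depth.
    """

    in_channels: int = 2
    base_width: int = 128
    depth: int = 4
    width_multipliers: Tuple[int, ...] = (1, 2, 2, 4)
    kernel_size: int = 3
    time_embed_dim: Optional[int] = None
    normalization: str = "group"  # "group" | "none"
    activation: str = "silu"  # "silu" | "relu"
    num_groups: int = 8

    def __post_init__(self):
        if self.in_channels < 2:
            raise ConfigError(
                f"in_channels must be >= 2 (target + conditioning), got {self.in_channels}"
            )
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ConfigError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.base_width < 1:
            raise ConfigError("base_width must be positive")
        if len(self.width_multipliers) != self.depth:
            raise ConfigError(
                f"width_multipliers length {len(self.width_multipliers)} != depth {self.depth}"
            )
        if self.normalization not in ("group", "none"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.activation not in ("silu", "relu"):
            raise ConfigError(f"unknown activation {self.activation!r}")

    @property
    def embed_dim(self) -> int:
        return self.time_embed_dim if self.time_embed_dim is not None else 4 * min(
            self.base_width, 32
        )


def _act(x: Tensor, kind: str) -> Tensor:
    return x.silu() if kind == "silu" else x.relu()


class ScoreUNet:
    """Score network with explicit, seeded parameter initialization.

    Parameters are plain :class:`~scoredose.autodiff.Tensor` leaves stored
    in an ordered dict; two models built from the same config and seed are
    bit-identical.
    """

    def __init__(self, config: ScoreModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.seed = int(seed)
        self.dtype = dtype
        self.params: Dict[str, Tensor] = {}
        self._rng = np.random.default_rng(self.seed)
        self._build()

    # -- parameter construction ----------------------------------------------
    def _param(self, name: str, shape, scale: Optional[float] = None) -> Tensor:
        if scale is None:
            data = np.zeros(shape, dtype=self.dtype)
        else:
            data = (self._rng.standard_normal(shape) * scale).astype(self.dtype)
        t = Tensor(data, requires_grad=True)
        self.params[name] = t
        return t

    def _conv_params(self, name: str, cin: int, cout: int, k: Optional[int] = None,
                     zero: bool = False):
        k = self.config.kernel_size if k is None else k
        scale = None if zero else np.sqrt(2.0 / (cin * k * k))
        self._param(f"{name}.w", (k, k, cin, cout), scale)
        self._param(f"{name}.b", (cout,), None)

    def _linear_params(self, name: str, din: int, dout: int, zero: bool = False):
        scale = None if zero else np.sqrt(1.0 / din)
        self._param(f"{name}.w", (din, dout), scale)
        self._param(f"{name}.b", (dout,), None)

    def _norm_params(self, name: str, c: int):
        if self.config.normalization == "group":
            self.params[f"{name}.g"] = Tensor(np.ones(c, dtype=self.dtype), requires_grad=True)
            self._param(f"{name}.s", (c,), None)  # shift, zero init

    def _build(self):
        cfg = self.config
        widths = [cfg.base_width * m for m in cfg.width_multipliers]
        E = cfg.embed_dim
        self._linear_params("temb.l1", E, E)
        self._linear_params("temb.l2", E, E)
        self._conv_params("stem", cfg.in_channels, cfg.base_width)

        def res_params(tag: str, cin: int, cout: int):
            self._norm_params(f"{tag}.n1", cin)
            self._conv_params(f"{tag}.c1", cin, cout)
            self._linear_params(f"{tag}.ta", E, cout, zero=True)
            self._linear_params(f"{tag}.tb", E, cout, zero=True)
            self._norm_params(f"{tag}.n2", cout)
            self._conv_params(f"{tag}.c2", cout, cout)
            if cin != cout:
                self._conv_params(f"{tag}.skip", cin, cout, k=1)

        prev = cfg.base_width
        for l, w in enumerate(widths):
            res_params(f"down{l}", prev, w)
            prev = w
        res_params("mid", prev, prev)
        for l in range(cfg.depth - 2, -1, -1):
            res_params(f"up{l}", widths[l + 1] + widths[l], widths[l])
        self._norm_params("head.n", widths[0])
        self._conv_params("head.c", widths[0], 1, zero=True)
        self._widths = widths

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def parameters(self) -> List[Tensor]:
        return list(self.params.values())

    # -- forward pieces ------------------------------------------------------
    def _norm(self, x: Tensor, name: str) -> Tensor:
        if self.config.normalization == "none":
            return x
        C = x.shape[3]
        G = int(np.gcd(self.config.num_groups, C))
        return group_norm(x, self.params[f"{name}.g"], self.params[f"{name}.s"], G)

    def _linear(self, x: Tensor, name: str) -> Tensor:
        return x @ self.params[f"{name}.w"] + self.params[f"{name}.b"]

    def _conv(self, x: Tensor, name: str) -> Tensor:
        return conv2d(x, self.params[f"{name}.w"], self.params[f"{name}.b"])

    def _time_embedding(self, sigma: np.ndarray) -> Tensor:
        E = self.config.embed_dim
        half = E // 2
        freqs = np.exp(np.linspace(0.0, np.log(100.0), half)).astype(self.dtype)
        s = np.log(sigma).astype(self.dtype)[:, None]  # (B, 1)
        ang = s * freqs[None, :]
        feats = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
        if feats.shape[1] < E:  # odd embed dim
            feats = np.pad(feats, ((0, 0), (0, E - feats.shape[1])))
        emb = _act(self._linear(Tensor(feats), "temb.l1"), self.config.activation)
        return self._linear(emb, "temb.l2")

    def _resblock(self, x: Tensor, emb: Tensor, tag: str) -> Tensor:
        cfg = self.config
        h = self._conv(_act(self._norm(x, f"{tag}.n1"), cfg.activation), f"{tag}.c1")
        B = x.shape[0]
        cout = h.shape[3]
        a = self._linear(emb, f"{tag}.ta").reshape(B, 1, 1, cout)
        b = self._linear(emb, f"{tag}.tb").reshape(B, 1, 1, cout)
        h = h * (a + 1.0) + b
        h = self._conv(_act(self._norm(h, f"{tag}.n2"), cfg.activation), f"{tag}.c2")
        if f"{tag}.skip.w" in self.params:
            x = self._conv(x, f"{tag}.skip")
        return x + h

    # -- public API ----------------------------------------------------------
    def forward(self, x_stack: np.ndarray, sigma: Union[float, np.ndarray]) -> Tensor:
        """Estimated score of channel 0; returns a differentiable Tensor.

        ``x_stack``: (B, in_channels, H, W) or (in_channels, H, W).
        ``sigma``: scalar noise std or per-sample array of shape (B,).
        """
        x_stack = np.asarray(x_stack, dtype=self.dtype)
        squeeze = x_stack.ndim == 3
        if squeeze:
            x_stack = x_stack[None]
        if x_stack.ndim != 4 or x_stack.shape[1] != self.config.in_channels:
            raise ShapeError(
                f"expected (B, {self.config.in_channels}, H, W) stack, got {x_stack.shape}"
            )
        B, _, H, W = x_stack.shape
        sigma = np.broadcast_to(np.asarray(sigma, dtype=np.float64), (B,)).copy()
        if np.any(sigma <= 0):
            raise ShapeError("sigma must be positive")

        m = 2 ** (self.config.depth - 1)
        Hp = -(-H // m) * m
        Wp = -(-W // m) * m
        x_nhwc = np.ascontiguousarray(x_stack.transpose(0, 2, 3, 1))
        if (Hp, Wp) != (H, W):
            x_nhwc = np.pad(
                x_nhwc, ((0, 0), (0, Hp - H), (0, Wp - W), (0, 0)), mode="reflect"
            )

        emb = self._time_embedding(sigma)
        h = self._conv(Tensor(x_nhwc), "stem")
        skips = []
        for l in range(self.config.depth):
            h = self._resblock(h, emb, f"down{l}")
            skips.append(h)
            if l < self.config.depth - 1:
                h = avg_pool2(h)
        h = self._resblock(h, emb, "mid")
        for l in range(self.config.depth - 2, -1, -1):
            h = upsample2(h)
            h = concat([h, skips[l]], axis=3)
            h = self._resblock(h, emb, f"up{l}")
        out = self._conv(_act(self._norm(h, "head.n"), self.config.activation), "head.c")
        if (Hp, Wp) != (H, W):
            out = crop2d(out, H, W)
        out = transpose_nchw(out)
        if squeeze:
            out = out.reshape(1, H, W)
        return out

    def __call__(self, x_stack: np.ndarray, sigma) -> np.ndarray:
        """Inference forward pass; returns a plain ndarray."""
        return self.forward(x_stack, sigma).data

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        missing = set(self.params) ^ set(state)
        if missing:
            raise ConfigError(f"state dict keys do not match model: {sorted(missing)}")
        for k, p in self.params.items():
            arr = np.asarray(state[k], dtype=self.dtype)
            if arr.shape != p.data.shape:
                raise ConfigError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def save(self, path, extra: Optional[dict] = None) -> None:
        """Save weights + config + seed (and optional metadata) to one archive."""
        meta = {"config": asdict(self.config), "seed": self.seed}
        if extra:
            meta["extra"] = extra
        buf = {k: v for k, v in self.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta, sort_keys=True).encode(),
                                              dtype=np.uint8), **buf)

    @classmethod
    def load(cls, path) -> "ScoreUNet":
        try:
            with np.load(path) as zf:
                meta = json.loads(bytes(zf["__meta__"]).decode())
                state = {k: zf[k] for k in zf.files if k != "__meta__"}
        except (zipfile.BadZipFile, KeyError, ValueError, json.JSONDecodeError,
                OSError) as e:
            raise ConfigError(f"corrupted or unreadable checkpoint {path}: {e}") from e
        cfg_d = meta["config"]
        cfg_d["width_multipliers"] = tuple(cfg_d["width_multipliers"])
        model = cls(ScoreModelConfig(**cfg_d), seed=meta["seed"])
        model.load_state_dict(state)
        model.loaded_extra = meta.get("extra")
        return model


def build_score_model(config: ScoreModelConfig, seed: int = 0) -> ScoreUNet:
    """Construct a seeded :class:`ScoreUNet` from a validated config."""
    return ScoreUNet(config, seed=seed)


class EMA:
    """Exponential moving average of model parameters.

    Tracks ``shadow = decay * shadow + (1 - decay) * param`` after each
    optimizer step; ``copy_to`` installs the averaged weights for
    evaluation/sampling.
    """

    def __init__(self, model: ScoreUNet, decay: float = 0.999):
        if not (0.0 <= decay < 1.0):
            raise ConfigError(f"ema decay must be in [0, 1), got {decay}")
        self.decay = decay
        self.n_updates = 0
        self.shadow = {k: p.data.copy() for k, p in model.params.items()}

    def update(self, model: ScoreUNet) -> None:
        # warmup-corrected decay so short runs are not dominated by the init
        self.n_updates += 1
        d = min(self.decay, (1.0 + self.n_updates) / (10.0 + self.n_updates))
        for k, p in model.params.items():
            self.shadow[k] *= d
            self.shadow[k] += (1.0 - d) * p.data

    def copy_to(self, model: ScoreUNet) -> None:
        model.load_state_dict(self.shadow)
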
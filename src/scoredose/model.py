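"""Model/Results interface tying the pipeline together.

:class:`DoseDiffusionModel` is constructed from paired cases (a
:class:`~scoredose.synthetic.Dataset` or explicit train/validation
lists) together with a noise schedule and network architecture;
:meth:`DoseDiffusionModel.fit` runs denoising score-matching and returns
a :class:`DoseDiffusionResults` carrying the trained network, the loss
trace, and the evaluation/sampling/plotting methods.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .exceptions import ConfigError, DataError
from .network import ScoreModelConfig, ScoreUNet, build_score_model
from .sampling import SamplerConfig, sample as _sample
from .sde import NoiseSchedule, make_schedule
from .synthetic import Dataset, PairedCase
from .training import TrainConfig, train as _train

__all__ = ["DoseDiffusionModel", "DoseDiffusionResults"]


class DoseDiffusionModel:
    """Conditional score-based diffusion model of delivered dose.

    Parameters
    ----------
    train_cases, val_cases
        Paired phantom (or user) cases; validation may be empty.
    schedule
        Noise schedule; defaults to the VE schedule with 1500 scales and
        ``sigma_max = 0.6``.
    network
        Architecture config; ``in_channels`` must be 2 (``with_ct=False``)
        or 3 (``with_ct=True``).
    with_ct
        Whether the CT channel is appended to the conditioning stack.
    """

    def __init__(
        self,
        train_cases: Sequence[PairedCase],
        val_cases: Sequence[PairedCase] = (),
        schedule: Optional[NoiseSchedule] = None,
        network: Optional[ScoreModelConfig] = None,
        with_ct: bool = False,
        seed: int = 0,
    ):
        if len(train_cases) == 0:
            raise DataError("no training cases")
        self.train_cases = list(train_cases)
        self.val_cases = list(val_cases)
        self.schedule = schedule or make_schedule("ve", 1500, sigma_min=0.01, sigma_max=0.6)
        self.with_ct = bool(with_ct)
        want_ch = 3 if with_ct else 2
        self.network_config = network or ScoreModelConfig(in_channels=want_ch)
        if self.network_config.in_channels != want_ch:
            raise ConfigError(
                f"network in_channels={self.network_config.in_channels} inconsistent "
                f"with with_ct={with_ct} (expected {want_ch})"
            )
        self.seed = int(seed)

    @classmethod
    def from_dataset(
        cls,
        dataset: Dataset,
        schedule: Optional[NoiseSchedule] = None,
        network: Optional[ScoreModelConfig] = None,
        with_ct: bool = False,
        seed: int = 0,
    ) -> "DoseDiffusionModel":
        """Build from a synthetic :class:`Dataset`, using its test split for validation."""
        return cls(dataset.train, dataset.test, schedule=schedule, network=network,
                   with_ct=with_ct, seed=seed)

    def fit(self, train_config: Optional[TrainConfig] = None,
            verbose: bool = False) -> "DoseDiffusionResults":
        """Train the score network and return the fitted results object."""
        cfg = train_config or TrainConfig(seed=self.seed)
        net = build_score_model(self.network_config, seed=self.seed)
        out = _train(net, self.train_cases, self.val_cases, cfg, self.schedule,
                     with_ct=self.with_ct, verbose=verbose)
        return DoseDiffusionResults(self, out.ema_model(), out.trace, cfg,
                                    raw_network=out.model)


class DoseDiffusionResults:
    """Fitted diffusion model: trained weights, loss trace, and inference."""

    def __init__(
        self,
        model: DoseDiffusionModel,
        network: ScoreUNet,
        loss_trace: dict,
        train_config: TrainConfig,
        raw_network: Optional[ScoreUNet] = None,
    ):
        self.model = model
        self.network = network  # EMA weights when enabled
        self.raw_network = raw_network
        self.loss_trace = loss_trace
        self.train_config = train_config

    # -- inference -----------------------------------------------------------
    def sample(
        self,
        cases: Sequence[PairedCase],
        sampler_config: Optional[SamplerConfig] = None,
        seed: Optional[int] = None,
    ) -> np.ndarray:
        """Predicted dose fields (B, H, W) for the given cases' conditioning."""
        cfg = sampler_config or SamplerConfig(N_steps=self.model.schedule.N,
                                              seed=self.model.seed)
        if seed is not None:
            cfg = SamplerConfig(**{**asdict_cfg(cfg), "seed": int(seed)})
        cond = np.stack([c.stack(with_ct=self.model.with_ct) for c in cases])
        return _sample(self.network, cond, cfg, self.model.schedule)

    def evaluate(
        self,
        cases: Sequence[PairedCase],
        sampler_config: Optional[SamplerConfig] = None,
        seed: Optional[int] = None,
        pdose: Optional[np.ndarray] = None,
    ) -> pd.DataFrame:
        """Per-case SSIM/RMSE%/MAE% of the prediction against measured dose.

        Also includes the planned-vs-measured baseline columns so the
        improvement over simply copying the planned dose is visible.
        """
        if len(cases) == 0:
            raise DataError("no cases to evaluate")
        if pdose is None:
            pdose = self.sample(cases, sampler_config, seed=seed)
        records = []
        base = []
        for c, p in zip(cases, pdose):
            records.append(_metrics.compute_metrics(p, c.mdose, c.case_id, c.site_label))
            base.append(_metrics.compute_metrics(c.rtdose, c.mdose, c.case_id,
                                                 c.site_label))
        frame = _metrics.records_to_frame(records)
        bframe = _metrics.records_to_frame(base)
        frame["baseline_mae_pct"] = bframe["mae_pct"].to_numpy()
        frame["baseline_rmse_pct"] = bframe["rmse_pct"].to_numpy()
        frame["baseline_ssim"] = bframe["ssim"].to_numpy()
        return frame

    def site_summary(self, frame: pd.DataFrame) -> dict:
        """Per-site quartile/outlier summary of an :meth:`evaluate` frame."""
        records = [
            _metrics.MetricsRecord(r.case_id, r.ssim, r.rmse_pct, r.mae_pct, r.site_label)
            for r in frame.itertuples(index=False)
        ]
        return _metrics.summarize_by_site(records)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        m = self.model
        sch = m.schedule
        lines = [
            "Dose diffusion model results",
            "=" * 60,
            f"{'Schedule':28s} {sch.kind.upper()} (N={sch.N}, "
            + (f"sigma in [{sch.sigma_min:g}, {sch.sigma_max:g}])" if sch.kind == "ve"
               else f"beta in [{sch.beta_min:g}, {sch.beta_max:g}])"),
            f"{'Conditioning channels':28s} "
            + ("RTDose + CT" if m.with_ct else "RTDose"),
            f"{'Network parameters':28s} {self.network.n_params:,d}",
            f"{'Base width / depth':28s} {m.network_config.base_width} / "
            f"{m.network_config.depth}",
            f"{'Training cases':28s} {len(m.train_cases)}",
            f"{'Validation cases':28s} {len(m.val_cases)}",
            f"{'Epochs':28s} {len(self.loss_trace['train'])}",
        ]
        if self.loss_trace["train"]:
            lines.append(f"{'Final train DSM loss':28s} {self.loss_trace['train'][-1]:.4f}")
        if self.loss_trace["val"]:
            lines.append(
                f"{'Val DSM loss (first->last)':28s} "
                f"{self.loss_trace['val'][0]:.4f} -> {self.loss_trace['val'][-1]:.4f}"
            )
        lines.append(f"{'EMA decay':28s} {self.train_config.ema_decay}")
        lines.append("=" * 60)
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------------
    def plot_profiles(self, case: PairedCase, pdose: np.ndarray, row_index: int,
                      ax=None):
        """Overlay measured / predicted / planned dose along one image row."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, fld in (("MDose", case.mdose), ("PDose", pdose),
                          ("RTDose", case.rtdose)):
            pos, vals = _metrics.line_profile(fld, row_index)
            ax.plot(pos, vals, label=name)
        ax.set_xlabel("position [px]")
        ax.set_ylabel("normalized dose")
        ax.set_title(f"{case.case_id} row {row_index}")
        ax.legend()
        return ax

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: weights + architecture + schedule + training metadata."""
        sch = self.model.schedule
        extra = {
            "schedule": {"kind": sch.kind, "N": sch.N, "sigma_min": sch.sigma_min,
                         "sigma_max": sch.sigma_max, "beta_min": sch.beta_min,
                         "beta_max": sch.beta_max},
            "with_ct": self.model.with_ct,
            "train_config": asdict(self.train_config),
            "loss_trace": self.loss_trace,
        }
        self.network.save(path, extra=extra)

    @classmethod
    def load(cls, path, train_cases: Sequence[PairedCase] = (),
             val_cases: Sequence[PairedCase] = ()) -> "DoseDiffusionResults":
        """Restore a fitted results object (cases optional, for re-evaluation)."""
        net = ScoreUNet.load(path)
        extra = net.loaded_extra or {}
        sch_d = extra.get("schedule", {})
        schedule = make_schedule(sch_d.get("kind", "ve"), sch_d.get("N", 1500),
                                 **{k: sch_d[k] for k in
                                    ("sigma_min", "sigma_max", "beta_min", "beta_max")
                                    if k in sch_d})
        tc = extra.get("train_config")
        train_config = TrainConfig(**tc) if tc else TrainConfig()
        model = DoseDiffusionModel(
            list(train_cases) or [_dummy_case(net.config)], list(val_cases),
            schedule=schedule, network=net.config,
            with_ct=extra.get("with_ct", net.config.in_channels == 3), seed=net.seed,
        )
        if not train_cases:
            model.train_cases = []
        return cls(model, net, extra.get("loss_trace", {"train": [], "val": []}),
                   train_config)


def asdict_cfg(cfg) -> dict:
    d = asdict(cfg)
    if d.get("clip") is not None:
        d["clip"] = tuple(d["clip"])
    return d


def _dummy_case(cfg: ScoreModelConfig) -> PairedCase:
    z = np.zeros((4, 4))
    return PairedCase("_placeholder", "H&N", z, z, z)
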
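"""Persistence: datasets, predictions, configs, run logs, NIfTI export.

Datasets are written as a directory holding one ``.npy`` array per
channel (stacked over cases) plus a ``manifest.json``; the layout is
deliberately plain so that reruns with the same seed are byte-identical.
Per-case NIfTI export (one ``.nii`` per case-channel, spacing in the
affine) is available for interoperability with medical-image viewers.
Configuration files are YAML mirroring the dataclass configs and are
validated on load; every run can write back a frozen resolved copy.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from .exceptions import ConfigError, DataError
from .network import ScoreModelConfig
from .sampling import SamplerConfig
from .sde import NoiseSchedule, make_schedule
from .synthetic import Dataset, ErrorModel, PairedCase
from .training import TrainConfig

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_pdose",
    "load_pdose",
    "export_case_nifti",
    "load_nifti",
    "RunConfig",
    "load_run_config",
    "write_run_log",
]

_CHANNELS = ("mdose", "rtdose", "ct")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def save_dataset(dataset: Dataset, path) -> Path:
    """Write a dataset directory: per-channel arrays + manifest.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for split, cases in (("train", dataset.train), ("test", dataset.test)):
        for ch in _CHANNELS:
            arr = np.stack([getattr(c, ch) for c in cases]).astype(np.float32)
            np.save(path / f"{split}_{ch}.npy", arr)
    _dump_json(dataset.manifest, path / "manifest.json")
    return path


def load_dataset(path) -> Dataset:
    """Read back a dataset directory written by :func:`save_dataset`."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise DataError(f"no manifest.json under {path}")
    manifest = json.loads(mpath.read_text())
    splits: Dict[str, List[PairedCase]] = {}
    for split in ("train", "test"):
        arrs = {ch: np.load(path / f"{split}_{ch}.npy") for ch in _CHANNELS}
        ids = manifest[f"{split}_ids"]
        cases = []
        for k, cid in enumerate(ids):
            cases.append(
                PairedCase(
                    case_id=cid,
                    site_label=manifest["sites"][cid],
                    ct=arrs["ct"][k],
                    rtdose=arrs["rtdose"][k],
                    mdose=arrs["mdose"][k],
                    seed=manifest["case_seeds"].get(cid),
                )
            )
        splits[split] = cases
    return Dataset(train=splits["train"], test=splits["test"], manifest=manifest)


def save_pdose(pdose: np.ndarray, case_ids: Sequence[str], path) -> Path:
    """Write predicted dose fields plus the case-id index."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "pdose.npy", np.asarray(pdose, dtype=np.float32))
    _dump_json({"case_ids": list(case_ids)}, path / "pdose_index.json")
    return path


def load_pdose(path):
    path = Path(path)
    f = path / "pdose.npy"
    if not f.exists():
        raise DataError(f"no predictions under {path}")
    idx = json.loads((path / "pdose_index.json").read_text())
    return np.load(f), idx["case_ids"]


def export_case_nifti(case: PairedCase, out_dir, pdose: Optional[np.ndarray] = None) -> List[Path]:
    """Write each channel of a case (and optionally its prediction) as .nii."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([case.spacing[0], case.spacing[1], 1.0, 1.0])
    written = []
    fields = {ch: getattr(case, ch) for ch in _CHANNELS}
    if pdose is not None:
        fields["pdose"] = pdose
    for name, arr in fields.items():
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32)[..., None], affine)
        p = out_dir / f"{case.case_id}_{name}.nii"
        nib.save(img, p)
        written.append(p)
    return written


def load_nifti(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float32).squeeze(-1)


class RunConfig:
    """Resolved configuration of one pipeline run (schedule/model/train/sampler/data).

    Built from a YAML mapping with sections ``schedule``, ``model``,
    ``train``, ``sampler``, ``data``, ``output`` and a global ``seed``;
    unknown keys or inconsistent channel counts raise
    :class:`~scoredose.exceptions.ConfigError`.
    """

    SECTIONS = ("schedule", "model", "train", "sampler", "data", "output", "seed")

    def __init__(self, raw: dict):
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        unknown = set(raw) - set(self.SECTIONS)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        self.seed = int(raw.get("seed", 0))
        sch = dict(raw.get("schedule", {}))
        kind = sch.pop("kind", "ve")
        N = int(sch.pop("N", 1500))
        try:
            self.schedule: NoiseSchedule = make_schedule(kind, N, **sch)
            model_kw = dict(raw.get("model", {}))
            if "width_multipliers" in model_kw:
                model_kw["width_multipliers"] = tuple(model_kw["width_multipliers"])
            self.model = ScoreModelConfig(**model_kw)
            train_kw = dict(raw.get("train", {}))
            train_kw.setdefault("seed", self.seed)
            self.train = TrainConfig(**train_kw)
            sampler_kw = dict(raw.get("sampler", {}))
            sampler_kw.setdefault("N_steps", N)
            sampler_kw.setdefault("seed", self.seed)
            if "clip" in sampler_kw and sampler_kw["clip"] is not None:
                sampler_kw["clip"] = tuple(sampler_kw["clip"])
            self.sampler = SamplerConfig(**sampler_kw)
        except TypeError as e:
            raise ConfigError(f"bad config field: {e}") from e
        self.data = dict(raw.get("data", {}))
        self.output = raw.get("output", "runs")
        if self.sampler.N_steps != self.schedule.N:
            raise ConfigError("sampler.N_steps must equal schedule.N")
        self.with_ct = self.model.in_channels == 3 and self.data.get("with_ct", True)

    def data_params(self) -> dict:
        d = self.data
        err_kw = dict(d.get("error", {}))
        if "shift" in err_kw:
            err_kw["shift"] = tuple(err_kw["shift"])
        return dict(
            n_cases=int(d.get("n_cases", 600)),
            split_ratio=float(d.get("split_ratio", 0.8)),
            grid_size=tuple(d.get("grid_size", (32, 32))),
            error=ErrorModel(**err_kw),
            seed=int(d.get("seed", self.seed)),
        )

    def resolved(self) -> dict:
        sch = self.schedule
        return {
            "seed": self.seed,
            "schedule": {"kind": sch.kind, "N": sch.N, "sigma_min": sch.sigma_min,
                         "sigma_max": sch.sigma_max, "beta_min": sch.beta_min,
                         "beta_max": sch.beta_max},
            "model": asdict(self.model),
            "train": asdict(self.train),
            "sampler": {**asdict(self.sampler),
                        "clip": list(self.sampler.clip) if self.sampler.clip else None},
            "data": self.data,
            "output": str(self.output),
        }

    def freeze(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        p = out_dir / "resolved_config.json"
        _dump_json(self.resolved(), p)
        return p


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(raw)


def write_run_log(out_dir, seed: int, note: str = "") -> Path:
    """Plain-text run log with seeds and library versions."""
    import scipy
    import skimage

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [
        f"seed: {seed}",
        f"python: {sys.version.split()[0]}",
        f"numpy: {np.__version__}",
        f"scipy: {scipy.__version__}",
        f"scikit-image: {skimage.__version__}",
    ]
    if note:
        lines.append(f"note: {note}")
    p = out_dir / "run.log"
    p.write_text("\n".join(lines) + "\n")
    return p
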
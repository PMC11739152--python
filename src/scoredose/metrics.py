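"""Dose-agreement metrics: SSIM, RMSE(%), MAE(%), line profiles, per-site boxes.

All metrics operate on the per-case normalized dose scale (case RTDose
maximum == 1); RMSE and MAE are reported in percent of that scale.  SSIM
uses the standard Gaussian-window formulation (11-pixel window,
``sigma = 1.5``, ``K1 = 0.01``, ``K2 = 0.03``, ``data_range = 1``) over
the whole grid by default; a body-mask-restricted variant is available
via ``mask``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .exceptions import DataError, ParameterError, RangeError, ShapeError

__all__ = [
    "MetricsRecord",
    "ssim",
    "rmse_pct",
    "mae_pct",
    "line_profile",
    "summarize_by_site",
    "compute_metrics",
    "records_to_frame",
]


@dataclass(frozen=True)
class MetricsRecord:
    """Per-case agreement between predicted and measured dose."""

    case_id: str
    ssim: float
    rmse_pct: float
    mae_pct: float
    site_label: str


def _check_pair(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"field shapes differ: {a.shape} vs {b.shape}")
    return a, b


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    window: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float = 1.0,
    gaussian_sigma: float = 1.5,
) -> float:
    """Mean local structural similarity over sliding Gaussian windows.

    Constants ``C1 = (k1 * L)^2`` and ``C2 = (k2 * L)^2`` with
    ``L = data_range``; symmetric in its arguments.
    """
    a, b = _check_pair(a, b)
    if data_range <= 0:
        raise ParameterError("data_range must be positive")
    win = min(window, min(a.shape) - (1 - min(a.shape) % 2))  # odd, <= image size
    return float(
        structural_similarity(
            a,
            b,
            win_size=win,
            gaussian_weights=True,
            sigma=gaussian_sigma,
            K1=k1,
            K2=k2,
            data_range=data_range,
            use_sample_covariance=False,
        )
    )


def rmse_pct(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error in percent of the normalized dose scale."""
    a, b = _check_pair(a, b)
    return float(100.0 * np.sqrt(np.mean((a - b) ** 2)))


def mae_pct(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute error in percent of the normalized dose scale."""
    a, b = _check_pair(a, b)
    return float(100.0 * np.mean(np.abs(a - b)))


def line_profile(field: np.ndarray, row_index: int) -> Tuple[np.ndarray, np.ndarray]:
    """Ordered ``(position, dose)`` samples along one image row."""
    field = np.asarray(field)
    if not (0 <= row_index < field.shape[0]):
        raise RangeError(f"row {row_index} outside 0..{field.shape[0] - 1}")
    return np.arange(field.shape[1]), field[row_index].copy()


def compute_metrics(
    pred: np.ndarray,
    ref: np.ndarray,
    case_id: str = "",
    site_label: str = "",
    mask: Optional[np.ndarray] = None,
    **ssim_kwargs,
) -> MetricsRecord:
    """SSIM/RMSE/MAE between a predicted and a reference dose field.

    With ``mask``, RMSE/MAE are restricted to the masked pixels and SSIM
    is computed on fields zeroed outside the mask.
    """
    pred, ref = _check_pair(pred, ref)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != pred.shape:
            raise ShapeError("mask shape mismatch")
        s = ssim(np.where(mask, pred, 0.0), np.where(mask, ref, 0.0), **ssim_kwargs)
        r = float(100.0 * np.sqrt(np.mean((pred[mask] - ref[mask]) ** 2)))
        m = float(100.0 * np.mean(np.abs(pred[mask] - ref[mask])))
    else:
        s = ssim(pred, ref, **ssim_kwargs)
        r = rmse_pct(pred, ref)
        m = mae_pct(pred, ref)
    return MetricsRecord(case_id=case_id, ssim=s, rmse_pct=r, mae_pct=m,
                         site_label=site_label)


def records_to_frame(records: Sequence[MetricsRecord]) -> pd.DataFrame:
    if len(records) == 0:
        raise DataError("no metric records")
    return pd.DataFrame([asdict(r) for r in records])


def _box_stats(values: np.ndarray) -> Dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = values[(values < lo) | (values > hi)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "outliers": [float(v) for v in outliers],
        "n": int(values.size),
    }


def summarize_by_site(records: Sequence[MetricsRecord]) -> Dict[str, Dict[str, Dict]]:
    """Per-site box statistics (median, Q1, Q3, IQR, 1.5*IQR outliers) per metric.

    Quartiles use linear interpolation; outliers are flagged outside
    ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``.
    """
    if len(records) == 0:
        raise DataError("no metric records to summarize")
    frame = records_to_frame(records)
    out: Dict[str, Dict[str, Dict]] = {}
    for site, grp in frame.groupby("site_label"):
        out[str(site)] = {
            metric: _box_stats(grp[metric].to_numpy(dtype=float))
            for metric in ("ssim", "rmse_pct", "mae_pct")
        }
    return out
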
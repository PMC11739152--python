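"""Synthetic paired-phantom generator.

Clinical training data for delivered-dose prediction (planning-system dose
plus the dose reconstructed from delivery measurements) is not publicly
available, so this module fabricates aligned ``(CT, RTDose, MDose)``
triplets with a *known* planned-to-delivered transform:

* **CT** — an elliptical body on empty background with a few internal
  ellipses of distinct intensity (organ stand-ins), on ``[0, 1]``.
* **RTDose** — a sum of anisotropic Gaussian kernels centred on target
  points inside the body, zeroed outside the body and normalized to a
  maximum of exactly 1 (the per-case dose normalization used throughout
  the package).
* **MDose** — ``clip(calib ⊙ shift(blur(RTDose)) + noise, 0, ∞)``: a
  Gaussian blur (finite detector resolution), a sub-pixel rigid shift
  (setup/positioning error), a smooth multiplicative calibration field
  (output/response drift), and small additive Gaussian noise.  The blur,
  shift, and calibration field are deterministic properties of the error
  model — the same for every case — so a conditional model can learn
  them; only the additive noise is per-case random.

Cases carry an anatomical-site label (H&N / chest / abdomen) used purely
for stratified splitting and per-site reporting, mirroring how clinical
cohorts are grouped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError

__all__ = [
    "DoseVolume",
    "PhantomSpec",
    "ErrorModel",
    "PairedCase",
    "Dataset",
    "make_case",
    "make_dataset",
    "SITES",
]

SITES = ("H&N", "chest", "abdomen")


@dataclass(frozen=True)
class DoseVolume:
    """A scalar dose (or CT) field with grid-spacing metadata in mm."""

    data: np.ndarray
    spacing: Tuple[float, float] = (1.0, 1.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one phantom family.

    ``body`` is ``(cy, cx, ay, ax)`` as fractions of the grid — centre and
    semi-axes of the body ellipse.  ``target_centers`` may pin the dose
    target positions (pixel coordinates); by default they are drawn
    randomly inside the body.
    """

    grid_size: Tuple[int, int] = (32, 32)
    body: Tuple[float, float, float, float] = (0.5, 0.5, 0.42, 0.45)
    n_structures: int = 3
    n_targets: int = 2
    site_label: str = "H&N"
    target_centers: Optional[Tuple[Tuple[float, float], ...]] = None

    def __post_init__(self):
        cy, cx, ay, ax = self.body
        if not (0 < ay <= 0.5 and 0 < ax <= 0.5 and 0 <= cy <= 1 and 0 <= cx <= 1):
            raise ParameterError(f"body ellipse {self.body} does not fit inside the grid")
        if self.n_targets < 1:
            raise ParameterError("need at least one dose target")
        if self.site_label not in SITES:
            raise ParameterError(f"site_label must be one of {SITES}")


@dataclass(frozen=True)
class ErrorModel:
    """The planned-to-delivered discrepancy applied to RTDose to get MDose.

    Units: ``blur_sigma`` and ``shift`` in pixels; ``calib_amplitude`` is
    the peak fractional deviation of the multiplicative calibration field
    (must stay below 0.2); ``calib_period`` its spatial period in pixels;
    ``noise_sd`` the additive noise std on the normalized dose scale.
    """

    blur_sigma: float = 1.5
    shift: Tuple[float, float] = (0.5, 0.5)
    calib_amplitude: float = 0.05
    calib_period: float = 16.0
    noise_sd: float = 0.01

    def __post_init__(self):
        if self.blur_sigma < 0:
            raise ParameterError("blur_sigma must be >= 0")
        if abs(self.calib_amplitude) >= 0.2:
            raise ParameterError("|calib_amplitude| must be < 0.2")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    def is_identity(self) -> bool:
        return (
            self.blur_sigma == 0
            and self.shift == (0.0, 0.0)
            and self.calib_amplitude == 0
            and self.noise_sd == 0
        )


@dataclass
class PairedCase:
    """Aligned (CT, RTDose, MDose) fields on one grid."""

    case_id: str
    site_label: str
    ct: np.ndarray
    rtdose: np.ndarray
    mdose: np.ndarray
    spacing: Tuple[float, float] = (1.0, 1.0)
    seed: Optional[int] = None

    def stack(self, with_ct: bool = False) -> np.ndarray:
        """Conditioning stack in the package's channel order (RTDose[, CT])."""
        chans = [self.rtdose] + ([self.ct] if with_ct else [])
        return np.stack(chans, axis=0)

    def volume(self, channel: str) -> DoseVolume:
        """One channel ('ct' | 'rtdose' | 'mdose') with its grid spacing."""
        if channel not in ("ct", "rtdose", "mdose"):
            raise ParameterError(f"unknown channel {channel!r}")
        return DoseVolume(data=getattr(self, channel), spacing=self.spacing)


def _ellipse_mask(shape, cy, cx, ay, ax) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def calibration_field(shape: Tuple[int, int], error: ErrorModel) -> np.ndarray:
    """Deterministic smooth multiplicative calibration field (same every case)."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    w = 2.0 * np.pi / error.calib_period
    return 1.0 + error.calib_amplitude * np.sin(w * yy + 0.7) * np.sin(w * xx + 1.3)


def planned_to_measured(rtdose: np.ndarray, error: ErrorModel,
                        rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Apply the error model: ``clip(calib * shift(blur(dose)) + noise, 0, inf)``."""
    if error.is_identity():
        return rtdose.copy()
    m = rtdose
    if error.blur_sigma > 0:
        m = ndimage.gaussian_filter(m, sigma=error.blur_sigma, mode="constant")
    if error.shift != (0.0, 0.0):
        m = ndimage.shift(m, shift=error.shift, order=3, mode="constant")
    if error.calib_amplitude != 0:
        m = m * calibration_field(rtdose.shape, error)
    if error.noise_sd > 0:
        if rng is None:
            raise ParameterError("noise_sd > 0 requires an rng")
        m = m + rng.normal(0.0, error.noise_sd, size=m.shape)
    return np.clip(m, 0.0, None)


def make_case(spec: PhantomSpec, error: ErrorModel, seed: int) -> PairedCase:
    """Generate one aligned phantom case, reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    H, W = spec.grid_size
    cy, cx, ay, ax = spec.body
    cy, cx, ay, ax = cy * (H - 1), cx * (W - 1), ay * H, ax * W
    body = _ellipse_mask((H, W), cy, cx, ay, ax)

    # CT: body at 0.3, internal structures at distinct higher intensities
    ct = np.zeros((H, W))
    ct[body] = 0.3
    for _ in range(spec.n_structures):
        scy = cy + rng.uniform(-0.5, 0.5) * ay
        scx = cx + rng.uniform(-0.5, 0.5) * ax
        say = rng.uniform(0.08, 0.2) * H
        sax = rng.uniform(0.08, 0.2) * W
        val = rng.uniform(0.4, 0.9)
        ct[_ellipse_mask((H, W), scy, scx, say, sax) & body] = val

    # dose targets inside the body
    if spec.target_centers is not None:
        centers = [tuple(map(float, c)) for c in spec.target_centers]
        for ty, tx in centers:
            if ((ty - cy) / ay) ** 2 + ((tx - cx) / ax) ** 2 > 1.0:
                raise ParameterError(f"target center {(ty, tx)} lies outside the body")
        # keep the rng stream aligned with the random-center path
        rng.uniform(size=(spec.n_targets, 2))
    else:
        offs = rng.uniform(-0.55, 0.55, size=(spec.n_targets, 2))
        centers = [(cy + oy * ay, cx + ox * ax) for oy, ox in offs]

    yy, xx = np.mgrid[0:H, 0:W]
    rtdose = np.zeros((H, W))
    for ty, tx in centers:
        sy = rng.uniform(0.08, 0.16) * H
        sx = rng.uniform(0.08, 0.16) * W
        amp = rng.uniform(0.5, 1.0)
        rtdose += amp * np.exp(-0.5 * (((yy - ty) / sy) ** 2 + ((xx - tx) / sx) ** 2))
    rtdose[~body] = 0.0
    peak = rtdose.max()
    if peak <= 0:
        raise ParameterError("degenerate phantom: zero dose everywhere")
    rtdose = rtdose / peak  # case normalization: RTDose max == 1

    mdose = planned_to_measured(rtdose, error, rng)
    return PairedCase(
        case_id="", site_label=spec.site_label, ct=ct, rtdose=rtdose, mdose=mdose,
        seed=int(seed),
    )


@dataclass
class Dataset:
    """A stratified train/test split of paired cases plus its manifest."""

    train: List[PairedCase]
    test: List[PairedCase]
    manifest: Dict

    @property
    def cases(self) -> List[PairedCase]:
        return self.train + self.test


def _stratified_counts(site_counts: Dict[str, int], ratio: float) -> Dict[str, int]:
    """Per-site train counts by largest remainder, totalling round(ratio * n)."""
    n = sum(site_counts.values())
    total_train = int(round(ratio * n))
    raw = {s: ratio * c for s, c in site_counts.items()}
    base = {s: int(np.floor(v)) for s, v in raw.items()}
    short = total_train - sum(base.values())
    order = sorted(site_counts, key=lambda s: (raw[s] - base[s], s), reverse=True)
    for s in order[:short]:
        base[s] += 1
    return base


def make_dataset(
    n_cases: int,
    split_ratio: float = 0.8,
    specs: Optional[Sequence[PhantomSpec]] = None,
    error: Optional[ErrorModel] = None,
    seed: int = 0,
    grid_size: Tuple[int, int] = (32, 32),
) -> Dataset:
    """Generate ``n_cases`` phantoms and split them ``split_ratio`` train / rest test.

    The split is random but stratified by site label (each site's train
    fraction within one case of the global ratio), disjoint and
    exhaustive, and fully reproducible from ``seed``.  ``specs`` defaults
    to one :class:`PhantomSpec` per anatomical site on ``grid_size``.
    """
    if n_cases < 2:
        raise ParameterError(f"need at least 2 cases, got {n_cases}")
    if not (0.0 < split_ratio < 1.0):
        raise ParameterError(f"split_ratio must be in (0, 1), got {split_ratio}")
    if specs is None:
        specs = [PhantomSpec(grid_size=grid_size, site_label=s) for s in SITES]
    if error is None:
        error = ErrorModel()

    rng = np.random.default_rng(seed)
    cases: List[PairedCase] = []
    for idx in range(n_cases):
        spec = specs[idx % len(specs)]
        case_seed = int(rng.integers(0, 2**31 - 1))
        case = make_case(spec, error, case_seed)
        case.case_id = f"case_{idx:04d}"
        cases.append(case)

    by_site: Dict[str, List[PairedCase]] = {}
    for c in cases:
        by_site.setdefault(c.site_label, []).append(c)
    train_counts = _stratified_counts({s: len(v) for s, v in by_site.items()}, split_ratio)
    n_train = sum(train_counts.values())
    if n_train == 0 or n_train == n_cases:
        raise ParameterError(
            f"split_ratio {split_ratio} produces an empty split for n={n_cases}"
        )

    train: List[PairedCase] = []
    test: List[PairedCase] = []
    for site in sorted(by_site):
        members = by_site[site]
        perm = rng.permutation(len(members))
        k = train_counts[site]
        train.extend(members[j] for j in perm[:k])
        test.extend(members[j] for j in perm[k:])
    train.sort(key=lambda c: c.case_id)
    test.sort(key=lambda c: c.case_id)

    def _jsonify(obj):
        # canonical JSON types so a saved/reloaded manifest compares equal
        if isinstance(obj, dict):
            return {k: _jsonify(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonify(v) for v in obj]
        return obj

    manifest = {
        "n_cases": n_cases,
        "split_ratio": split_ratio,
        "seed": int(seed),
        "grid_size": list(grid_size),
        "error_model": _jsonify(asdict(error)),
        "specs": [_jsonify(asdict(s)) for s in specs],
        "train_ids": [c.case_id for c in train],
        "test_ids": [c.case_id for c in test],
        "case_seeds": {c.case_id: c.seed for c in cases},
        "sites": {c.case_id: c.site_label for c in cases},
        "channel_order": ["mdose", "rtdose", "ct"],
        "normalization": "per-case: all channels on the scale where case RTDose max == 1",
    }
    return Dataset(train=train, test=test, manifest=manifest)
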
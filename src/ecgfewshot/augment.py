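"""Stochastic augmentation family for contrastive view generation.

Three operators, applied in the fixed order crop -> scale -> noise:

* random crop/resample — a contiguous window is stretched back to full
  length, emulating heart-rate variability;
* amplitude scaling — one multiplicative gain shared across leads and time,
  emulating amplitude drift;
* additive Gaussian noise — i.i.d. per sample, emulating acquisition noise.

Two presets are exposed: mild ``ssl_views`` magnitudes for contrastive
positives, and a deliberately aggressive ``downstream_strong`` block used by
the augmentation-ablation training groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic_ecg import ConfigurationError, EcgRecord

__all__ = [
    "AugmentationConfig",
    "ViewPair",
    "random_crop_resample",
    "amplitude_scale",
    "add_gaussian_noise",
    "augment_signal",
    "make_view_pair",
    "SSL_VIEW_DEFAULTS",
    "DOWNSTREAM_STRONG_DEFAULTS",
]

logger = logging.getLogger(__name__)

_ALL_OPS = ("crop_resample", "amp_scale", "gauss_noise")


@dataclass(frozen=True)
class AugmentationConfig:
    crop_frac_range: tuple[float, float] = (0.7, 1.0)
    scale_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.05
    enabled_ops: tuple[str, ...] = _ALL_OPS

    def __post_init__(self) -> None:
        lo, hi = self.crop_frac_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError(f"bad crop_frac_range {self.crop_frac_range}")
        slo, shi = self.scale_range
        if not (0 < slo <= shi):
            raise ConfigurationError(f"bad scale_range {self.scale_range}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        bad = set(self.enabled_ops) - set(_ALL_OPS)
        if bad:
            raise ConfigurationError(f"unknown augmentation ops: {sorted(bad)}")


SSL_VIEW_DEFAULTS = AugmentationConfig()
DOWNSTREAM_STRONG_DEFAULTS = AugmentationConfig(
    crop_frac_range=(0.5, 1.0), scale_range=(0.5, 1.5), noise_sd=0.15
)


@dataclass
class ViewPair:
    """Two stochastically augmented views of one source record."""

    view_i: np.ndarray
    view_j: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        if self.view_i.shape != self.view_j.shape:
            raise ValueError("views must share the source record's shape")


def random_crop_resample(x: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Crop a random contiguous window of ``round(frac*T)`` samples and
    linearly stretch it back to length T.  ``frac=1`` is the identity."""
    x = np.asarray(x, dtype=float)
    T = x.shape[-1]
    if not (0 < frac <= 1):
        raise ConfigurationError(f"crop fraction must be in (0, 1], got {frac}")
    L = int(round(frac * T))
    if L < 2:
        raise ConfigurationError(f"crop window of {L} samples is too short")
    if L == T:
        return x.copy()
    offset = int(rng.integers(0, T - L + 1))
    window = x[..., offset : offset + L]
    src = np.linspace(0.0, L - 1.0, T)
    idx = np.arange(L, dtype=float)
    out = np.empty_like(x)
    for l in range(x.shape[0]):
        out[l] = np.interp(src, idx, window[l])
    return out


def amplitude_scale(x: np.ndarray, scale_range: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Multiply the whole signal by one gain ~ Uniform(lo, hi)."""
    lo, hi = scale_range
    if not (0 < lo <= hi):
        raise ConfigurationError(f"bad scale_range {scale_range}")
    s = float(rng.uniform(lo, hi))
    return np.asarray(x, dtype=float) * s


def add_gaussian_noise(x: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian noise with the given SD to every sample."""
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    x = np.asarray(x, dtype=float)
    if noise_sd == 0:
        return x.copy()
    return x + noise_sd * rng.standard_normal(x.shape)


def augment_signal(x: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator) -> np.ndarray:
    """One draw from the augmentation family (fixed order crop -> scale -> noise)."""
    out = np.asarray(x, dtype=float)
    if "crop_resample" in cfg.enabled_ops:
        frac = float(rng.uniform(*cfg.crop_frac_range))
        out = random_crop_resample(out, frac, rng)
    if "amp_scale" in cfg.enabled_ops:
        out = amplitude_scale(out, cfg.scale_range, rng)
    if "gauss_noise" in cfg.enabled_ops:
        out = add_gaussian_noise(out, cfg.noise_sd, rng)
    return out


def make_view_pair(rec: EcgRecord, cfg: AugmentationConfig, rng: np.random.Generator) -> ViewPair:
    """Two independent augmentation draws of one preprocessed record.

    With no enabled operators the pair degenerates to (x, x) — useful as a
    contrastive-loss sanity case — and a warning is logged.
    """
    if not cfg.enabled_ops:
        logger.warning(
            "make_view_pair called with no enabled ops; returning identical views"
        )
        return ViewPair(rec.signal.copy(), rec.signal.copy(), rec.record_id)
    vi = augment_signal(rec.signal, cfg, rng)
    vj = augment_signal(rec.signal, cfg, rng)
    return ViewPair(vi, vj, rec.record_id)
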
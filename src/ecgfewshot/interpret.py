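"""1-D Grad-CAM saliency and quantitative region-attention weights.

Grad-CAM over the time axis: the gradient of a target-class logit with
respect to the encoder's last convolutional feature map is averaged over
time to give one weight per channel; the rectified weighted channel sum,
linearly upsampled to the input length and normalized to max 1, is the
per-timestep importance map.  Region attention weights then quantify where
a classifier looks — e.g. the fraction of total saliency mass inside QRS
windows versus the inter-beat baseline, the diagnostically relevant region
for atrial fibrillation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Classifier, Tensor

__all__ = [
    "ImportanceMap",
    "RegionMask",
    "gradcam_1d",
    "region_attention_weight",
    "qrs_mask",
]


@dataclass
class ImportanceMap:
    """Nonnegative per-timestep saliency, max-normalized to 1 when nonzero."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("importance map must be a finite nonnegative vector")
        self.values = v


@dataclass
class RegionMask:
    """Boolean mask over timesteps marking a region of interest."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 1 or m.dtype != bool:
            raise ValueError("region mask must be a 1-D boolean vector")
        self.mask = m

    def complement(self) -> "RegionMask":
        return RegionMask(~self.mask)


def gradcam_1d(
    model: Classifier, x: np.ndarray, target_class: int, normalize: bool = True
) -> ImportanceMap:
    """Grad-CAM importance over time for one (12, T) input and target class.

    Channel weights are the time-averaged gradients of the target logit
    w.r.t. the last conv feature map; the map is the ReLU of the weighted
    channel sum, upsampled to the input length and divided by its maximum
    when positive (a constant-output model yields an all-zero map).
    """
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError("x must be a single (leads, T) signal")
    if not 0 <= int(target_class) < 5:
        raise ValueError(f"target_class {target_class} out of range")
    logits = model(Tensor(x[None].astype(np.float32)))
    logits[0, int(target_class)].backward()
    fmap = model.encoder.last_conv
    assert fmap is not None
    grads = fmap.grad  # (1, C, T')
    if grads is None:
        grads = np.zeros_like(fmap.data)
    weights = grads.mean(axis=2)  # (1, C)
    cam = np.maximum((weights[:, :, None] * fmap.data).sum(axis=1)[0], 0.0)
    t_feat = np.linspace(0, x.shape[1] - 1, num=cam.size)
    upsampled = np.interp(np.arange(x.shape[1]), t_feat, cam)
    if normalize:
        peak = upsampled.max()
        if peak > 0:
            upsampled = upsampled / peak
    return ImportanceMap(upsampled)


def region_attention_weight(map_: ImportanceMap, region: RegionMask) -> float:
    """Fraction of total saliency mass inside the region: sum_in / sum_all."""
    values, mask = map_.values, region.mask
    if values.size != mask.size:
        raise ValueError("map and region mask must have equal length")
    total = values.sum()
    if total <= 0:
        raise ZeroDivisionError("total saliency mass is zero; weight undefined")
    return float(values[mask].sum() / total)


def qrs_mask(
    beat_times_s: np.ndarray, fs: float, n_samples: int, half_width_s: float = 0.06
) -> RegionMask:
    """Boolean QRS-region mask: +/- ``half_width_s`` around each R-peak time."""
    mask = np.zeros(n_samples, dtype=bool)
    for t in np.asarray(beat_times_s, dtype=float):
        lo = max(0, int(np.floor((t - half_width_s) * fs)))
        hi = min(n_samples, int(np.ceil((t + half_width_s) * fs)) + 1)
        if lo < hi:
            mask[lo:hi] = True
    return RegionMask(mask)
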
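"""Experiment configuration: schema, validation, seed derivation, hashing.

One YAML file declares every stage (generator, splits, augmentation blocks,
pretraining, fine-tuning, audit).  A single global seed expands
deterministically into per-stage and per-run seeds, so group comparisons
share data while runs vary only in initialization and training stochasticity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augment import DOWNSTREAM_STRONG_DEFAULTS, SSL_VIEW_DEFAULTS, AugmentationConfig
from .finetune import FinetuneConfig
from .nn import DEFAULT_ENCODER_SPEC, TINY_ENCODER_SPEC, EncoderSpec, ProjectionSpec
from .preprocess import SplitSpec
from .ssl_pretrain import PretrainConfig
from .synthetic_ecg import ConfigurationError

__all__ = ["ExperimentConfig", "load_config", "derive_seed"]

_ENCODER_PRESETS = {"default": DEFAULT_ENCODER_SPEC, "tiny": TINY_ENCODER_SPEC}

# stage labels hashed into per-stage seed streams
_STAGE_IDS = {"data": 1, "pretrain": 2, "matrix": 3}


def derive_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage, per-run seed below 2**31."""
    if stage not in _STAGE_IDS:
        raise ConfigurationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage], int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _aug_from_dict(d: dict, defaults: AugmentationConfig) -> AugmentationConfig:
    return AugmentationConfig(
        crop_frac_range=tuple(d.get("crop_frac_range", defaults.crop_frac_range)),
        scale_range=tuple(d.get("scale_range", defaults.scale_range)),
        noise_sd=float(d.get("noise_sd", defaults.noise_sd)),
        enabled_ops=tuple(d.get("enabled_ops", defaults.enabled_ops)),
    )


@dataclass
class ExperimentConfig:
    seed: int = 0
    run_dir: str = "runs/default"
    split_spec: SplitSpec = field(default_factory=SplitSpec)
    ssl_views: AugmentationConfig = SSL_VIEW_DEFAULTS
    downstream_strong: AugmentationConfig = DOWNSTREAM_STRONG_DEFAULTS
    encoder_spec: EncoderSpec = DEFAULT_ENCODER_SPEC
    projection_spec: ProjectionSpec = field(default_factory=ProjectionSpec)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    groups: tuple[str, ...] = ("A", "A'", "B", "C", "E", "D-Aug", "D-NoAug")
    n_seeds: int = 3

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def run_seeds(self) -> list[int]:
        return [derive_seed(self.seed, "matrix", i) for i in range(self.n_seeds)]


def _to_jsonable(obj):
    from dataclasses import asdict, is_dataclass

    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {
        "seed", "run_dir", "splits", "augment", "encoder", "projection",
        "pretrain", "finetune", "audit",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")

    seed = int(raw.get("seed", 0))
    split_kwargs = dict(raw.get("splits", {}))
    if "test_mixture" in split_kwargs:
        split_kwargs["test_mixture"] = tuple(split_kwargs["test_mixture"])
    split_kwargs.setdefault("seed", derive_seed(seed, "data"))
    try:
        split_spec = SplitSpec(**split_kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"splits: {exc}") from exc

    aug_raw = raw.get("augment", {})
    ssl_views = _aug_from_dict(aug_raw.get("ssl_views", {}), SSL_VIEW_DEFAULTS)
    strong = _aug_from_dict(aug_raw.get("downstream_strong", {}), DOWNSTREAM_STRONG_DEFAULTS)

    enc_raw = dict(raw.get("encoder", {}))
    preset = enc_raw.pop("preset", "default")
    if preset not in _ENCODER_PRESETS:
        raise ConfigurationError(f"unknown encoder preset {preset!r}")
    enc_spec = _ENCODER_PRESETS[preset]
    if enc_raw:
        from dataclasses import asdict, replace

        if "conv_blocks" in enc_raw:
            enc_raw["conv_blocks"] = tuple(tuple(b) for b in enc_raw["conv_blocks"])
        try:
            enc_spec = replace(enc_spec, **enc_raw)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"encoder: {exc}") from exc

    proj_raw = raw.get("projection", {})
    proj_spec = ProjectionSpec(dims=tuple(proj_raw.get("dims", (64, 128, 64))))

    pre_raw = dict(raw.get("pretrain", {}))
    pre_raw.setdefault("seed", derive_seed(seed, "pretrain"))
    try:
        pretrain = PretrainConfig(**pre_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"pretrain: {exc}") from exc

    ft_raw = dict(raw.get("finetune", {}))
    ft_raw.pop("seed", None)  # per-run seeds come from the audit stage
    try:
        finetune = FinetuneConfig(**ft_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"finetune: {exc}") from exc

    audit_raw = raw.get("audit", {})
    groups = tuple(audit_raw.get("groups", ("A", "A'", "B", "C", "E", "D-Aug", "D-NoAug")))
    n_seeds = int(audit_raw.get("n_seeds", 3))
    if n_seeds < 1:
        raise ConfigurationError("audit.n_seeds must be >= 1")

    return ExperimentConfig(
        seed=seed,
        run_dir=str(raw.get("run_dir", "runs/default")),
        split_spec=split_spec,
        ssl_views=ssl_views,
        downstream_strong=strong,
        encoder_spec=enc_spec,
        projection_spec=proj_spec,
        pretrain=pretrain,
        finetune=finetune,
        groups=groups,
        n_seeds=n_seeds,
    )
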
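"""Resampling, per-lead Z-score normalization and split construction.

The fixed preprocessing pipeline is: resample each record to 100 Hz, then
Z-score each lead within its own 10 s segment,

    x_norm[l, t] = (x[l, t] - mu_l) / (sigma_l + eps),

with no cross-record statistics.  Splits are generated disjointly by
record-id namespace: a class-balanced few-shot training set, balanced and
imbalanced 300-sample references, a balanced validation set for early
stopping, a long-tailed test set, and an unlabeled pretraining pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import resample_poly

from .synthetic_ecg import (
    ConfigurationError,
    EcgRecord,
    generate_labeled_set,
    generate_unlabeled_pool,
)

__all__ = [
    "NormalizationParams",
    "SplitSpec",
    "Splits",
    "DEFAULT_TEST_MIXTURE",
    "resample_record",
    "zscore_normalize",
    "build_splits",
    "preprocess_record",
]

EPSILON_DEFAULT = 1e-8

# Long-tailed mixture with SR-dominant mass for the imbalanced reference and
# test sets: SR, AFIB, STACH, SARRH, SBRAD.
DEFAULT_TEST_MIXTURE: tuple[float, ...] = (0.55, 0.15, 0.12, 0.10, 0.08)


@dataclass
class NormalizationParams:
    """Audit trail of one record's Z-score: per-lead mean/SD and epsilon."""

    epsilon: float
    mean: np.ndarray  # shape (12,)
    sd: np.ndarray  # shape (12,)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")
        if np.any(self.sd < 0):
            raise ValueError("per-lead SD must be >= 0")


@dataclass(frozen=True)
class SplitSpec:
    """Sizes and mixtures of the named splits."""

    few_shot_n_per_class: int = 14
    reference_n: int = 300
    reference_balanced: bool = True
    val_n_per_class: int = 7
    test_size: int = 400
    test_mixture: tuple[float, ...] = DEFAULT_TEST_MIXTURE
    unlabeled_n: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.few_shot_n_per_class,
            self.reference_n,
            self.val_n_per_class,
            self.test_size,
            self.unlabeled_n,
        )
        if any(c < 1 for c in counts):
            raise ConfigurationError("all split sizes must be >= 1")
        mix = np.asarray(self.test_mixture, dtype=float)
        if mix.shape != (5,) or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
            raise ConfigurationError("test_mixture must be a 5-simplex")
        if self.reference_n % 5 != 0:
            raise ConfigurationError("reference_n must be divisible by 5")


@dataclass
class Splits:
    """The named record collections used by the experiment matrix."""

    few: list[EcgRecord]
    val: list[EcgRecord]
    test: list[EcgRecord]
    unlabeled: list[EcgRecord]
    ref: list[EcgRecord]
    ref_balanced: list[EcgRecord]
    spec: SplitSpec | None = None

    def as_dict(self) -> dict[str, list[EcgRecord]]:
        return {
            "few": self.few,
            "val": self.val,
            "test": self.test,
            "unlabeled": self.unlabeled,
            "ref": self.ref,
            "ref_bal": self.ref_balanced,
        }


def resample_record(rec: EcgRecord, target_fs: float) -> EcgRecord:
    """Resample a record to ``target_fs`` (downsampling only).

    Uses polyphase filtering on mean-centered leads: the per-lead mean is
    removed before the anti-aliasing filter and restored afterwards, so
    constant (DC) leads are preserved exactly and edge ringing is reduced.
    A record already at ``target_fs`` is returned unchanged.
    """
    if rec.fs < target_fs:
        raise NotImplementedError(
            f"upsampling {rec.fs} -> {target_fs} Hz is not supported"
        )
    if rec.fs == target_fs:
        return rec
    from fractions import Fraction

    frac = Fraction(int(round(target_fs * 1000)), int(round(rec.fs * 1000)))
    mean = rec.signal.mean(axis=1, keepdims=True)
    out = resample_poly(rec.signal - mean, frac.numerator, frac.denominator, axis=1)
    out = out + mean
    n_expected = round(rec.duration_s * target_fs)
    out = out[:, :n_expected]
    return EcgRecord(
        signal=out,
        fs=float(target_fs),
        duration_s=rec.duration_s,
        label=rec.label,
        record_id=rec.record_id,
        meta=dict(rec.meta),
    )


def zscore_normalize(
    rec: EcgRecord, epsilon: float = EPSILON_DEFAULT, return_params: bool = False
):
    """Per-lead Z-score within the record: (x - mu_l) / (sigma_l + eps)."""
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be > 0")
    mu = rec.signal.mean(axis=1, keepdims=True)
    sd = rec.signal.std(axis=1, keepdims=True)
    out = (rec.signal - mu) / (sd + epsilon)
    norm_rec = EcgRecord(
        signal=out,
        fs=rec.fs,
        duration_s=rec.duration_s,
        label=rec.label,
        record_id=rec.record_id,
        meta=dict(rec.meta),
    )
    if return_params:
        params = NormalizationParams(epsilon=epsilon, mean=mu.ravel(), sd=sd.ravel())
        return norm_rec, params
    return norm_rec


def preprocess_record(
    rec: EcgRecord, target_fs: float = 100.0, epsilon: float = EPSILON_DEFAULT
) -> EcgRecord:
    """The fixed pipeline: resample to ``target_fs``, then Z-score per lead."""
    return zscore_normalize(resample_record(rec, target_fs), epsilon)


def _mixture_set(
    n: int,
    mixture,
    rng: np.random.Generator,
    id_prefix: str,
    fs: float,
    duration_s: float,
) -> list[EcgRecord]:
    return generate_unlabeled_pool(
        n, mixture, rng, fs=fs, duration_s=duration_s, id_prefix=id_prefix,
        strip_labels=False,
    )


def build_splits(
    spec: SplitSpec,
    fs: float = 100.0,
    duration_s: float = 10.0,
    epsilon: float = EPSILON_DEFAULT,
) -> Splits:
    """Generate, resample and normalize all named splits.

    Each split draws from an independent random stream spawned from
    ``spec.seed`` and owns a record-id namespace, so the collections are
    disjoint by construction and reproducible bit-for-bit from the seed.
    """
    ss = np.random.SeedSequence(spec.seed)
    streams = [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(6)]
    r_few, r_val, r_test, r_unl, r_ref, r_refb = streams

    few = generate_labeled_set(
        spec.few_shot_n_per_class, r_few, fs=fs, duration_s=duration_s, id_prefix="few"
    )
    val = generate_labeled_set(
        spec.val_n_per_class, r_val, fs=fs, duration_s=duration_s, id_prefix="val"
    )
    test = _mixture_set(spec.test_size, spec.test_mixture, r_test, "test", fs, duration_s)
    unlabeled = generate_unlabeled_pool(
        spec.unlabeled_n, spec.test_mixture, r_unl, fs=fs, duration_s=duration_s,
        id_prefix="unl",
    )
    ref = _mixture_set(spec.reference_n, spec.test_mixture, r_ref, "ref", fs, duration_s)
    ref_balanced = generate_labeled_set(
        spec.reference_n // 5, r_refb, fs=fs, duration_s=duration_s, id_prefix="refbal"
    )

    def prep(records: list[EcgRecord]) -> list[EcgRecord]:
        return [preprocess_record(r, 100.0, epsilon) for r in records]

    splits = Splits(
        few=prep(few),
        val=prep(val),
        test=prep(test),
        unlabeled=prep(unlabeled),
        ref=prep(ref),
        ref_balanced=prep(ref_balanced),
        spec=spec,
    )
    _assert_disjoint(splits)
    return splits


def _assert_disjoint(splits: Splits) -> None:
    seen: set[str] = set()
    for name, records in splits.as_dict().items():
        ids = {r.record_id for r in records}
        if len(ids) != len(records):
            raise ConfigurationError(f"duplicate record ids inside split {name!r}")
        if seen & ids:
            raise ConfigurationError(f"record ids collide between splits at {name!r}")
        seen |= ids
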
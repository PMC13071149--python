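"""Synthetic 12-lead ECG rhythm generator.

Produces labeled and unlabeled records whose class structure mirrors the five
common rhythm classes used throughout the package: sinus rhythm (SR), atrial
fibrillation (AFIB), sinus tachycardia (STACH), sinus arrhythmia (SARRH) and
sinus bradycardia (SBRAD).  The point is not physiological fidelity: each
class is separable through exactly the features a rhythm classifier must use
— heart rate, RR-interval variability, respiratory RR modulation, P-wave
presence and fibrillatory baseline activity.

Beat morphology is a sum of Gaussian bumps (P, Q, R, S, T) placed on the beat
train; the 12 leads are realized as fixed per-lead gains on one base waveform
plus independent Gaussian noise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RhythmClass",
    "RhythmParams",
    "EcgRecord",
    "LeadProjection",
    "CLASS_NAMES",
    "default_params",
    "default_projection",
    "generate_rr_series",
    "synthesize_record",
    "generate_labeled_set",
    "generate_unlabeled_pool",
    "GenerationError",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Invalid generator or experiment configuration."""


class GenerationError(RuntimeError):
    """A record could not be generated under the requested parameters."""


class RhythmClass(enum.IntEnum):
    """The five rhythm classes, in fixed index order 0-4."""

    SR = 0
    AFIB = 1
    STACH = 2
    SARRH = 3
    SBRAD = 4


CLASS_NAMES: tuple[str, ...] = tuple(c.name for c in RhythmClass)

# (center offset s relative to R, width s, amplitude) for each wave.
# Amplitudes are on an arbitrary mV-like scale with R normalized to 1.
_DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (-0.16, 0.025, 0.15),
    "Q": (-0.03, 0.010, -0.10),
    "R": (0.00, 0.012, 1.00),
    "S": (0.027, 0.010, -0.15),
    "T": (0.30, 0.060, 0.30),
}


@dataclass(frozen=True)
class RhythmParams:
    """Per-class generation parameters.

    Attributes
    ----------
    hr_range_bpm:
        (low, high) range from which the record's mean heart rate is drawn.
    rr_cv:
        Target coefficient of variation of the RR intervals.
    resp_mod_depth:
        Fractional sinusoidal RR modulation at respiratory frequency
        (0.15-0.4 Hz); nonzero only for SARRH.
    p_amp:
        P-wave amplitude; zero for AFIB (absent P waves).
    fib_amp:
        Amplitude of the fibrillatory 5-9 Hz baseline oscillation; nonzero
        only for AFIB.
    wave_params:
        Per-wave Gaussian bump (center offset s, width s, amplitude).
    """

    hr_range_bpm: tuple[float, float]
    rr_cv: float
    resp_mod_depth: float = 0.0
    p_amp: float = 0.15
    fib_amp: float = 0.0
    wave_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_WAVES)
    )

    def __post_init__(self) -> None:
        lo, hi = self.hr_range_bpm
        if not (20.0 < lo <= hi < 250.0):
            raise ConfigurationError(
                f"hr_range_bpm must lie within (20, 250), got {self.hr_range_bpm}"
            )
        if self.rr_cv < 0:
            raise ConfigurationError("rr_cv must be >= 0")
        if min(self.resp_mod_depth, self.p_amp, self.fib_amp) < 0:
            raise ConfigurationError("modulation depth and amplitudes must be >= 0")


_DEFAULT_PARAMS: dict[RhythmClass, RhythmParams] = {
    RhythmClass.SR: RhythmParams(hr_range_bpm=(60, 100), rr_cv=0.03),
    RhythmClass.AFIB: RhythmParams(
        hr_range_bpm=(60, 150), rr_cv=0.24, p_amp=0.0, fib_amp=0.08
    ),
    RhythmClass.STACH: RhythmParams(hr_range_bpm=(101, 160), rr_cv=0.03),
    RhythmClass.SARRH: RhythmParams(
        hr_range_bpm=(60, 100), rr_cv=0.03, resp_mod_depth=0.15
    ),
    RhythmClass.SBRAD: RhythmParams(hr_range_bpm=(35, 59), rr_cv=0.03),
}


def default_params(cls: RhythmClass) -> RhythmParams:
    """Default :class:`RhythmParams` for one rhythm class."""
    try:
        return _DEFAULT_PARAMS[RhythmClass(cls)]
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"unknown rhythm class: {cls!r}") from exc


@dataclass(frozen=True)
class LeadProjection:
    """Fixed per-lead gains applied to the base waveform, plus noise level."""

    weights: np.ndarray  # shape (12,)
    per_lead_noise_sd: float = 0.03

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (12,) or not np.all(np.isfinite(w)):
            raise ConfigurationError("projection weights must be a finite 12-vector")
        if not np.any(w != 0):
            raise ConfigurationError("at least one lead gain must be nonzero")
        if self.per_lead_noise_sd < 0:
            raise ConfigurationError("per_lead_noise_sd must be >= 0")
        object.__setattr__(self, "weights", w)


def default_projection(rng: np.random.Generator, noise_sd: float = 0.03) -> LeadProjection:
    """Random per-lead gains in [0.4, 1.2] with random sign flips on 4 leads.

    Sign flips loosely emulate leads that see the cardiac vector from the
    opposite direction (e.g. aVR); magnitudes stay well away from zero so no
    lead is degenerate.
    """
    gains = rng.uniform(0.4, 1.2, size=12)
    flip = rng.permutation(12)[:4]
    gains[flip] *= -1.0
    return LeadProjection(weights=gains, per_lead_noise_sd=noise_sd)


@dataclass
class EcgRecord:
    """One 12-lead record: ``signal`` has shape (12, round(duration_s * fs))."""

    signal: np.ndarray
    fs: float
    duration_s: float
    label: Optional[RhythmClass]
    record_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2 or sig.shape[0] != 12:
            raise ValueError(f"signal must be 12 x T, got shape {sig.shape}")
        if sig.shape[1] != round(self.duration_s * self.fs):
            raise ValueError(
                f"expected {round(self.duration_s * self.fs)} samples, got {sig.shape[1]}"
            )
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains NaN or Inf")
        self.signal = sig

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def generate_rr_series(
    cls: RhythmClass,
    duration_s: float,
    rng: np.random.Generator,
    params: RhythmParams | None = None,
) -> np.ndarray:
    """Generate an RR-interval series (seconds) covering ``duration_s``.

    The series is rescaled so that its realized mean heart rate, 60/mean(RR),
    equals the target rate drawn uniformly from ``params.hr_range_bpm``; the
    rescale preserves the coefficient of variation and any respiratory
    modulation.  AFIB uses gamma-distributed intervals (irregularly
    irregular); sinus classes use Gaussian jitter around the mean, SARRH with
    an additional sinusoid at a respiratory frequency drawn from 0.15-0.4 Hz.

    Returns intervals whose cumulative sum is >= duration_s.
    """
    cls = RhythmClass(cls)
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    params = params if params is not None else default_params(cls)

    lo, hi = params.hr_range_bpm
    if duration_s * hi / 60.0 < 1.0:
        raise GenerationError(
            f"hr_range {params.hr_range_bpm} cannot place one beat in {duration_s}s"
        )
    # stay off the range edges so the realized mean never leaves the range
    margin = 0.05 * (hi - lo)
    target_hr = rng.uniform(lo + margin, hi - margin) if hi > lo else lo
    mean_rr = 60.0 / target_hr
    # one spare beat beyond the window so the cumsum always covers it
    n_beats = int(np.ceil(duration_s / mean_rr)) + 3

    if cls is RhythmClass.AFIB:
        cv = max(params.rr_cv, 1e-12)
        shape = 1.0 / cv**2
        rr = rng.gamma(shape, scale=mean_rr / shape, size=n_beats)
    else:
        jitter = params.rr_cv * rng.standard_normal(n_beats)
        mod = np.zeros(n_beats)
        if params.resp_mod_depth > 0:
            f_resp = rng.uniform(0.15, 0.4)
            phase = rng.uniform(0, 2 * np.pi)
            # modulation evaluated at the nominal beat times
            t_nom = np.arange(n_beats) * mean_rr
            mod = params.resp_mod_depth * np.sin(2 * np.pi * f_resp * t_nom + phase)
        rr = mean_rr * (1.0 + jitter + mod)

    rr = np.clip(rr, 0.2, 3.0)
    # pin realized mean HR to the target without touching relative structure
    rr *= mean_rr / rr.mean()
    cum = np.cumsum(rr)
    n_keep = int(np.searchsorted(cum, duration_s)) + 1
    return rr[: min(n_keep, n_beats)]


def _gaussian_bumps(t: np.ndarray, centers: np.ndarray, width: float, amp: float) -> np.ndarray:
    """Sum of Gaussian bumps of one wave type over all beat centers."""
    out = np.zeros_like(t)
    for c in centers:
        lo = np.searchsorted(t, c - 5 * width)
        hi = np.searchsorted(t, c + 5 * width)
        seg = t[lo:hi]
        out[lo:hi] += amp * np.exp(-0.5 * ((seg - c) / width) ** 2)
    return out


def synthesize_record(
    cls: RhythmClass,
    rng: np.random.Generator,
    params: RhythmParams | None = None,
    projection: LeadProjection | None = None,
    fs: float = 100.0,
    duration_s: float = 10.0,
    record_id: str = "syn-0",
) -> EcgRecord:
    """Synthesize one 12-lead record of the given rhythm class.

    The base waveform is the P/Q/R/S/T bump train at the RR-derived beat
    times; AFIB suppresses the P bump and adds a fibrillatory sinusoid at a
    random 5-9 Hz frequency.  Each lead is ``gain * base + noise``.
    Ground-truth beat (R-peak) times are stored in ``meta['beat_times']``.
    """
    cls = RhythmClass(cls)
    if fs not in (100.0, 500.0, 100, 500):
        raise ConfigurationError(f"fs must be 100 or 500 Hz, got {fs}")
    params = params if params is not None else default_params(cls)
    projection = projection if projection is not None else default_projection(rng)

    rr = generate_rr_series(cls, duration_s, rng, params)
    beat_times = np.cumsum(rr) - rr[0] * 0.5  # first beat partway into the window
    t = np.arange(round(duration_s * fs)) / fs

    waves = dict(params.wave_params)
    p_center, p_width, p_amp_rel = waves.pop("P")
    base = np.zeros_like(t)
    for _, (center, width, amp) in waves.items():
        base += _gaussian_bumps(t, beat_times + center, width, amp)
    if params.p_amp > 0:
        base += _gaussian_bumps(t, beat_times + p_center, p_width, params.p_amp)
    else:
        del p_amp_rel  # P wave absent (AFIB)
    if params.fib_amp > 0:
        f_fib = rng.uniform(5.0, 9.0)
        phase = rng.uniform(0, 2 * np.pi)
        base += params.fib_amp * np.sin(2 * np.pi * f_fib * t + phase)

    signal = projection.weights[:, None] * base[None, :]
    if projection.per_lead_noise_sd > 0:
        signal = signal + projection.per_lead_noise_sd * rng.standard_normal(signal.shape)

    return EcgRecord(
        signal=signal,
        fs=float(fs),
        duration_s=float(duration_s),
        label=cls,
        record_id=record_id,
        meta={"beat_times": beat_times, "base_waveform": base},
    )


def generate_labeled_set(
    n_per_class: int,
    rng: np.random.Generator,
    params_by_class: dict[RhythmClass, RhythmParams] | None = None,
    fs: float = 100.0,
    duration_s: float = 10.0,
    id_prefix: str = "lab",
) -> list[EcgRecord]:
    """Class-balanced labeled set: ``5 * n_per_class`` records, ids unique.

    Classes are interleaved (record k has class k mod 5) so any prefix of the
    list stays approximately balanced.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    params_by_class = params_by_class or {}
    records = []
    for i in range(n_per_class):
        for cls in RhythmClass:
            rec = synthesize_record(
                cls,
                rng,
                params=params_by_class.get(cls),
                fs=fs,
                duration_s=duration_s,
                record_id=f"{id_prefix}-{cls.name}-{i:05d}",
            )
            records.append(rec)
    return records


def generate_unlabeled_pool(
    n: int,
    class_mixture: np.ndarray | list[float],
    rng: np.random.Generator,
    params_by_class: dict[RhythmClass, RhythmParams] | None = None,
    fs: float = 100.0,
    duration_s: float = 10.0,
    id_prefix: str = "unl",
    strip_labels: bool = True,
) -> list[EcgRecord]:
    """Pool of ``n`` records drawn from a hidden class mixture.

    By default the label field is stripped (None) on every returned record,
    emulating a pool built by discarding annotations; ``strip_labels=False``
    retains the hidden labels (useful for audits of the mixture and for
    building imbalanced labeled reference/test sets).
    """
    mixture = np.asarray(class_mixture, dtype=float)
    if mixture.shape != (5,) or np.any(mixture < 0) or abs(mixture.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"class_mixture must be a 5-simplex, got {class_mixture!r}")
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    params_by_class = params_by_class or {}
    classes = rng.choice(5, size=n, p=mixture)
    records = []
    for i, c in enumerate(classes):
        cls = RhythmClass(int(c))
        rec = synthesize_record(
            cls,
            rng,
            params=params_by_class.get(cls),
            fs=fs,
            duration_s=duration_s,
            record_id=f"{id_prefix}-{i:06d}",
        )
        if strip_labels:
            rec.label = None
        records.append(rec)
    return records
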
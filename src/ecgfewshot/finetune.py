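"""Supervised fine-tuning with early stopping and best-epoch tracking.

Trains encoder + linear head jointly (full unfreezing) on a labeled split,
either from scratch or from contrastively pretrained encoder weights, with
multiclass cross-entropy and a deliberately low learning rate (1e-4).  After
every epoch the validation Macro-F1 is recorded; training stops once no
improvement has been seen for ``patience`` epochs, the weights from the best
epoch e* are restored, and the test set is evaluated exactly once.

The best validation epoch e* (1-based, earliest tie wins) is the package's
training-dynamics proxy: e* <= 1 marks a run that collapsed at the very
start of optimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .augment import AugmentationConfig, augment_signal
from .nn import Adam, Classifier, EncoderSpec, Tensor, log_softmax
from .stability_audit import accuracy, confusion_matrix, macro_f1
from .synthetic_ecg import EcgRecord, RhythmClass

__all__ = [
    "FinetuneConfig",
    "RunRecord",
    "EarlyStopper",
    "cross_entropy",
    "select_best_epoch",
    "predict",
    "train_supervised",
]


@dataclass(frozen=True)
class FinetuneConfig:
    init: Literal["scratch", "ssl_checkpoint"] = "scratch"
    downstream_aug: bool = False
    learning_rate: float = 1e-4
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 32
    seed: int = 0
    monitor_metric: str = "macro_f1"

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.init not in ("scratch", "ssl_checkpoint"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.monitor_metric != "macro_f1":
            raise ValueError("only validation Macro-F1 monitoring is supported")


@dataclass
class RunRecord:
    """One training run: validation trajectory, best epoch and test outcome."""

    seed: int
    val_history: list[float]
    best_epoch: int
    test_confusion: np.ndarray
    test_macro_f1: float
    test_accuracy: float
    group_tag: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.best_epoch <= len(self.val_history)):
            raise ValueError("best_epoch out of range of val_history")
        cm = np.asarray(self.test_confusion)
        if cm.shape != (5, 5) or np.any(cm < 0):
            raise ValueError("test_confusion must be a nonnegative 5x5 matrix")


def cross_entropy(probs: np.ndarray, label: RhythmClass | int) -> float:
    """Multiclass cross-entropy -log p[label] for one probability vector."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != (5,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("probs must be a 5-class probability simplex")
    idx = int(label)
    if not 0 <= idx < 5:
        raise ValueError(f"label index {idx} out of range")
    return float(-np.log(np.clip(probs[idx], 1e-300, None)))


def select_best_epoch(val_history) -> int:
    """Earliest 1-based epoch attaining the maximum of the monitored metric."""
    hist = np.asarray(val_history, dtype=float)
    if hist.size == 0:
        raise ValueError("empty validation history")
    return int(np.argmax(hist)) + 1


class EarlyStopper:
    """Stop once ``patience`` epochs pass with no strict improvement.

    ``update`` is called with the monitored metric after each epoch and
    returns True when training should halt — exactly ``patience`` epochs
    after the last improvement.  Ties do not count as improvement, so the
    earliest of equal peaks is kept.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_metric = -np.inf
        self.best_epoch = 0
        self.epoch = 0

    def update(self, metric: float) -> bool:
        self.epoch += 1
        if metric > self.best_metric:
            self.best_metric = metric
            self.best_epoch = self.epoch
            return False
        return self.epoch - self.best_epoch >= self.patience


def _forward_logits(model: Classifier, signals: np.ndarray, batch_size: int = 128) -> np.ndarray:
    out = []
    for start in range(0, len(signals), batch_size):
        xb = signals[start : start + batch_size].astype(np.float32)
        out.append(model(Tensor(xb)).data)
    return np.concatenate(out, axis=0)


def predict(model: Classifier, records: list[EcgRecord]) -> np.ndarray:
    """Argmax class predictions for a list of preprocessed records."""
    signals = np.stack([r.signal for r in records])
    return np.argmax(_forward_logits(model, signals), axis=1)


def _eval_macro_f1(model: Classifier, records: list[EcgRecord]) -> float:
    true = np.array([int(r.label) for r in records])
    pred = predict(model, records)
    return macro_f1(confusion_matrix(true, pred))


def train_supervised(
    train: list[EcgRecord],
    val: list[EcgRecord],
    test: list[EcgRecord],
    init_state: Optional[dict[str, np.ndarray]] = None,
    cfg: FinetuneConfig = FinetuneConfig(),
    aug: Optional[AugmentationConfig] = None,
    enc_spec: EncoderSpec | None = None,
    group_tag: str = "",
    return_model: bool = False,
):
    """Train encoder + head on ``train``, early-stop on ``val``, report on ``test``.

    ``init_state`` holds pretrained encoder weights and is required when
    ``cfg.init == 'ssl_checkpoint'``.  When ``cfg.downstream_aug`` is true,
    every training record is re-perturbed by the strong augmentation block
    each epoch; validation and test records are never augmented.
    """
    if cfg.init == "ssl_checkpoint" and init_state is None:
        raise ValueError("init='ssl_checkpoint' requires pretrained encoder weights")
    if cfg.downstream_aug and aug is None:
        raise ValueError("downstream_aug=True requires an augmentation config")
    if any(r.label is None for r in train):
        raise ValueError("training records must be labeled")
    train_ids = {r.record_id for r in train}
    leaked = train_ids & {r.record_id for r in test}
    if leaked:
        raise RuntimeError(f"test-set leakage into training ids: {sorted(leaked)[:3]}")

    enc_spec = enc_spec or EncoderSpec()
    ss = np.random.SeedSequence(cfg.seed)
    init_ss, data_ss = ss.spawn(2)
    model = Classifier(enc_spec, np.random.Generator(np.random.PCG64(init_ss)))
    if init_state is not None and cfg.init == "ssl_checkpoint":
        model.encoder.load_state_dict(init_state)
    data_rng = np.random.Generator(np.random.PCG64(data_ss))
    opt = Adam(model.parameters(), lr=cfg.learning_rate)

    signals = np.stack([r.signal for r in train])
    labels = np.array([int(r.label) for r in train])

    stopper = EarlyStopper(cfg.patience)
    val_history: list[float] = []
    best_state: dict[str, np.ndarray] | None = None

    for _ in range(cfg.max_epochs):
        order = data_rng.permutation(len(train))
        if cfg.downstream_aug:
            epoch_signals = np.stack(
                [augment_signal(signals[i], aug, data_rng) for i in order]
            )
        else:
            epoch_signals = signals[order]
        epoch_labels = labels[order]
        for start in range(0, len(train), cfg.batch_size):
            xb = epoch_signals[start : start + cfg.batch_size].astype(np.float32)
            yb = epoch_labels[start : start + cfg.batch_size]
            opt.zero_grad()
            logits = model(Tensor(xb))
            logp = log_softmax(logits, axis=-1)
            loss = -(logp[np.arange(len(yb)), yb].mean())
            loss.backward()
            opt.step()

        metric = _eval_macro_f1(model, val)
        val_history.append(metric)
        improved = metric > stopper.best_metric
        stop = stopper.update(metric)
        if improved:
            best_state = model.state_dict()
        if stop:
            break

    assert best_state is not None
    model.load_state_dict(best_state)
    best_epoch = stopper.best_epoch

    true = np.array([int(r.label) for r in test])
    pred = predict(model, test)
    cm = confusion_matrix(true, pred)
    record = RunRecord(
        seed=cfg.seed,
        val_history=val_history,
        best_epoch=best_epoch,
        test_confusion=cm.counts,
        test_macro_f1=macro_f1(cm),
        test_accuracy=accuracy(cm),
        group_tag=group_tag,
    )
    return (record, model) if return_model else record
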
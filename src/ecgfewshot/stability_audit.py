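"""Evaluation metrics, collapse statistic and the controlled group matrix.

The audit treats training stability as a first-class endpoint: besides test
Macro-F1 and accuracy it records each run's best validation epoch e* and the
group-level collapse rate

    CollapseRate = (1/R) * #{runs with e* <= 1},

the fraction of repeated runs whose validation metric peaked at the very
first epoch — the signature of a degenerate, near-constant predictor.

``run_experiment_matrix`` executes the seven controlled configurations:

    A       300 imbalanced, scratch, no augmentation   (upper-bound reference)
    A'      300 balanced,   scratch, no augmentation   (balanced reference)
    B       300 balanced,   scratch, strong augmentation
    C        70 balanced,   scratch, no augmentation   (few-shot baseline)
    E        70 balanced,   scratch, strong augmentation ("aug only")
    D-Aug    70 balanced,   SSL init, strong augmentation
    D-NoAug  70 balanced,   SSL init, no augmentation  (core setting)

each over R seeds, and aggregates mean +/- SD Macro-F1/accuracy, mean best
epoch and collapse rate per group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "GroupResult",
    "GROUP_DEFINITIONS",
    "confusion_matrix",
    "per_class_prf",
    "macro_f1",
    "accuracy",
    "collapse_rate",
    "majority_baseline_macro_f1",
    "aggregate_group",
    "run_experiment_matrix",
    "results_table",
]

N_CLASSES = 5


@dataclass
class ConfusionMatrix:
    """5x5 count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        cm = np.asarray(self.counts)
        if cm.shape != (N_CLASSES, N_CLASSES) or np.any(cm < 0):
            raise ValueError("counts must be a nonnegative 5x5 matrix")
        if not np.issubdtype(cm.dtype, np.integer):
            if not np.allclose(cm, np.round(cm)):
                raise ValueError("counts must be integers")
            cm = cm.astype(np.int64)
        self.counts = cm

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally counts[i, j] = #(true == i and pred == j) over the five classes."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label arrays must be 1-D and of equal length")
    if t.size and (t.min() < 0 or t.max() >= N_CLASSES or p.min() < 0 or p.max() >= N_CLASSES):
        raise ValueError("labels outside the 5-class set")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def per_class_prf(cm: ConfusionMatrix) -> list[tuple[float, float, float]]:
    """Per-class (precision, recall, F1); any 0/0 is defined as 0."""
    counts = cm.counts
    out = []
    for c in range(N_CLASSES):
        tp = counts[c, c]
        fp = counts[:, c].sum() - tp
        fn = counts[c, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        out.append((float(prec), float(rec), float(f1)))
    return out


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the five per-class F1 scores."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.mean([f1 for _, _, f1 in per_class_prf(cm)]))


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def collapse_rate(best_epochs: Sequence[int], threshold: int = 1) -> float:
    """Fraction of runs whose best validation epoch is <= ``threshold``."""
    epochs = list(best_epochs)
    if not epochs:
        raise ValueError("best_epochs must be non-empty")
    if any(e < 1 for e in epochs):
        raise ValueError("best epochs are 1-based (>= 1)")
    return sum(1 for e in epochs if e <= threshold) / len(epochs)


def majority_baseline_macro_f1(class_distribution) -> float:
    """Macro-F1 of a constant predictor that always emits the majority class.

    For majority fraction p the majority class scores F1 = 2p/(1+p) and all
    other classes 0, so the macro average is 2p / (5 (1+p)).
    """
    dist = np.asarray(class_distribution, dtype=float)
    if abs(dist.sum() - 1.0) > 1e-9 or np.any(dist < 0):
        raise ValueError("class distribution must sum to 1")
    p = float(dist.max())
    return 2 * p / (N_CLASSES * (1 + p))


@dataclass
class GroupResult:
    group_tag: str
    n_labeled: int
    strategy: str
    aug_flag: bool
    macro_f1_mean: float
    macro_f1_sd: float
    acc_mean: float
    acc_sd: float
    best_epoch_mean: float
    collapse_rate: float
    R: int

    def __post_init__(self) -> None:
        if min(self.macro_f1_sd, self.acc_sd) < 0 or not 0 <= self.collapse_rate <= 1:
            raise ValueError("invalid aggregate values")


def _sample_sd(values: np.ndarray) -> float:
    # sample SD (denominator R-1) to match mean +/- SD reporting over seeds
    return float(values.std(ddof=1)) if len(values) > 1 else 0.0


def aggregate_group(runs) -> GroupResult:
    """Aggregate one group's runs over seeds into means, SDs and collapse rate."""
    if not runs:
        raise ValueError("no runs to aggregate")
    tags = {r.group_tag for r in runs}
    if len(tags) != 1:
        raise ValueError(f"mixed group tags: {sorted(tags)}")
    f1s = np.array([r.test_macro_f1 for r in runs])
    accs = np.array([r.test_accuracy for r in runs])
    epochs = [r.best_epoch for r in runs]
    meta = getattr(runs[0], "_group_meta", {})
    return GroupResult(
        group_tag=tags.pop(),
        n_labeled=meta.get("n_labeled", 0),
        strategy=meta.get("strategy", ""),
        aug_flag=meta.get("aug", False),
        macro_f1_mean=float(f1s.mean()),
        macro_f1_sd=_sample_sd(f1s),
        acc_mean=float(accs.mean()),
        acc_sd=_sample_sd(accs),
        best_epoch_mean=float(np.mean(epochs)),
        collapse_rate=collapse_rate(epochs),
        R=len(runs),
    )


# (tag, training split, strategy, downstream augmentation)
GROUP_DEFINITIONS: tuple[tuple[str, str, str, bool], ...] = (
    ("A", "ref", "scratch", False),
    ("A'", "ref_bal", "scratch", False),
    ("B", "ref_bal", "scratch", True),
    ("C", "few", "scratch", False),
    ("E", "few", "scratch", True),
    ("D-Aug", "few", "ssl", True),
    ("D-NoAug", "few", "ssl", False),
)


def run_experiment_matrix(
    splits,
    seeds: Sequence[int],
    base_cfg=None,
    strong_aug=None,
    enc_spec=None,
    ssl_state: Optional[dict[str, np.ndarray]] = None,
    groups: Sequence[str] | None = None,
    progress: Optional[callable] = None,
) -> tuple[list[GroupResult], list]:
    """Run the controlled group matrix over all seeds.

    Returns (group results, all run records).  ``ssl_state`` (pretrained
    encoder weights) is required when any D group is enabled.
    """
    from .augment import DOWNSTREAM_STRONG_DEFAULTS
    from .finetune import FinetuneConfig, train_supervised

    base_cfg = base_cfg or FinetuneConfig()
    strong_aug = strong_aug or DOWNSTREAM_STRONG_DEFAULTS
    defs = [g for g in GROUP_DEFINITIONS if groups is None or g[0] in groups]
    if any(strategy == "ssl" for _, _, strategy, _ in defs) and ssl_state is None:
        raise ValueError("SSL checkpoint required for D groups but none provided")

    split_map = splits.as_dict()
    group_results: list[GroupResult] = []
    all_runs = []
    for tag, split_name, strategy, aug_flag in defs:
        train_set = split_map[split_name]
        runs = []
        for seed in seeds:
            cfg = replace(
                base_cfg,
                seed=int(seed),
                init="ssl_checkpoint" if strategy == "ssl" else "scratch",
                downstream_aug=aug_flag,
            )
            run = train_supervised(
                train_set,
                splits.val,
                splits.test,
                init_state=ssl_state if strategy == "ssl" else None,
                cfg=cfg,
                aug=strong_aug if aug_flag else None,
                enc_spec=enc_spec,
                group_tag=tag,
            )
            run._group_meta = {
                "n_labeled": len(train_set),
                "strategy": strategy,
                "aug": aug_flag,
            }
            runs.append(run)
            if progress is not None:
                progress(tag, seed, run)
        group_results.append(aggregate_group(runs))
        all_runs.extend(runs)
    return group_results, all_runs


def results_table(group_results: list[GroupResult]) -> pd.DataFrame:
    """Render the group matrix in the standard audit layout.

    SDs are sample standard deviations (denominator R-1) over seeds.
    """
    rows = []
    for g in group_results:
        rows.append(
            {
                "group": g.group_tag,
                "N": g.n_labeled,
                "strategy": g.strategy,
                "aug": "enabled" if g.aug_flag else "disabled",
                "macro_f1_mean": round(g.macro_f1_mean, 4),
                "macro_f1_sd": round(g.macro_f1_sd, 4),
                "accuracy_mean": round(g.acc_mean, 4),
                "accuracy_sd": round(g.acc_sd, 4),
                "best_epoch_mean": round(g.best_epoch_mean, 2),
                "collapse_rate": round(g.collapse_rate, 4),
            }
        )
    return pd.DataFrame(rows)
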
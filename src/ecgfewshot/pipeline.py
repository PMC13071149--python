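"""Stage orchestration shared by the CLI and the analysis scripts.

Every stage is a pure function of (config, run directory): splits are
rebuilt deterministically from the config seed, so stages can run in one
process or as separate invocations and still agree bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .config import ExperimentConfig
from .io import load_checkpoint, save_checkpoint, write_manifest, write_run_log
from .preprocess import Splits, build_splits
from .ssl_pretrain import PretrainResult, pretrain
from .stability_audit import GroupResult, results_table, run_experiment_matrix

__all__ = [
    "get_splits",
    "stage_generate",
    "stage_pretrain",
    "stage_matrix",
    "stage_report",
    "run_all",
    "checkpoint_path",
]

logger = logging.getLogger(__name__)


def checkpoint_path(cfg: ExperimentConfig) -> Path:
    return Path(cfg.run_dir) / "encoder_checkpoint.npz"


def get_splits(cfg: ExperimentConfig) -> Splits:
    return build_splits(cfg.split_spec)


def _timed(name: str, fn):
    t0 = time.time()
    out = fn()
    logger.info("stage %s finished in %.1f s", name, time.time() - t0)
    return out


def stage_generate(cfg: ExperimentConfig) -> Splits:
    """Build all splits and write the dataset manifest."""
    splits = _timed("generate", lambda: get_splits(cfg))
    run_dir = Path(cfg.run_dir)
    write_manifest(splits, run_dir / "manifest.csv")
    (run_dir / "config_hash.txt").write_text(cfg.config_hash() + "\n")
    return splits


def stage_pretrain(cfg: ExperimentConfig, splits: Splits | None = None) -> PretrainResult:
    """Contrastive pretraining on the unlabeled pool; writes the checkpoint."""
    splits = splits or get_splits(cfg)
    result = _timed(
        "pretrain",
        lambda: pretrain(
            splits.unlabeled,
            enc_spec=cfg.encoder_spec,
            proj_spec=cfg.projection_spec,
            aug=cfg.ssl_views,
            cfg=cfg.pretrain,
        ),
    )
    save_checkpoint(checkpoint_path(cfg), result, cfg.config_hash())
    # loss history CSV (epoch, mean_loss)
    hist = "\n".join(f"{i+1},{v:.6f}" for i, v in enumerate(result.loss_history))
    (Path(cfg.run_dir) / "pretrain_loss.csv").write_text("epoch,mean_loss\n" + hist + "\n")
    return result


def stage_matrix(
    cfg: ExperimentConfig, splits: Splits | None = None, progress=None
) -> tuple[list[GroupResult], list]:
    """Run the controlled group matrix; writes per-run logs and the table."""
    splits = splits or get_splits(cfg)
    needs_ssl = any(g.startswith("D") for g in cfg.groups)
    ssl_state = None
    if needs_ssl:
        ckpt = checkpoint_path(cfg)
        if not ckpt.exists():
            raise FileNotFoundError(
                f"D groups enabled but no SSL checkpoint at {ckpt}; run pretrain first"
            )
        ssl_state, ckpt_spec, _ = load_checkpoint(ckpt)
        if ckpt_spec != cfg.encoder_spec:
            raise ValueError("checkpoint encoder architecture differs from config")

    def run():
        return run_experiment_matrix(
            splits,
            seeds=cfg.run_seeds(),
            base_cfg=cfg.finetune,
            strong_aug=cfg.downstream_strong,
            enc_spec=cfg.encoder_spec,
            ssl_state=ssl_state,
            groups=cfg.groups,
            progress=progress,
        )

    group_results, runs = _timed("matrix", run)
    run_dir = Path(cfg.run_dir)
    for r in runs:
        write_run_log(
            r, run_dir / "runs" / f"{r.group_tag}_seed{r.seed}.json", cfg.config_hash()
        )
        np.savetxt(
            run_dir / "runs" / f"{r.group_tag}_seed{r.seed}_confusion.csv",
            np.asarray(r.test_confusion),
            fmt="%d",
            delimiter=",",
        )
    table = results_table(group_results)
    table.to_csv(run_dir / "results_table.csv", index=False)
    return group_results, runs


def stage_report(cfg: ExperimentConfig, group_results: list[GroupResult]) -> str:
    """Render the results table and a per-group JSON summary."""
    table = results_table(group_results)
    text = table.to_string(index=False)
    run_dir = Path(cfg.run_dir)
    (run_dir / "results_table.txt").write_text(text + "\n")
    summary = {
        g.group_tag: {
            "macro_f1_mean": g.macro_f1_mean,
            "macro_f1_sd": g.macro_f1_sd,
            "accuracy_mean": g.acc_mean,
            "accuracy_sd": g.acc_sd,
            "best_epoch_mean": g.best_epoch_mean,
            "collapse_rate": g.collapse_rate,
            "R": g.R,
        }
        for g in group_results
    }
    (run_dir / "group_summary.json").write_text(json.dumps(summary, indent=1))
    return text


def run_all(cfg: ExperimentConfig, progress=None) -> tuple[list[GroupResult], list]:
    """generate -> pretrain -> matrix -> report, chained on shared splits."""
    Path(cfg.run_dir).mkdir(parents=True, exist_ok=True)
    splits = stage_generate(cfg)
    if any(g.startswith("D") for g in cfg.groups):
        stage_pretrain(cfg, splits)
    group_results, runs = stage_matrix(cfg, splits, progress=progress)
    stage_report(cfg, group_results)
    return group_results, runs
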
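"""Artifact I/O: record files, split manifests, checkpoints, run logs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import EncoderSpec
from .synthetic_ecg import EcgRecord, RhythmClass

__all__ = [
    "save_record",
    "load_record",
    "write_manifest",
    "save_checkpoint",
    "load_checkpoint",
    "write_run_log",
]


def save_record(rec: EcgRecord, directory: str | Path) -> Path:
    """Write one record as a raw float32 array plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bin_path = directory / f"{rec.record_id}.f32"
    rec.signal.astype(np.float32).tofile(bin_path)
    sidecar = {
        "record_id": rec.record_id,
        "fs": rec.fs,
        "duration_s": rec.duration_s,
        "label": rec.label.name if rec.label is not None else None,
        "n_leads": rec.signal.shape[0],
    }
    (directory / f"{rec.record_id}.json").write_text(json.dumps(sidecar))
    return bin_path


def load_record(directory: str | Path, record_id: str) -> EcgRecord:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{record_id}.json").read_text())
    n_leads = sidecar.get("n_leads", 12)
    signal = np.fromfile(directory / f"{record_id}.f32", dtype=np.float32)
    signal = signal.reshape(n_leads, -1).astype(np.float64)
    label = sidecar["label"]
    return EcgRecord(
        signal=signal,
        fs=sidecar["fs"],
        duration_s=sidecar["duration_s"],
        label=RhythmClass[label] if label is not None else None,
        record_id=sidecar["record_id"],
    )


def write_manifest(splits, path: str | Path) -> pd.DataFrame:
    """Dataset manifest CSV: record_id, label, split."""
    rows = []
    for split_name, records in splits.as_dict().items():
        for r in records:
            rows.append(
                {
                    "record_id": r.record_id,
                    "label": r.label.name if r.label is not None else "",
                    "split": split_name,
                }
            )
    df = pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


def save_checkpoint(path: str | Path, result, config_hash: str = "") -> None:
    """Encoder checkpoint: weights plus an architecture/config echo."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "encoder_spec": asdict(result.encoder_spec),
        "config_hash": config_hash,
        "loss_history": list(result.loss_history),
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **result.encoder_state,
    )


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], EncoderSpec, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec_dict = meta["encoder_spec"]
    spec_dict["conv_blocks"] = tuple(tuple(b) for b in spec_dict["conv_blocks"])
    spec = EncoderSpec(**spec_dict)
    return state, spec, meta


def write_run_log(run, path: str | Path, config_hash: str = "") -> None:
    """Per-run JSON log with the full validation trajectory and test outcome."""
    payload = {
        "group_tag": run.group_tag,
        "seed": run.seed,
        "config_hash": config_hash,
        "val_history": [float(v) for v in run.val_history],
        "best_epoch": int(run.best_epoch),
        "test_macro_f1": float(run.test_macro_f1),
        "test_accuracy": float(run.test_accuracy),
        "confusion_matrix": np.asarray(run.test_confusion).tolist(),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))
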
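"""Optional PTB-XL adapter: read WFDB records into :class:`EcgRecord`.

Maps a PTB-XL-layout directory (500 Hz WFDB record/header pairs plus the
``ptbxl_database.csv`` metadata file) onto the package's record type,
keeping only the five single-label rhythm classes.  Requires the ``wfdb``
package, which is an optional dependency; everything else in the package
runs without it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_ecg import EcgRecord, RhythmClass

__all__ = ["load_ptbxl_rhythm_records"]

_RHYTHM_CODES = {c.name for c in RhythmClass}


def _require_wfdb():
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the PTB-XL adapter needs the optional 'wfdb' package "
            "(pip install wfdb); synthetic mode does not"
        ) from exc
    return wfdb


def load_ptbxl_rhythm_records(
    root: str | Path,
    max_records: int | None = None,
    sampling_rate: int = 500,
) -> list[EcgRecord]:
    """Load PTB-XL records carrying exactly one of the five rhythm labels.

    ``root`` is the dataset directory containing ``ptbxl_database.csv`` and
    the ``records500``/``records100`` trees.  Records whose SCP codes name
    more than one rhythm class, or none, are skipped (single-label task).
    """
    wfdb = _require_wfdb()
    root = Path(root)
    meta = pd.read_csv(root / "ptbxl_database.csv", index_col="ecg_id")
    filename_col = "filename_hr" if sampling_rate == 500 else "filename_lr"

    records: list[EcgRecord] = []
    for ecg_id, row in meta.iterrows():
        codes = set(eval(row.scp_codes, {"__builtins__": {}}, {})) & _RHYTHM_CODES
        if len(codes) != 1:
            continue
        label = RhythmClass[codes.pop()]
        signal, fields = wfdb.rdsamp(str(root / row[filename_col]))
        records.append(
            EcgRecord(
                signal=np.asarray(signal).T,
                fs=float(fields["fs"]),
                duration_s=signal.shape[0] / fields["fs"],
                label=label,
                record_id=f"ptbxl-{ecg_id}",
            )
        )
        if max_records is not None and len(records) >= max_records:
            break
    return records
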
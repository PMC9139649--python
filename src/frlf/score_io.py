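"""Readers/writers for the on-disk score and label formats.

Score matrices travel as long-form CSV with columns ``sample_id``,
``model_id``, then one column per class score, or as an equivalent JSON
records layout (one record per sample/model row).  Both round-trip
losslessly.  Labels and predictions use two-column CSV
(``sample_id, label``); split manifests add a ``partition`` column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Hashable, Sequence

import pandas as pd

from .fusion_core import InvalidScoreError, ScoreMatrix

__all__ = [
    "read_scores_csv",
    "write_scores_csv",
    "read_scores_json",
    "write_scores_json",
    "read_scores",
    "read_labels_csv",
    "write_labels_csv",
    "write_split_manifest",
]

_META_COLS = ("sample_id", "model_id")


def _samples_to_frame(sample_ids: Sequence[str], samples: Sequence[ScoreMatrix]) -> pd.DataFrame:
    if len(sample_ids) != len(samples):
        raise ValueError("one sample_id per ScoreMatrix required")
    rows = []
    for sid, sm in zip(sample_ids, samples):
        for i, mid in enumerate(sm.model_ids):
            rec = {"sample_id": sid, "model_id": mid}
            rec.update({cid: sm.scores[i, j] for j, cid in enumerate(sm.class_ids)})
            rows.append(rec)
    return pd.DataFrame(rows)


def _frame_to_samples(df: pd.DataFrame) -> tuple[list[str], list[ScoreMatrix]]:
    for col in _META_COLS:
        if col not in df.columns:
            raise InvalidScoreError(f"score table is missing required column {col!r}")
    class_cols = [c for c in df.columns if c not in _META_COLS]
    if len(class_cols) < 2:
        raise InvalidScoreError("score table needs at least two class columns")
    if df.empty:
        return [], []
    sample_ids: list[str] = []
    samples: list[ScoreMatrix] = []
    # groupby(sort=False) preserves first-appearance order of samples
    for sid, grp in df.groupby("sample_id", sort=False):
        model_ids = [str(m) for m in grp["model_id"]]
        scores = grp[class_cols].to_numpy(dtype=float)
        samples.append(ScoreMatrix(scores, model_ids, [str(c) for c in class_cols]))
        sample_ids.append(str(sid))
    return sample_ids, samples


def write_scores_csv(path: str | Path, sample_ids: Sequence[str],
                     samples: Sequence[ScoreMatrix]) -> None:
    # %.17g keeps the round-trip bit-exact for doubles
    _samples_to_frame(sample_ids, samples).to_csv(path, index=False, float_format="%.17g")


def read_scores_csv(path: str | Path) -> tuple[list[str], list[ScoreMatrix]]:
    # round_trip parsing: pandas' fast path can be 1 ulp off
    return _frame_to_samples(pd.read_csv(path, float_precision="round_trip"))


def write_scores_json(path: str | Path, sample_ids: Sequence[str],
                      samples: Sequence[ScoreMatrix]) -> None:
    df = _samples_to_frame(sample_ids, samples)
    Path(path).write_text(json.dumps(df.to_dict(orient="records"), indent=1))


def read_scores_json(path: str | Path) -> tuple[list[str], list[ScoreMatrix]]:
    records = json.loads(Path(path).read_text())
    return _frame_to_samples(pd.DataFrame.from_records(records))


def read_scores(path: str | Path) -> tuple[list[str], list[ScoreMatrix]]:
    """Dispatch on extension: .json -> JSON records, otherwise CSV."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        return read_scores_json(p)
    return read_scores_csv(p)


def write_labels_csv(path: str | Path, pairs: Sequence[tuple[Hashable, Hashable]]) -> None:
    pd.DataFrame(pairs, columns=["sample_id", "label"]).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ValueError(f"label file is missing required column {col!r}")
    return dict(zip(df["sample_id"], df["label"]))


def write_split_manifest(
    path: str | Path,
    train: Sequence[tuple[Hashable, Hashable]],
    test: Sequence[tuple[Hashable, Hashable]],
) -> None:
    rows = [(sid, lab, "train") for sid, lab in train]
    rows += [(sid, lab, "test") for sid, lab in test]
    pd.DataFrame(rows, columns=["sample_id", "label", "partition"]).to_csv(path, index=False)
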
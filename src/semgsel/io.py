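"""Readers and writers for the pipeline's text formats.

Recordings travel as CSV (one row per sample, one column per channel,
optional label/segment columns); feature matrices as TSV with a
"channel:feature" row index plus a JSON sidecar; variable sets and
co-occurrence matrices as TSV; reports and manifests as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix, Recording, WindowSpec
from .fusion import CooccurrenceMatrix
from .varset import VariableSet

LABEL_COL = "label"
SEGMENT_COL = "segment"


def _maybe_int(x):
    try:
        return int(x)
    except (TypeError, ValueError):
        return x


# -- recordings -------------------------------------------------------------


def write_recording_csv(rec: Recording, path) -> None:
    df = pd.DataFrame(rec.samples,
                      columns=[str(c) for c in rec.channel_ids])
    df[LABEL_COL] = rec.labels
    if rec.segments is not None:
        df[SEGMENT_COL] = rec.segments
    df.to_csv(path, index=False)


def read_recording_csv(path, sampling_rate: float) -> Recording:
    df = pd.read_csv(path)
    if LABEL_COL not in df.columns:
        raise ValueError(f"recording CSV needs a '{LABEL_COL}' column")
    labels = df.pop(LABEL_COL).to_numpy()
    segments = df.pop(SEGMENT_COL).to_numpy() if SEGMENT_COL in df.columns \
        else None
    channel_ids = tuple(_maybe_int(c) for c in df.columns)
    return Recording(samples=df.to_numpy(dtype=float),
                     sampling_rate=sampling_rate, labels=labels,
                     channel_ids=channel_ids, segments=segments)


def read_window_labels(path) -> pd.DataFrame:
    """Window-label table: columns window_start, window_end, label."""
    df = pd.read_csv(path, sep=None, engine="python")
    need = {"window_start", "window_end", "label"}
    if not need.issubset(df.columns):
        raise ValueError(f"window-label file needs columns {sorted(need)}")
    return df


# -- feature matrices -------------------------------------------------------


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """TSV with rows "channel:feature" + JSON sidecar (<path>.json)."""
    path = Path(path)
    fm.to_dataframe().to_csv(path, sep="\t", index_label="variable")
    sidecar = {
        "col_labels": [str(x) for x in fm.col_labels],
        "standardization": fm.standardization,
        "window_spec": asdict(fm.window_spec) if fm.window_spec else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))


def read_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="variable")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    row_index = tuple(
        (_maybe_int(s.split(":", 1)[0]), s.split(":", 1)[1])
        for s in df.index)
    labels = np.asarray([_maybe_int(x) for x in sidecar["col_labels"]])
    ws = sidecar.get("window_spec")
    return FeatureMatrix(values=df.to_numpy(dtype=float),
                         row_index=row_index, col_labels=labels,
                         standardization=sidecar.get("standardization"),
                         window_spec=WindowSpec(**ws) if ws else None)


# -- variable sets ----------------------------------------------------------


def write_variable_set(vs: VariableSet, path) -> None:
    rows = [{"rank": i + 1, "channel": ch, "feature": ft,
             "score": vs.scores[i] if vs.scores else ""}
            for i, (ch, ft) in enumerate(vs.pairs)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variable_set(path, method: str) -> VariableSet:
    df = pd.read_csv(path, sep="\t").sort_values("rank")
    pairs = tuple((_maybe_int(ch), ft)
                  for ch, ft in zip(df["channel"], df["feature"]))
    scores = ()
    if "score" in df.columns and df["score"].notna().all() \
            and (df["score"].astype(str) != "").all():
        scores = tuple(float(s) for s in df["score"])
    return VariableSet(pairs=pairs, method=method, scores=scores)


# -- co-occurrence matrices -------------------------------------------------


def write_cooccurrence(coocc: CooccurrenceMatrix, path) -> None:
    coocc.to_dataframe().to_csv(path, sep="\t", index_label="channel")


def read_cooccurrence(path, method: str) -> CooccurrenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="channel")
    df = df.drop(index="Sum", errors="ignore")
    channels = tuple(_maybe_int(c) for c in df.columns)
    return CooccurrenceMatrix(counts=df.to_numpy(dtype=int),
                              channels=channels, method=method)


# -- JSON helpers -----------------------------------------------------------


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset, tuple)):
        return list(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")
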
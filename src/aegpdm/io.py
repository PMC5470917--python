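"""Sensor CSV dialect, label/detection/latent CSV artifacts.

The sensor dialect has the header ``t,u1_ax,u1_ay,u1_az,u1_wx,u1_wy,u1_wz,
u2_ax,...,u2_wz`` with one row per frame (accelerations in g, angular
velocities in rad/s, time in seconds).  Lines starting with ``#`` are
metadata comments; every file this module writes embeds the generating
seed/configuration hash in such a comment so a run can be traced to its
inputs.  Floats are written with repr-exact precision, making re-runs with
identical inputs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureSeries, assemble_series
from .novelty import DetectionResult, ScoreGrid

__all__ = [
    "SENSOR_COLUMNS",
    "read_sensor_csv",
    "write_sensor_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_detection_csv",
    "write_latent_csv",
    "write_grid_csv",
    "write_trace_csv",
]

SENSOR_COLUMNS = ["t"] + [
    f"u{u}_{c}" for u in (1, 2) for c in ("ax", "ay", "az", "wx", "wy", "wz")
]

_FMT = "%.17g"


def _meta_comment(meta: dict | None) -> str:
    meta = dict(meta or {})
    blob = json.dumps(meta, sort_keys=True)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:16]
    return f"# aegpdm meta={blob} hash={digest}\n"


def _write_frame(path, df: pd.DataFrame, meta: dict | None) -> None:
    with open(path, "w", newline="") as f:
        f.write(_meta_comment(meta))
        df.to_csv(f, index=False, float_format=_FMT)


def write_sensor_csv(path, t, raw, meta: dict | None = None) -> None:
    """Write raw two-unit frames in the documented sensor dialect."""
    raw = np.asarray(raw, dtype=float)
    df = pd.DataFrame(
        np.column_stack([np.asarray(t, dtype=float), raw]),
        columns=SENSOR_COLUMNS,
    )
    _write_frame(path, df, meta)


def read_sensor_csv(path):
    """Parse a sensor CSV into (t, FeatureSeries) via feature assembly.

    Raises a parse error naming the offending column or row for missing
    columns, non-numeric cells and non-monotone timestamps.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df[SENSOR_COLUMNS]
    for c in SENSOR_COLUMNS:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(col.isna().to_numpy())
        if bad.size:
            raise ValueError(
                f"{path}: non-numeric value in column {c!r}, row {bad[0]}"
            )
        df[c] = col
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"{path}: non-monotone time at row {row}")
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 10.0
    raw = df[SENSOR_COLUMNS[1:]].to_numpy(dtype=float)
    return t, assemble_series(raw, rate=rate, t=t)


def write_labels_csv(path, labels, meta: dict | None = None) -> None:
    df = pd.DataFrame({"frame": np.arange(len(labels)), "label": labels})
    _write_frame(path, df, meta)


def read_labels_csv(path) -> np.ndarray:
    return pd.read_csv(path, comment="#")["label"].to_numpy(dtype=object)


def write_detection_csv(path, result: DetectionResult,
                        meta: dict | None = None) -> None:
    """Detection report: ``frame,score,flag`` plus alarm metadata."""
    meta = dict(meta or {})
    meta["threshold"] = result.threshold
    meta["alarm_frame"] = result.alarm_frame
    df = pd.DataFrame({
        "frame": np.arange(len(result.scores)),
        "score": result.scores,
        "flag": result.flags.astype(int),
    })
    _write_frame(path, df, meta)


def write_latent_csv(path, mean, var=None, meta: dict | None = None) -> None:
    mean = np.asarray(mean, dtype=float)
    data = {"frame": np.arange(mean.shape[0])}
    for j in range(mean.shape[1]):
        data[f"x{j + 1}"] = mean[:, j]
    if var is not None:
        var = np.asarray(var, dtype=float)
        for j in range(var.shape[1]):
            data[f"s{j + 1}"] = var[:, j]
    _write_frame(path, pd.DataFrame(data), meta)


def write_grid_csv(path, grid: ScoreGrid, meta: dict | None = None) -> None:
    """Dense score matrix; first row/column hold the axis coordinates."""
    body = np.full((grid.scores.shape[0] + 1, grid.scores.shape[1] + 1), np.nan)
    body[0, 1:] = grid.x
    body[1:, 0] = grid.y
    body[1:, 1:] = grid.scores
    with open(path, "w", newline="") as f:
        f.write(_meta_comment(meta))
        np.savetxt(f, body, delimiter=",", fmt=_FMT)


def write_trace_csv(path, trace: dict, meta: dict | None = None) -> None:
    _write_frame(path, pd.DataFrame(trace), meta)
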
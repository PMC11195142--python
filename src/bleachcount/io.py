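"""File round-tripping: trace CSV, legacy binary traces, step TSV, JSON reports.

Dialects
--------
Trace CSV: header ``time,<id1>,<id2>,...``; one row per frame; time in
seconds at a fixed interval.

Legacy binary (little-endian): int32 frame count F, int16 trace count T,
then F x T int16 intensities in trace-major order.  Auto-detected by the
``.dat``/``.bin`` extension, overridable.

Step TSV: columns trace_id, n_steps, status, changepoints (semicolon-joined
frame indices).

Reports are JSON with any timestamps kept outside the comparable payload, so
two runs with the same seed produce byte-identical payloads.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .steps import IntensityTrace, StepCall

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_traces_binary",
    "read_traces_binary",
    "read_traces",
    "write_step_calls",
    "read_step_counts",
    "write_json_report",
    "load_config_file",
]

_BINARY_SUFFIXES = {".dat", ".bin"}


def write_traces_csv(traces: Sequence[IntensityTrace], path: str | Path) -> None:
    if not traces:
        raise ValueError("no traces to write")
    interval = traces[0].frame_interval
    n = traces[0].n_frames
    for t in traces:
        if t.n_frames != n or t.frame_interval != interval:
            raise ValueError("all traces in one file must share frame count and interval")
    columns = {"time": np.round(np.arange(n) * interval, 9)}
    columns.update((t.trace_id, t.intensities) for t in traces)
    pd.DataFrame(columns).to_csv(path, index=False, float_format="%.6f")


def read_traces_csv(path: str | Path) -> list[IntensityTrace]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trace file") from None
    if df.shape[1] < 2 or df.columns[0] != "time":
        raise ValueError(
            f"{path}: line 1: malformed header, expected 'time,<trace_id>,...', "
            f"got {','.join(map(str, df.columns[:3]))}..."
        )
    if len(df) == 0:
        raise ValueError(f"{path}: no frames")
    time = df["time"].to_numpy(float)
    if len(time) > 1:
        dt = np.diff(time)
        if np.any(dt <= 0) or np.ptp(dt) > 1e-6:
            raise ValueError(f"{path}: time column must increase at a fixed interval")
        interval = float(dt.mean())
    else:
        interval = 0.1
    return [
        IntensityTrace(df[c].to_numpy(float), frame_interval=interval, trace_id=str(c))
        for c in df.columns[1:]
    ]


def write_traces_binary(traces: Sequence[IntensityTrace], path: str | Path) -> None:
    """Legacy dialect; intensities are rounded to the nearest int16."""
    if not traces:
        raise ValueError("no traces to write")
    n = traces[0].n_frames
    data = np.vstack([t.intensities for t in traces])
    if np.any(np.abs(data) > np.iinfo(np.int16).max):
        raise ValueError("intensities exceed the int16 range of the legacy dialect")
    with open(path, "wb") as fh:
        fh.write(struct.pack("<i", n))
        fh.write(struct.pack("<h", len(traces)))
        fh.write(np.rint(data).astype("<i2").tobytes())


def read_traces_binary(path: str | Path, frame_interval: float = 0.1) -> list[IntensityTrace]:
    raw = Path(path).read_bytes()
    if len(raw) < 6:
        raise ValueError(f"{path}: truncated header at byte {len(raw)} (need 6 bytes)")
    n_frames = struct.unpack_from("<i", raw, 0)[0]
    n_traces = struct.unpack_from("<h", raw, 4)[0]
    expected = 6 + 2 * n_frames * n_traces
    if n_frames <= 0 or n_traces <= 0 or len(raw) < expected:
        raise ValueError(
            f"{path}: truncated payload at byte {len(raw)}, expected {expected} bytes "
            f"for {n_traces} traces x {n_frames} frames"
        )
    data = np.frombuffer(raw, dtype="<i2", count=n_frames * n_traces, offset=6)
    data = data.reshape(n_traces, n_frames).astype(float)
    return [
        IntensityTrace(row, frame_interval=frame_interval, trace_id=f"trace{i:05d}")
        for i, row in enumerate(data)
    ]


def read_traces(path: str | Path, dialect: str = "auto") -> list[IntensityTrace]:
    """Read traces, auto-detecting CSV vs legacy binary by extension."""
    path = Path(path)
    if dialect == "auto":
        dialect = "binary" if path.suffix.lower() in _BINARY_SUFFIXES else "csv"
    if dialect == "binary":
        return read_traces_binary(path)
    if dialect == "csv":
        return read_traces_csv(path)
    raise ValueError(f"unknown trace dialect {dialect!r}")


def write_step_calls(calls: Iterable[StepCall], path: str | Path) -> None:
    rows = [
        {
            "trace_id": c.trace_id,
            "n_steps": c.n_steps,
            "status": c.status,
            "changepoints": ";".join(str(f) for f in c.changepoint_frames),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["trace_id", "n_steps", "status", "changepoints"]).to_csv(
        path, sep="\t", index=False
    )


def read_step_counts(path: str | Path) -> tuple[int, int, int]:
    """Tally (n1, n2, n3+) from a step TSV or a two-column ``w<TAB>count`` file.

    A per-trace step TSV (from the detector) is tallied over accepted calls;
    a pre-tallied file maps each step category w = 1..3 to its count.
    """
    df = pd.read_csv(path, sep="\t")
    if {"n_steps", "status"}.issubset(df.columns):
        acc = df[df["status"] == "accepted"]["n_steps"].to_numpy(int)
        return int((acc == 1).sum()), int((acc == 2).sum()), int((acc >= 3).sum())
    if {"w", "count"}.issubset(df.columns):
        tally = dict(zip(df["w"].astype(int), df["count"].astype(int)))
        if not set(tally) <= {1, 2, 3}:
            raise ValueError(f"{path}: step categories must be w in {{1, 2, 3}}")
        return tally.get(1, 0), tally.get(2, 0), tally.get(3, 0)
    raise ValueError(
        f"{path}: expected columns (n_steps, status) or (w, count), got {list(df.columns)}"
    )


def write_json_report(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_config_file(path: str | Path) -> dict:
    """Structured run configuration: YAML key-value, nested by module."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of module -> options")
    return cfg
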
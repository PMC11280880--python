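"""Readers and writers for accelerometer streams.

Two on-disk formats are supported: a generic CSV (header
``timestamp,ax,ay,az[,label]``) and the raw WISDM smartwatch text format
(``user,activity_code,timestamp,x,y,z;`` per line).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .preprocess import RawSeries

#: default mapping of WISDM activity codes onto the three target classes;
#: codes not listed are dropped.  A = walking, B = jogging, D = sitting,
#: E = standing.
DEFAULT_WISDM_CODE_MAP: dict[str, str] = {
    "D": "sedentary",
    "E": "sedentary",
    "A": "moderately_active",
    "B": "active",
}


def read_csv(path, class_map: Mapping[str, str] | None = None) -> RawSeries:
    """Read a generic accelerometer CSV into a :class:`RawSeries`.

    ``class_map`` optionally remaps label values; unmapped labels pass
    through unchanged.  Raises :class:`ParseError` with line context on
    malformed input.
    """
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise ParseError(f"{path}: {err}") from err
    required = ("timestamp", "ax", "ay", "az")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at line {line}"
            )
    labels = None
    if "label" in df.columns:
        vals = []
        for v in df["label"]:
            if pd.isna(v) or v == "":
                vals.append(None)
            else:
                v = str(v)
                vals.append(class_map.get(v, v) if class_map else v)
        labels = np.asarray(vals, dtype=object)
    return RawSeries(
        xyz=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        timestamps=df["timestamp"].to_numpy(dtype=float),
        labels=labels,
    )


def write_csv(raw: RawSeries, path) -> None:
    """Write a :class:`RawSeries` in the generic CSV format (deterministic
    text: fixed float formatting)."""
    n = len(raw)
    data = {
        "timestamp": (
            raw.timestamps
            if raw.timestamps is not None
            else np.arange(n, dtype=float)
        ),
        "ax": raw.xyz[:, 0],
        "ay": raw.xyz[:, 1],
        "az": raw.xyz[:, 2],
    }
    df = pd.DataFrame(data)
    if raw.labels is not None:
        df["label"] = ["" if l is None else l for l in raw.labels]
    df.to_csv(path, index=False, float_format="%.9g")


def read_wisdm(
    path,
    code_map: Mapping[str, str] | None = None,
    timestamp_scale: float = 1e-9,
) -> dict[str, RawSeries]:
    """Parse the raw WISDM text format into one series per subject.

    Lines look like ``1600,A,252207666810782,-0.36,8.13,1.05;``.  The
    trailing ';' is stripped, activity codes are mapped to classes via
    ``code_map`` (codes absent from the map are dropped), and timestamps
    (nanosecond ticks by default) are rebased to seconds from each subject's
    first sample.  Duplicate or non-increasing timestamps within a subject
    are replaced by a uniform sample index to keep the series valid.
    """
    code_map = dict(DEFAULT_WISDM_CODE_MAP if code_map is None else code_map)
    per_user: dict[str, list[tuple[float, float, float, float, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().rstrip(";")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 6:
                raise ParseError(
                    f"{path}: expected 6 comma-separated fields at line {lineno}"
                )
            user, code, ts, x, y, z = parts
            if code not in code_map:
                continue
            try:
                row = (float(ts), float(x), float(y), float(z), code_map[code])
            except ValueError as err:
                raise ParseError(f"{path}: bad numeric field at line {lineno}") from err
            per_user.setdefault(user, []).append(row)
    out: dict[str, RawSeries] = {}
    for user, rows in per_user.items():
        rows.sort(key=lambda r: r[0])
        ts = np.asarray([r[0] for r in rows], dtype=float)
        ts = (ts - ts[0]) * timestamp_scale
        if np.any(np.diff(ts) <= 0):
            ts = np.arange(len(rows), dtype=float)
        out[user] = RawSeries(
            xyz=np.asarray([[r[1], r[2], r[3]] for r in rows], dtype=float),
            timestamps=ts,
            labels=np.asarray([r[4] for r in rows], dtype=object),
        )
    return out
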
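"""Read and write keypoint-sequence tables (CSV and JSONL).

The CSV layout mirrors the conventional flat export of MediaPipe Pose runs:
an ``Index`` column numbering clips (1-based), a ``Frame`` column numbering
frames within the recording (1-based, strictly increasing within a clip),
then ``{i}_{axis}_({Name})`` columns for each of the 33 landmarks and axes
x/y/z (optionally a visibility axis ``v``), optional precomputed speed
columns, and a trailing ``Y`` label column.

JSONL stores one frame per line as a nested record carrying ``clip_id``,
``label``, ``fps`` and per-landmark dictionaries; it is the lossless,
self-describing dialect.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    CLASS_VOCABULARY,
    LANDMARK_NAMES,
    N_LANDMARKS,
    Clip,
    ClipDataset,
    Landmark,
    PoseFrame,
    validate_dataset,
)

#: Recognized precomputed speed columns, in canonical order. The first three
#: match the common three-speed table layout; the nose speed is accepted when
#: a pipeline was configured to emit it.
SPEED_COLUMNS: tuple[str, ...] = (
    "Central_Body_Speed",
    "Left_Knee_Speed",
    "Right_Knee_Speed",
    "Nose_Speed",
)


class SchemaError(ValueError):
    """Header does not match the expected landmark-table layout."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries the row number."""


class ValidationError(ValueError):
    """Structurally parsed data violates a dataset invariant."""


def landmark_column(index: int, axis: str) -> str:
    return f"{index}_{axis}_({LANDMARK_NAMES[index]})"


def coordinate_columns(include_visibility: bool = False) -> list[str]:
    axes = ("x", "y", "z", "v") if include_visibility else ("x", "y", "z")
    return [landmark_column(i, ax) for i in range(N_LANDMARKS) for ax in axes]


def _check_header(columns: list[str]) -> tuple[bool, list[str]]:
    """Verify landmark columns; return (has_visibility, speed columns present)."""
    colset = {}
    for c in columns:
        colset[c] = colset.get(c, 0) + 1
    dups = [c for c, n in colset.items() if n > 1]
    if dups:
        raise SchemaError(f"duplicate column(s): {', '.join(sorted(dups))}")
    missing = [c for c in coordinate_columns() if c not in colset]
    if missing:
        raise SchemaError(f"missing landmark column(s): {', '.join(missing)}")
    vis_cols = [landmark_column(i, "v") for i in range(N_LANDMARKS)]
    n_vis = sum(c in colset for c in vis_cols)
    if n_vis not in (0, N_LANDMARKS):
        missing_vis = [c for c in vis_cols if c not in colset]
        raise SchemaError(f"partial visibility columns; missing: {', '.join(missing_vis)}")
    speeds = [c for c in SPEED_COLUMNS if c in colset]
    return n_vis == N_LANDMARKS, speeds


def _numeric(df: pd.DataFrame, col: str) -> np.ndarray:
    series = df[col]
    if series.dtype == object:
        coerced = pd.to_numeric(series, errors="coerce")
        bad = coerced.isna() & series.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric value {series.iloc[row]!r} in column {col!r} at data row {row + 1}")
        series = coerced
    return series.to_numpy(dtype=float)


def read_keypoint_table(path: str | Path, dialect: str = "csv") -> ClipDataset:
    """Load a keypoint table into a :class:`ClipDataset`.

    Rows are grouped by clip index and ordered by frame number regardless of
    their order in the file.  Precomputed speed columns, when present, are
    preserved on each clip's ``precomputed_speeds`` (they may be recomputed
    downstream).  Raises :class:`SchemaError`, :class:`ParseError` or
    :class:`ValidationError` as appropriate.
    """
    path = Path(path)
    if dialect == "csv":
        ds = _read_csv(path)
    elif dialect == "jsonl":
        ds = _read_jsonl(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    problems = validate_dataset(ds)
    if problems:
        raise ValidationError("; ".join(str(p) for p in problems[:10]))
    return ds


def _read_csv(path: Path) -> ClipDataset:
    import csv as _csv

    with open(path, encoding="utf-8") as fh:
        header = next(_csv.reader(fh))  # pandas mangles duplicate headers, so check the raw row
    has_vis, speed_cols = _check_header(header)
    df = pd.read_csv(path)
    for required in ("Index", "Frame", "Y"):
        if required not in df.columns:
            raise SchemaError(f"missing column {required!r}")

    # Clip index and label may be written only on a clip's first row.
    df["Index"] = df["Index"].ffill()
    df["Y"] = df.groupby("Index")["Y"].transform(lambda s: s.ffill().bfill())

    frame_no = _numeric(df, "Frame").astype(int)
    coord = np.stack([_numeric(df, c) for c in coordinate_columns()], axis=1)
    coord = coord.reshape(len(df), N_LANDMARKS, 3)
    if has_vis:
        vis = np.stack([_numeric(df, landmark_column(i, "v")) for i in range(N_LANDMARKS)], axis=1)
    else:
        vis = np.ones((len(df), N_LANDMARKS))
    speeds = {c: _numeric(df, c) for c in speed_cols}

    clips: list[Clip] = []
    for clip_key, rows in df.groupby("Index", sort=True):
        idx = np.asarray(rows.index)
        order = np.argsort(frame_no[idx], kind="stable")
        idx = idx[order]
        frames = [
            PoseFrame(
                frame_index=int(frame_no[r]),
                landmarks=[
                    Landmark(i, coord[r, i, 0], coord[r, i, 1], coord[r, i, 2], vis[r, i])
                    for i in range(N_LANDMARKS)
                ],
            )
            for r in idx
        ]
        label = rows["Y"].iloc[0]
        clip_id = str(int(clip_key)) if float(clip_key) == int(float(clip_key)) else str(clip_key)
        clip = Clip(clip_id=clip_id, label=str(label), frames=frames)
        clip.precomputed_speeds = {c: speeds[c][idx].tolist() for c in speed_cols}
        clips.append(clip)
    return ClipDataset(clips=clips, class_vocabulary=CLASS_VOCABULARY)


def _read_jsonl(path: Path) -> ClipDataset:
    records: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON at line {lineno}: {exc}") from exc
            for key in ("clip_id", "label", "frame_index", "landmarks"):
                if key not in rec:
                    raise SchemaError(f"line {lineno}: missing field {key!r}")
            if len(rec["landmarks"]) != N_LANDMARKS:
                raise SchemaError(f"line {lineno}: expected {N_LANDMARKS} landmarks, found {len(rec['landmarks'])}")
            entry = records.setdefault(
                rec["clip_id"],
                {"label": rec["label"], "fps": rec.get("fps", 30.0), "frames": [], "speeds": {}},
            )
            landmarks = [
                Landmark(
                    index=int(lm["index"]),
                    x=float(lm["x"]),
                    y=float(lm["y"]),
                    z=float(lm["z"]),
                    visibility=float(lm.get("visibility", 1.0)),
                )
                for lm in sorted(rec["landmarks"], key=lambda d: d["index"])
            ]
            entry["frames"].append(PoseFrame(frame_index=int(rec["frame_index"]), landmarks=landmarks))
            for name, value in rec.get("speeds", {}).items():
                entry["speeds"].setdefault(name, []).append((int(rec["frame_index"]), float(value)))
    clips = []
    for clip_id, entry in records.items():
        frames = sorted(entry["frames"], key=lambda f: f.frame_index)
        clip = Clip(clip_id=clip_id, label=entry["label"], frames=frames, fps=entry["fps"])
        clip.precomputed_speeds = {
            name: [v for _, v in sorted(vals)] for name, vals in entry["speeds"].items()
        }
        clips.append(clip)
    return ClipDataset(clips=clips, class_vocabulary=CLASS_VOCABULARY)


def write_keypoint_table(
    ds: ClipDataset,
    path: str | Path,
    dialect: str = "csv",
    include_visibility: bool = False,
) -> None:
    """Serialize a dataset in the flat CSV layout or the nested JSONL dialect.

    Coordinates are written at full repr precision so a write/read round trip
    is lossless.  Any precomputed speed series attached to the clips are
    emitted as speed columns.
    """
    path = Path(path)
    if dialect == "csv":
        _write_csv(ds, path, include_visibility)
    elif dialect == "jsonl":
        _write_jsonl(ds, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_csv(ds: ClipDataset, path: Path, include_visibility: bool) -> None:
    speed_cols = [
        c for c in SPEED_COLUMNS if any(c in getattr(clip, "precomputed_speeds", {}) for clip in ds.clips)
    ]
    rows = []
    for clip_no, clip in enumerate(ds.clips, start=1):
        pre = getattr(clip, "precomputed_speeds", {})
        for t, frame in enumerate(clip.frames):
            row: dict[str, object] = {"Index": clip_no, "Frame": frame.frame_index}
            for lm in frame.landmarks:
                row[landmark_column(lm.index, "x")] = lm.x
                row[landmark_column(lm.index, "y")] = lm.y
                row[landmark_column(lm.index, "z")] = lm.z
                if include_visibility:
                    row[landmark_column(lm.index, "v")] = lm.visibility
            for c in speed_cols:
                row[c] = pre[c][t] if c in pre else np.nan
            row["Y"] = clip.label
            rows.append(row)
    columns = ["Index", "Frame"] + coordinate_columns(include_visibility) + speed_cols + ["Y"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def _write_jsonl(ds: ClipDataset, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for clip in ds.clips:
            pre = getattr(clip, "precomputed_speeds", {})
            for t, frame in enumerate(clip.frames):
                rec = {
                    "clip_id": clip.clip_id,
                    "label": clip.label,
                    "fps": clip.fps,
                    "frame_index": frame.frame_index,
                    "landmarks": [
                        {"index": lm.index, "x": lm.x, "y": lm.y, "z": lm.z, "visibility": lm.visibility}
                        for lm in frame.landmarks
                    ],
                }
                if pre:
                    rec["speeds"] = {name: vals[t] for name, vals in pre.items()}
                fh.write(json.dumps(rec) + "\n")
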
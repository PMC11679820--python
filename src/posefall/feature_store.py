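"""Persist prepared feature sequences (HDF5) and normalization parameters (JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .preprocessing import FeatureMatrix, NormalizationParams


def save_features(features: list[FeatureMatrix], path: str | Path) -> None:
    if not features:
        raise ValueError("nothing to save")
    T, D = features[0].values.shape
    for m in features:
        if m.values.shape != (T, D):
            raise ValueError("all feature matrices must share one shape; standardize frames first")
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=np.stack([m.values for m in features]))
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("clip_id", data=np.array([m.clip_id for m in features], dtype=object), dtype=str_dt)
        f.create_dataset("label", data=np.array([m.label for m in features], dtype=object), dtype=str_dt)
        f.create_dataset("channel_names", data=np.array(features[0].channel_names, dtype=object), dtype=str_dt)


def load_features(path: str | Path) -> list[FeatureMatrix]:
    with h5py.File(path, "r") as f:
        X = f["X"][...]
        clip_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["clip_id"][...]]
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["label"][...]]
        channels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_names"][...]]
    return [
        FeatureMatrix(clip_id=cid, label=lab, values=X[i], channel_names=list(channels))
        for i, (cid, lab) in enumerate(zip(clip_ids, labels))
    ]


def save_norm_params(params: NormalizationParams, path: str | Path, fitted_on: str = "train") -> None:
    payload = {
        "fitted_on": fitted_on,
        "channel_names": list(params.channel_names),
        "x_min": params.x_min.tolist(),
        "x_max": params.x_max.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_norm_params(path: str | Path) -> NormalizationParams:
    payload = json.loads(Path(path).read_text())
    return NormalizationParams(
        x_min=np.array(payload["x_min"]),
        x_max=np.array(payload["x_max"]),
        channel_names=list(payload["channel_names"]),
    )
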
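"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate.

A single :class:`RunConfig` drives all stages; one global seed
deterministically derives the per-stage seeds, so a rerun with the same
config is bit-reproducible for data and features and deterministic for
metrics.  Every artifact is written with a config snapshot and input
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .evaluation import EvalReport, evaluate_predictions
from .feature_store import save_features, save_norm_params
from .io import write_keypoint_table
from .nn.models import RecurrentConfig, TransformerConfig
from .nn.training import PRESETS, TrainConfig, build_preset, predict, split_dataset, train
from .preprocessing import apply_minmax, fit_minmax, prepare_features
from .schema import CLASS_VOCABULARY
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger("posefall")


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    seed: int = 0
    output_dir: str = "run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    frames: int | None = None  # None -> dataset minimum
    include_nose_speed: bool = False
    include_visibility: bool = False
    smooth_all: bool = False
    preset: str = "transformer3"
    max_epochs: int | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(3)
        return {
            "generate": int(state[0] % 2**31),
            "preprocess": int(state[1] % 2**31),
            "train": int(state[2] % 2**31),
        }

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        raw.update(overrides)
        return cls(generator=gen, **raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"].pop("templates", None)  # templates are code-defined defaults
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: RunConfig) -> EvalReport:
    """Execute every stage, writing artifacts under ``cfg.output_dir``.

    Artifacts: ``dataset.csv``, ``features.h5``, ``norm_params.json``,
    ``model.npz`` + ``model_config.json``, ``history.csv``, ``report.json``
    and ``run_config.json`` (the snapshot, with stage seeds and checksums).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    gen_cfg = replace(cfg.generator, seed=seeds["generate"])
    ds = generate_dataset(gen_cfg)
    dataset_path = out / "dataset.csv"
    write_keypoint_table(ds, dataset_path, dialect="csv")
    timings["simulate"] = time.perf_counter() - t0
    logger.info("simulate: %d clips in %.1fs", len(ds), timings["simulate"])

    t0 = time.perf_counter()
    features = prepare_features(
        ds,
        n_frames=cfg.frames,
        seed=seeds["preprocess"],
        include_nose_speed=cfg.include_nose_speed,
        include_visibility=cfg.include_visibility,
        smooth_all=cfg.smooth_all,
    )
    features_path = out / "features.h5"
    save_features(features, features_path)
    timings["preprocess"] = time.perf_counter() - t0
    logger.info("preprocess: %d x %s features in %.1fs", len(features), features[0].values.shape, timings["preprocess"])

    t0 = time.perf_counter()
    T, D = features[0].values.shape
    model, train_cfg = build_preset(cfg.preset, D, T, seed=seeds["train"], max_epochs=cfg.max_epochs)
    tr, va, te = split_dataset(features, train_cfg)
    norm = fit_minmax(tr)
    save_norm_params(norm, out / "norm_params.json", fitted_on="train")
    tr_n = [apply_minmax(m, norm) for m in tr]
    va_n = [apply_minmax(m, norm) for m in va]
    te_n = [apply_minmax(m, norm) for m in te]
    model, history = train(model, tr_n, va_n, train_cfg)
    _save_model(model, cfg.preset, train_cfg, out)
    _save_history(history, out / "history.csv")
    timings["train"] = time.perf_counter() - t0
    logger.info("train: %d epochs in %.1fs", len(history["train_loss"]), timings["train"])

    t0 = time.perf_counter()
    probs = predict(model, te_n)
    report = evaluate_predictions([m.label for m in te], probs)
    timings["evaluate"] = time.perf_counter() - t0

    payload = report.to_dict()
    payload["run_config"] = cfg.snapshot()
    payload["stage_seeds"] = seeds
    payload["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    payload["input_checksums"] = {
        "dataset.csv": _sha256(dataset_path),
        "features.h5": None,  # HDF5 serialization is not byte-stable; contents are
    }
    (out / "report.json").write_text(json.dumps(payload, indent=1))
    (out / "run_config.json").write_text(json.dumps(cfg.snapshot(), indent=1, default=str))
    return report


def _save_model(model, preset: str, train_cfg: TrainConfig, out: Path) -> None:
    np.savez(out / "model.npz", *model.get_weights())
    meta = {
        "preset": preset,
        "d_in": model.d_in,
        "T": model.T,
        "train_config": dataclasses.asdict(train_cfg),
        "model_config": dataclasses.asdict(model.cfg),
        "kind": "transformer" if isinstance(model.cfg, TransformerConfig) else model.cfg.kind,
        "vocabulary": list(CLASS_VOCABULARY),
    }
    (out / "model_config.json").write_text(json.dumps(meta, indent=1))


def load_model(model_dir: str | Path):
    """Rebuild a saved classifier (architecture from config, weights from npz)."""
    from .nn.models import build_recurrent, build_transformer

    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "model_config.json").read_text())
    seed = meta["train_config"]["seed"]
    if meta["kind"] == "transformer":
        model = build_transformer(meta["d_in"], meta["T"], TransformerConfig(**meta["model_config"]), seed=seed)
    else:
        model = build_recurrent(meta["d_in"], meta["T"], RecurrentConfig(**meta["model_config"]), seed=seed)
    with np.load(model_dir / "model.npz") as data:
        weights = [data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))]
    model.set_weights(weights)
    return model, meta


def _save_history(history: dict[str, list[float]], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(history).to_csv(path, index_label="epoch")
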
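"""Checkpointing: one ``params.npz`` of parameter arrays plus a JSON sidecar
with everything needed to rebuild the network (config, feature widths,
target statistics)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import ModelConfig
from .ddi_pretrain import DDIModel
from .synergy_model import FeatureDims, MultiSynModel

__all__ = ["save_synergy_model", "load_synergy_model", "save_ddi_model", "load_ddi_model"]


def _save_params(params, path: Path) -> None:
    np.savez(path, **{f"p{i}": p.data for i, p in enumerate(params)})


def _load_params(params, path: Path) -> None:
    arrays = np.load(path)
    if len(arrays.files) != len(params):
        raise ValueError("checkpoint parameter count mismatch")
    for i, p in enumerate(params):
        saved = arrays[f"p{i}"]
        if saved.shape != p.data.shape:
            raise ValueError(f"parameter {i} shape mismatch: {saved.shape} vs {p.data.shape}")
        p.data[...] = saved


def save_synergy_model(model: MultiSynModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": json.loads(model.config.model_dump_json()),
        "dims": {"descriptor": model.dims.descriptor, "graph": model.dims.graph,
                 "cell": model.dims.cell, "ddi": model.dims.ddi},
        "y_mean": model.y_mean, "y_std": model.y_std, "trained": model.trained,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    _save_params(model.parameters(), out / "params.npz")


def load_synergy_model(out_dir: str | Path) -> MultiSynModel:
    out = Path(out_dir)
    meta = json.loads((out / "model.json").read_text())
    model = MultiSynModel(ModelConfig(**meta["config"]), FeatureDims(**meta["dims"]))
    _load_params(model.parameters(), out / "params.npz")
    model.y_mean = meta["y_mean"]
    model.y_std = meta["y_std"]
    model.trained = meta["trained"]
    return model


def save_ddi_model(model: DDIModel, config: ModelConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": json.loads(config.model_dump_json()),
        "n_desc": model.n_desc, "n_classes": model.n_classes,
        "post_widths": [layer.W.shape[1] for layer in model.post.layers],
        "trained": model.trained,
    }
    (out / "ddi_model.json").write_text(json.dumps(meta, indent=2))
    _save_params(model.parameters(), out / "ddi_params.npz")


def load_ddi_model(out_dir: str | Path) -> DDIModel:
    out = Path(out_dir)
    meta = json.loads((out / "ddi_model.json").read_text())
    cfg = ModelConfig(**meta["config"])
    model = DDIModel(meta["n_desc"], meta["n_classes"], cfg,
                     np.random.default_rng(0), meta["post_widths"])
    _load_params(model.parameters(), out / "ddi_params.npz")
    model.trained = meta["trained"]
    return model
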
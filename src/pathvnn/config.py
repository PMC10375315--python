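"""Run configuration: one YAML/JSON file driving every pipeline stage.

Defaults mirror the model's reference settings (k=6 hidden units per
module, learning rate 1e-5, 300 epochs, smoothing penalty epsilon=80,
12 AUC bins over [0, 1.2]); unknown keys are rejected so typos fail fast,
and the resolved config (with the seed) is written into every output
directory for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import yaml

from .model import ModelConfig


@dataclass
class PathsConfig:
    ontology: str | None = None
    annotations: dict = field(default_factory=dict)  # channel -> path
    mutation: str | None = None
    amplification: str | None = None
    deletion: str | None = None
    expression: str | None = None
    fingerprints: str | None = None
    descriptors: str | None = None
    triplets: str | None = None
    synergy_pairs: str | None = None
    targets: str | None = None
    checkpoint: str | None = None
    out_dir: str = "runs"


@dataclass
class EvaluationConfig:
    n_per_class: int = 100
    runs: int = 1000
    k_folds: int = 5
    scheme: str = "random"


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0
    min_genes: int = 1
    propagate: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _fill(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str | None = None, overrides: dict | None = None
                ) -> RunConfig:
    """Load a YAML/JSON config file; missing keys take defaults, unknown
    keys raise. `overrides` (flat dot-keys like 'model.epochs') win over
    the file, which wins over defaults."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text)) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    for key, value in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    sub = {}
    top = {f.name: f for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - set(top)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for name, f in top.items():
        if name not in data:
            continue
        if name == "paths":
            sub[name] = _fill(PathsConfig, data[name], "paths")
        elif name == "model":
            sub[name] = _fill(ModelConfig, data[name], "model")
        elif name == "evaluation":
            sub[name] = _fill(EvaluationConfig, data[name], "evaluation")
        else:
            sub[name] = data[name]
    cfg = RunConfig(**sub)
    # the seed propagates to the model unless the model block pinned its own
    if "model" not in data or "seed" not in data.get("model", {}):
        cfg.model.seed = cfg.seed
    return cfg


def save_config(cfg: RunConfig, path: str) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
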
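"""Configuration dataclasses and YAML loading."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["ModelConfig", "TrainingConfig", "RunConfig", "load_config"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``d1``/``d2`` are the structure/attribute channel embedding widths
    (128 each by default), ``dv`` the fused node width, ``de`` the scoring
    hidden width, ``d_ea`` the hyperedge-attention width and ``d_att`` the
    node-attention width.  The four ablation flags disable one component
    each: a channel, or one of the two attention mechanisms (replaced by
    uniform weights).
    """

    d1: int = 128
    d2: int = 128
    dv: int = 128
    de: int = 64
    d_ea: int = 128
    d_att: int = 128
    dropout: float = 0.5
    leaky_slope: float = 0.2
    no_structure: bool = False
    no_attribute: bool = False
    uniform_node_attention: bool = False
    uniform_edge_attention: bool = False

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "dv", "de", "d_ea", "d_att"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.no_structure and self.no_attribute:
            raise ValueError("cannot disable both encoder channels")


@dataclass
class TrainingConfig:
    """Optimization hyperparameters (Adam, ranking loss over sampled
    negative hyperedges, early stopping on validation AUC)."""

    learning_rate: float = 0.001
    max_epochs: int = 200
    batch_size: int = 64
    negatives_per_positive: int = 1
    patience: int = 20
    seed: int = 0
    loss_mode: str = "mean"   # "mean": average negatives inside the loss;
                              # "paired": one matched negative per positive

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.loss_mode not in ("mean", "paired"):
            raise ValueError("loss_mode must be 'mean' or 'paired'")


@dataclass
class RunConfig:
    """Full pipeline configuration for the command-line interface."""

    edges: str = ""
    attributes: str = ""
    output_dir: str = "runs"
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    n_runs: int = 100          # negative resamplings averaged at evaluation
    neg_ratio: float = 1.0     # negatives per test positive in the candidate pool
    sweep_dims: list[int] = field(default_factory=lambda: [8, 32, 128, 512])

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return cls(**data)


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Read a YAML config file; flat keys for nested fields are accepted
    (e.g. ``learning_rate`` routes into the training section)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    model_keys = {f.name for f in fields(ModelConfig)}
    train_keys = {f.name for f in fields(TrainingConfig)}
    model_raw = dict(raw.pop("model", {}))
    train_raw = dict(raw.pop("training", {}))
    for key in list(raw):
        if key in model_keys:
            model_raw[key] = raw.pop(key)
        elif key in train_keys:
            train_raw[key] = raw.pop(key)
    cfg = _build(RunConfig, {**raw,
                             "model": _build(ModelConfig, model_raw),
                             "training": _build(TrainingConfig, train_raw)})
    return cfg
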
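"""Pipeline configuration and deterministic per-stage seeding."""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Node2VecParams:
    """Biased random-walk + skip-gram settings (common node2vec defaults)."""

    p: float = 1.0          # return parameter
    q: float = 1.0          # in-out parameter
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 5
    epochs: int = 5
    negative: int = 5

    def validate(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("node2vec p and q must be positive")
        for name in ("walks_per_node", "walk_length", "window", "epochs", "negative"):
            if getattr(self, name) < 1:
                raise ValueError(f"node2vec {name} must be >= 1")


@dataclass
class GateParams:
    """Graph attention auto-encoder settings."""

    layer_dims: tuple[int, ...] = (128,)
    learning_rate: float = 1e-3
    epochs: int = 200
    structure_loss_weight: float = 1.0
    activation: str = "tanh"

    def validate(self) -> None:
        if any(d < 1 for d in self.layer_dims):
            raise ValueError("GATE layer dims must be positive")
        if self.structure_loss_weight < 0:
            raise ValueError("structure loss weight must be >= 0")
        if self.epochs < 1:
            raise ValueError("GATE epochs must be >= 1")


@dataclass
class ClassifierParams:
    """Self-attention + fully-connected multi-label classifier settings."""

    use_attention: bool = True
    attention_dim: int = 128
    hidden_sizes: tuple[int, ...] = (256, 64)
    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int | None = None  # None = full batch
    threshold: float = 0.5
    weight_decay: float = 0.3
    dropout: float = 0.0

    def validate(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("decision threshold must be in (0, 1)")
        if self.attention_dim < 1 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("layer sizes must be positive")
        if self.epochs < 1:
            raise ValueError("classifier epochs must be >= 1")
        if not 0 <= self.dropout < 1 or self.weight_decay < 0:
            raise ValueError("invalid regularization settings")


@dataclass
class PipelineConfig:
    """End-to-end settings for the localization pipeline.

    ``sequence_dim``/``association_dim`` are the node-embedding widths for the
    sequence-similarity network and the three bipartite association networks.
    ``functional_threshold`` binarizes the fused functional similarity into the
    miRNA functional network used by the auto-encoder: a float is an absolute
    cut-off, while the default ``"auto"`` targets ~10% edge density (the 90th
    percentile of off-diagonal similarity), which keeps the neighborhood graph
    informative for any similarity distribution.  One master ``seed`` is
    split deterministically per stage.
    """

    sequence_dim: int = 64
    association_dim: int = 128
    functional_threshold: float | str = "auto"
    use_gate: bool = True
    cv_folds: int = 10
    seed: int = 0
    node2vec: Node2VecParams = field(default_factory=Node2VecParams)
    gate: GateParams = field(default_factory=GateParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)

    def __post_init__(self) -> None:
        if isinstance(self.node2vec, dict):
            self.node2vec = Node2VecParams(**self.node2vec)
        if isinstance(self.gate, dict):
            self.gate = GateParams(**self.gate)
        if isinstance(self.classifier, dict):
            self.classifier = ClassifierParams(**self.classifier)
        for p in (self.gate, self.classifier):
            if isinstance(getattr(p, "layer_dims", None), list):
                p.layer_dims = tuple(p.layer_dims)
        if isinstance(self.gate.layer_dims, list):
            self.gate.layer_dims = tuple(self.gate.layer_dims)
        if isinstance(self.classifier.hidden_sizes, list):
            self.classifier.hidden_sizes = tuple(self.classifier.hidden_sizes)
        self.validate()

    def validate(self) -> None:
        if self.sequence_dim < 1 or self.association_dim < 1:
            raise ValueError("embedding dims must be positive")
        if self.functional_threshold != "auto" and not (
            0 <= float(self.functional_threshold) <= 1
        ):
            raise ValueError('functional threshold must be in [0, 1] or "auto"')
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        self.node2vec.validate()
        self.gate.validate()
        self.classifier.validate()

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return zlib.crc32(f"{stage}:{self.seed}".encode()) & 0x7FFFFFFF

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
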
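"""Configuration dataclasses with YAML round-trip.

Every knob the harness can turn lives here: operator choice and its
hyperparameters, the per-instance encoder, and the optimisation schedule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PicasoConfig",
    "AggregatorConfig",
    "EncoderSpec",
    "TrainConfig",
    "to_yaml",
    "from_yaml",
]


@dataclass
class PicasoConfig:
    """Hyperparameters of the cascaded attentional set operator.

    Parameters
    ----------
    n_hive : int
        Number of learnable histopathologic vectors (queries); the aggregate
        has shape ``n_hive x dim``. Both clinical tasks use 1.
    dim : int
        Width d of the queries and projected instance embeddings.
    n_heads : int
        Attention heads; ``dim`` must divide evenly.
    n_steps : int
        J, the number of cascaded transformer updates of the query state.
    share_weights : bool
        Reuse one transformer block at every step so the parameter count is
        independent of J.
    ff_mult : int
        Feed-forward hidden width as a multiple of ``dim``.
    """

    n_hive: int = 1
    dim: int = 512
    n_heads: int = 8
    n_steps: int = 3
    share_weights: bool = True
    ff_mult: int = 2
    temperature: float | None = None  # None -> 1/sqrt(d_head)

    def __post_init__(self):
        if self.n_hive < 1 or self.dim < 1:
            raise ValueError("n_hive and dim must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps (J) must be >= 1")
        if self.dim % self.n_heads != 0:
            raise ValueError(f"dim={self.dim} not divisible by n_heads={self.n_heads}")
        if self.temperature is not None and self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class AggregatorConfig:
    """Operator choice plus the knobs shared across operators."""

    operator: str = "picaso"
    dim: int = 64
    n_heads: int = 8
    n_hive: int = 1
    n_steps: int = 3
    share_weights: bool = True
    n_seeds: int = 1  # set-transformer pooling seeds


@dataclass
class EncoderSpec:
    """Pluggable per-instance encoder description.

    ``identity`` passes precomputed vectors through; ``tiny_cnn`` is the
    shipped trainable default for small images; ``external`` lets callers
    supply their own callable.
    """

    name: str = "tiny_cnn"
    out_dim: int = 64
    projection_dim: int = 64
    in_channels: int = 3

    def __post_init__(self):
        if self.out_dim < 1:
            raise ValueError("out_dim must be >= 1")
        if self.name not in ("tiny_cnn", "identity", "external"):
            raise ValueError(f"unknown encoder {self.name!r}")


@dataclass
class TrainConfig:
    """Optimisation schedule (BCE + Adam)."""

    lr: float = 1e-4
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def to_yaml(cfg, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg)))


def from_yaml(cls, path):
    data = yaml.safe_load(Path(path).read_text())
    return cls(**data)
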
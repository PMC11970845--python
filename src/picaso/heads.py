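"""Task heads mapping the aggregated query state to predictions.

Two targets are supported. The instance-anomaly head scores each instance
of a set by how far its embedding deviates (L1) from the aggregate — the
aggregate of an attention cascade with one query behaves like a weighted
mean of the set, so the lesion-bearing instance stands out as the outlier.
The set-classification head maps the flattened aggregate through one affine
layer to a single probability for the whole case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .nn import Linear, Module

__all__ = [
    "InstanceScorePrediction",
    "SetLabelPrediction",
    "InstanceAnomalyHead",
    "SetClassificationHead",
]


@dataclass
class InstanceScorePrediction:
    """Per-instance lesion probabilities for one case."""

    case_id: object
    scores: np.ndarray          # (M,) in [0, 1]
    deviations: np.ndarray      # (M,) nonnegative L1 distances


@dataclass
class SetLabelPrediction:
    """Case-level binary prediction."""

    case_id: object
    probability: float
    label_hat: int = field(init=False)

    def __post_init__(self):
        # ties at the 0.5 operating point are classified positive
        self.label_hat = int(self.probability >= 0.5)


class InstanceAnomalyHead(Module):
    """L1-deviation head for the one-positive-per-set task.

    ``mode="vector"`` feeds the d-vector of elementwise absolute differences
    |E_i - mu| through a shared affine layer (one logit per instance); with
    uniform weights this degrades gracefully to the scalar-L1 reading, which
    is also available directly as ``mode="scalar"``. Requires a single query
    vector (n_hive = 1).
    """

    def __init__(self, rng_or_seed, dim: int, mode: str = "vector"):
        rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
               else np.random.default_rng(rng_or_seed))
        if mode not in ("vector", "scalar"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.out = Linear(rng, dim if mode == "vector" else 1, 1)

    def logits(self, e: Tensor, mu_final: Tensor) -> Tensor:
        if mu_final.shape[0] != 1:
            raise ValueError(
                "instance anomaly head requires n_hive == 1 "
                f"(got aggregate of shape {mu_final.shape})"
            )
        dev = (e - mu_final).abs()                     # (M, d)
        if self.mode == "scalar":
            dev = dev.sum(axis=-1, keepdims=True)      # (M, 1)
        return self.out(dev)                           # (M, 1)

    def __call__(self, e: Tensor, mu_final: Tensor,
                 case_id=None) -> InstanceScorePrediction:
        z = self.logits(e, mu_final)
        scores = 1.0 / (1.0 + np.exp(-z.data[:, 0]))
        deviations = np.abs(e.data - mu_final.data).sum(axis=-1)
        return InstanceScorePrediction(case_id=case_id, scores=scores,
                                       deviations=deviations)


class SetClassificationHead(Module):
    """Flatten the aggregate, one affine map, sigmoid."""

    def __init__(self, rng_or_seed, dim: int, n_hive: int = 1):
        rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
               else np.random.default_rng(rng_or_seed))
        self.out = Linear(rng, n_hive * dim, 1)
        self.n_hive = n_hive
        self.dim = dim

    def logits(self, mu_final: Tensor) -> Tensor:
        flat = mu_final.reshape(1, self.n_hive * self.dim)
        return self.out(flat)                          # (1, 1)

    def __call__(self, mu_final: Tensor, case_id=None) -> SetLabelPrediction:
        z = self.logits(mu_final)
        prob = float(1.0 / (1.0 + np.exp(-z.data[0, 0])))
        return SetLabelPrediction(case_id=case_id, probability=prob)
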
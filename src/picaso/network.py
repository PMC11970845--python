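"""End-to-end network: encoder -> per-instance projection -> set operator -> head.

One :class:`SetNetwork` handles both tasks. Instances of a whole batch of
sets are encoded in a single stacked pass (the encoder is per-instance, so
this is purely a speed matter), then each set is aggregated and scored
separately because set sizes vary.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .config import AggregatorConfig, EncoderSpec
from .encoders import build_encoder
from .heads import InstanceAnomalyHead, SetClassificationHead
from .nn import Linear, Module
from .operators import make_aggregator

__all__ = ["SetNetwork"]


class SetNetwork(Module):
    """Trainable composite for the one-positive or binary set task."""

    def __init__(self, task: str, agg: AggregatorConfig | None = None,
                 encoder: EncoderSpec | None = None, seed: int = 0,
                 head_mode: str = "vector", external_fn=None):
        if task not in ("one_positive", "binary"):
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        self.agg_config = agg or AggregatorConfig()
        self.encoder_spec = encoder or EncoderSpec()
        rng = np.random.default_rng(seed)
        self.encoder = build_encoder(self.encoder_spec, seed=seed,
                                     external_fn=external_fn)
        d = self.agg_config.dim
        if self.encoder_spec.out_dim != d:
            self.projection = Linear(rng, self.encoder_spec.out_dim, d)
        else:
            self.projection = None
        self.aggregator = make_aggregator(
            self.agg_config.operator, dim=d, n_heads=self.agg_config.n_heads,
            n_hive=self.agg_config.n_hive, n_steps=self.agg_config.n_steps,
            share_weights=self.agg_config.share_weights,
            n_seeds=self.agg_config.n_seeds, seed=seed + 1,
        )
        head_rng = np.random.default_rng(seed + 2)
        if task == "one_positive":
            if self.aggregator.n_out != 1:
                raise ValueError("one_positive task requires n_hive/n_out == 1")
            self.head = InstanceAnomalyHead(head_rng, d, mode=head_mode)
        else:
            self.head = SetClassificationHead(head_rng, d,
                                              n_hive=self.aggregator.n_out)

    # ------------------------------------------------------------------ fwd
    def _embed_batch(self, batch_data) -> tuple[Tensor, list[int]]:
        """Encode all instances of all sets in one pass; return sizes."""
        sizes = [len(d) for d in batch_data]
        if self.encoder_spec.name == "identity":
            stacked = Tensor(np.concatenate(
                [np.asarray(d, dtype=np.float32) for d in batch_data]))
            e = self.encoder(stacked)
        else:
            arrs = [np.asarray(im, dtype=np.float32) for d in batch_data for im in d]
            stack = np.stack(arrs)
            if stack.ndim == 3:
                stack = stack[..., None]
            e = self.encoder(Tensor(stack))
        if self.projection is not None:
            e = self.projection(e)
        return e, sizes

    def forward_sets(self, batch_data) -> list[Tensor]:
        """Per-set logit tensors: (M_i, 1) for one_positive, (1, 1) for binary."""
        e, sizes = self._embed_batch(batch_data)
        logits = []
        start = 0
        for m in sizes:
            e_i = e[start:start + m]
            mu = self.aggregator(e_i)
            if self.task == "one_positive":
                logits.append(self.head.logits(e_i, mu))
            else:
                logits.append(self.head.logits(mu))
            start += m
        return logits

    def batch_logits(self, batch_data) -> Tensor:
        """All logits of the batch stacked into one column tensor."""
        return concat(self.forward_sets(batch_data), axis=0)

    def predict_scores(self, batch_data) -> list[np.ndarray]:
        """Per-set probability arrays (sigmoid of the logits), no grad kept."""
        out = []
        for z in self.forward_sets(batch_data):
            out.append((1.0 / (1.0 + np.exp(-z.data))).ravel())
        return out
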
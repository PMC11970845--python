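"""Model/Results presentation layer.

`SetModel` is constructed from data (built sets plus a task name) and
configuration; `fit()` trains the underlying network and returns a
`SetModelResults` carrying the loss history, held-out metrics with
bootstrap CIs, and a text `summary()`. Simulation-free prediction,
evaluation on new sets and plotting hang off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AggregatorConfig, EncoderSpec, TrainConfig
from .metrics import MetricReport
from .network import SetNetwork
from .training import collect_scores, evaluate, sweep_set_size, train

__all__ = ["SetModel", "SetModelResults"]


class SetModel:
    """A permutation-invariant set model bound to training data.

    Parameters
    ----------
    sets : list of (data, target)
        Training sets; ``data`` is a list of images or an M x d matrix,
        ``target`` a one-hot vector (one-positive task) or scalar label.
    task : {"one_positive", "binary"}
    aggregator : str
        Operator name (see :data:`picaso.operators.AGGREGATOR_NAMES`).
    """

    def __init__(self, sets, task: str = "one_positive",
                 aggregator: str = "picaso",
                 agg_config: AggregatorConfig | None = None,
                 encoder: EncoderSpec | None = None, seed: int = 0):
        self.sets = list(sets)
        self.task = task
        cfg = agg_config or AggregatorConfig()
        if aggregator != cfg.operator:
            cfg = AggregatorConfig(**{**cfg.__dict__, "operator": aggregator})
        self.agg_config = cfg
        self.encoder_spec = encoder or EncoderSpec()
        self.seed = seed
        self.network = SetNetwork(task, agg=cfg, encoder=self.encoder_spec,
                                  seed=seed)

    @classmethod
    def from_dataframe(cls, manifest: pd.DataFrame, pool: dict, task: str,
                       **kwargs) -> "SetModel":
        """Build from a tidy manifest (instance_id, group_id, label, set_id)
        plus an instance pool, grouping rows by ``set_id``."""
        sets = []
        for _, grp in manifest.groupby("set_id", sort=True):
            data = [pool[i].image if pool[i].image is not None else pool[i].vector
                    for i in grp["instance_id"]]
            if pool[grp["instance_id"].iloc[0]].vector is not None:
                data = np.asarray(data, dtype=np.float32)
            if task == "one_positive":
                target = grp["label"].to_numpy(dtype=np.float32)
            else:
                target = np.float32(grp["label"].iloc[0])
            sets.append((data, target))
        return cls(sets, task=task, **kwargs)

    def fit(self, config: TrainConfig | None = None, val_sets=None,
            verbose: bool = False) -> "SetModelResults":
        config = config or TrainConfig(seed=self.seed)
        history = train(self.network, self.sets, config, val_sets=val_sets,
                        verbose=verbose)
        return SetModelResults(self, history, config, val_sets=val_sets)


class SetModelResults:
    """Fit artefacts: trained network, history, evaluation, summary."""

    def __init__(self, model: SetModel, history: pd.DataFrame,
                 config: TrainConfig, val_sets=None):
        self.model = model
        self.network = model.network
        self.history = history
        self.config = config
        self._report: MetricReport | None = None
        self._val_sets = val_sets

    def predict(self, sets):
        """Per-set probability arrays."""
        _, scores = collect_scores(self.network, sets)
        return scores

    def evaluate(self, sets, n_bootstrap: int = 1000,
                 seed: int = 0) -> MetricReport:
        report = evaluate(self.network, sets, n_bootstrap=n_bootstrap,
                          seed=seed)
        self._report = report
        return report

    def sweep_set_size(self, make_sets, m_values, **kwargs) -> pd.DataFrame:
        return sweep_set_size(self.network, make_sets, m_values, **kwargs)

    def save(self, path) -> None:
        self.network.save(path)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(self.history["epoch"], self.history["loss"], label="train loss")
        if "val_auroc" in self.history:
            ax2 = ax.twinx()
            ax2.plot(self.history["epoch"], self.history["val_auroc"],
                     color="C1", label="val AUROC")
            ax2.set_ylabel("validation AUROC")
        ax.set_xlabel("epoch")
        ax.set_ylabel("BCE loss")
        return ax

    def summary(self) -> str:
        cfg = self.model.agg_config
        lines = [
            "Permutation-invariant set model",
            "=" * 46,
            f"task:            {self.model.task}",
            f"operator:        {cfg.operator}",
            f"dim / heads:     {cfg.dim} / {cfg.n_heads}",
            f"steps J:         {cfg.n_steps} (shared weights: {cfg.share_weights})",
            f"encoder:         {self.model.encoder_spec.name}",
            f"parameters:      {self.network.n_parameters():,}",
            f"training sets:   {len(self.model.sets)}",
            f"epochs / lr:     {self.config.epochs} / {self.config.lr}",
            f"final loss:      {self.history['loss'].iloc[-1]:.4f}",
        ]
        if self._report is not None:
            r = self._report
            lines.append("-" * 46)
            for name in ("auroc", "aupr", "recall", "accuracy"):
                v = getattr(r, name)
                if v is None:
                    continue
                ci = r.ci.get(name)
                tail = f"  (95% CI {ci[0]:.3f}-{ci[1]:.3f})" if ci else ""
                lines.append(f"{name:>8s}:       {v:.4f}{tail}")
        return "\n".join(lines)
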
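"""Training loop, evaluation harness and the two robustness sweeps.

Training follows the clinical protocol at desk scale: binary cross entropy,
Adam at learning rate 1e-4, 20 epochs, batches of 32 sets. Evaluation pools
instance scores (one-positive task) or uses per-set probabilities (binary
task) and attaches percentile-bootstrap 95% CIs. The two sweeps mirror the
published robustness analyses: metrics versus the number of cascade steps
J, and metrics versus evaluation set size M for a model trained at maximum
set size 8 (no retraining).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AggregatorConfig, EncoderSpec, TrainConfig
from .metrics import (MetricReport, instance_metrics, paired_bootstrap_pvalue,
                      set_metrics)
from .network import SetNetwork
from .nn import Adam, bce_with_logits

__all__ = ["train", "evaluate", "collect_scores", "compare_operators",
           "sweep_steps", "sweep_set_size"]


def _targets_of(sets) -> list[np.ndarray]:
    return [np.atleast_1d(np.asarray(t, dtype=np.float64)) for _, t in sets]


def train(model: SetNetwork, sets, config: TrainConfig | None = None,
          val_sets=None, verbose: bool = False):
    """Train in place; returns a per-epoch history DataFrame.

    ``sets`` is a list of ``(data, target)`` pairs as produced by
    :func:`picaso.sets.materialize` or the synthetic generators. Aborts with
    a diagnostic if the loss goes non-finite.
    """
    if not sets:
        raise ValueError("no training sets")
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    targets = _targets_of(sets)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(sets))
        losses = []
        for lo in range(0, len(sets), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            batch = [sets[i][0] for i in idx]
            tgt = np.concatenate([targets[i] for i in idx])[:, None]
            logits = model.batch_logits(batch)
            loss = bce_with_logits(logits, tgt)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // config.batch_size}: "
                    f"{float(loss.data)}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_sets is not None:
            rep = evaluate(model, val_sets, n_bootstrap=0)
            row["val_auroc"] = rep.auroc
            row["val_aupr"] = rep.aupr
        history.append(row)
        if verbose:
            print(f"epoch {epoch:3d}  loss {row['loss']:.4f}"
                  + (f"  val_auroc {row.get('val_auroc', float('nan')):.3f}"
                     if val_sets is not None else ""))
    return pd.DataFrame(history)


def collect_scores(model: SetNetwork, sets):
    """Per-set (labels, scores) arrays for the model's task."""
    labels = _targets_of(sets)
    scores = []
    for data, _ in sets:
        scores.append(model.predict_scores([data])[0])
    return labels, scores


def evaluate(model: SetNetwork, sets, n_bootstrap: int = 1000,
             seed: int = 0) -> MetricReport:
    """Metric report on held-out sets (see module docstring for pooling)."""
    labels, scores = collect_scores(model, sets)
    if model.task == "one_positive":
        return instance_metrics(labels, scores, n_bootstrap=n_bootstrap,
                                seed=seed)
    flat_l = np.array([l[0] for l in labels], dtype=int)
    flat_s = np.array([s[0] for s in scores], dtype=float)
    return set_metrics(flat_l, flat_s, n_bootstrap=n_bootstrap, seed=seed)


def compare_operators(models: dict[str, SetNetwork], sets,
                      metric: str = "auroc", n_resamples: int = 10_000,
                      seed: int = 0) -> pd.DataFrame:
    """Pairwise two-sided paired-bootstrap p-values on identical sets."""
    from . import metrics as _m

    metric_fn = {"auroc": _m.auroc, "aupr": _m.aupr}[metric]
    collected = {name: collect_scores(model, sets)
                 for name, model in models.items()}
    names = list(models)
    rows = []
    for i, a in enumerate(names):
        for b in names[i:]:
            la, sa = collected[a]
            lb, sb = collected[b]
            p = paired_bootstrap_pvalue(metric_fn, la, sa, lb, sb,
                                        n_resamples=n_resamples, seed=seed)
            rows.append({"model_a": a, "model_b": b, "metric": metric,
                         "p_value": p})
    return pd.DataFrame(rows)


def sweep_steps(j_values, train_sets, val_sets, seeds=(0,),
                task: str = "one_positive",
                agg: AggregatorConfig | None = None,
                encoder: EncoderSpec | None = None,
                train_config: TrainConfig | None = None) -> pd.DataFrame:
    """Train one cascade per (J, seed) and tabulate validation metrics.

    Performance need not be monotone in J; the table simply reports it.
    """
    base = agg or AggregatorConfig(operator="picaso")
    rows = []
    for j in j_values:
        for seed in seeds:
            cfg = AggregatorConfig(**{**base.__dict__, "n_steps": int(j)})
            model = SetNetwork(task, agg=cfg, encoder=encoder, seed=seed)
            tc = train_config or TrainConfig()
            tc = TrainConfig(lr=tc.lr, epochs=tc.epochs,
                             batch_size=tc.batch_size, seed=seed)
            train(model, train_sets, tc)
            rep = evaluate(model, val_sets, n_bootstrap=0)
            rows.append({"J": int(j), "seed": seed, "auroc": rep.auroc,
                         "aupr": rep.aupr, "recall": rep.recall})
    return pd.DataFrame(rows)


def sweep_set_size(model: SetNetwork, make_sets, m_values,
                   n_bootstrap: int = 0, seed: int = 0) -> pd.DataFrame:
    """Evaluate a trained model on sets rebuilt at each size, no retraining.

    ``make_sets(m)`` must return evaluation sets of total size ``m`` drawn
    from the same distribution the model was trained on.
    """
    rows = []
    for m in m_values:
        sets = make_sets(int(m))
        rep = evaluate(model, sets, n_bootstrap=n_bootstrap, seed=seed)
        rows.append({"M": int(m), "auroc": rep.auroc, "aupr": rep.aupr,
                     "recall": rep.recall, "n_sets": len(sets)})
    return pd.DataFrame(rows)
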
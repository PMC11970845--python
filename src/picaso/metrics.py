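"""Rank-based evaluation with bootstrap uncertainty.

AUROC and AUPR point estimates are the standard rank-based estimators
(midrank tie handling; AUPR is average precision). Confidence intervals are
percentile bootstraps over *sets* — the case is the sampling unit, so all
instances of a resampled set move together. Pairwise model comparison is a
paired bootstrap of the metric difference with a two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "auroc",
    "aupr",
    "MetricReport",
    "bootstrap_ci",
    "pooled_instance_arrays",
    "instance_metrics",
    "set_metrics",
    "paired_bootstrap_pvalue",
]


def auroc(labels, scores) -> float:
    """Area under the ROC curve (Mann-Whitney with midranks)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    # clamp float overshoot (e.g. 1 + 4e-16 from summed precision steps)
    return float(np.clip(roc_auc_score(labels, scores), 0.0, 1.0))


def aupr(labels, scores) -> float:
    """Area under the precision-recall curve (average precision)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR undefined: no positive labels")
    return float(np.clip(average_precision_score(labels, scores), 0.0, 1.0))


@dataclass
class MetricReport:
    """Point estimates with 95% bootstrap CIs for one model on one split."""

    auroc: float
    aupr: float
    recall: float
    accuracy: float | None = None
    ci: dict = field(default_factory=dict)      # metric -> (low, high)
    n_bootstrap: int = 0
    n_sets: int = 0
    p_values: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("auroc", "aupr", "recall"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict:
        out = {"auroc": self.auroc, "aupr": self.aupr, "recall": self.recall,
               "n_sets": self.n_sets, "n_bootstrap": self.n_bootstrap}
        if self.accuracy is not None:
            out["accuracy"] = self.accuracy
        for m, (lo, hi) in self.ci.items():
            out[f"{m}_ci_low"], out[f"{m}_ci_high"] = lo, hi
        return out


def pooled_instance_arrays(per_set_labels, per_set_scores):
    """Concatenate per-set instance labels/scores into pooled arrays."""
    labels = np.concatenate([np.asarray(l) for l in per_set_labels])
    scores = np.concatenate([np.asarray(s) for s in per_set_scores])
    return labels, scores


def _recall_argmax(per_set_labels, per_set_scores) -> float:
    """Fraction of sets whose true-positive instance attains the top score."""
    hits = 0
    for l, s in zip(per_set_labels, per_set_scores):
        l, s = np.asarray(l), np.asarray(s)
        hits += bool(s[l == 1].max() >= s.max())
    return hits / len(per_set_labels)


def _recall_threshold(labels, scores, thr: float = 0.5) -> float:
    labels, scores = np.asarray(labels), np.asarray(scores)
    pos = labels == 1
    if pos.sum() == 0:
        return float("nan")
    return float((scores[pos] >= thr).mean())


def bootstrap_ci(stat_fn, n_sets: int, n_bootstrap: int = 1000,
                 seed: int = 0, level: float = 0.95):
    """Percentile bootstrap over set indices.

    ``stat_fn(idx)`` computes the statistic on the resampled set indices and
    may return NaN for degenerate resamples (single-class), which are
    dropped.
    """
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n_sets, size=n_sets)
        v = stat_fn(idx)
        if np.isfinite(v):
            stats.append(v)
    alpha = (1.0 - level) / 2
    return (float(np.quantile(stats, alpha)),
            float(np.quantile(stats, 1.0 - alpha)))


def instance_metrics(per_set_labels, per_set_scores, n_bootstrap: int = 1000,
                     seed: int = 0) -> MetricReport:
    """Pooled-instance AUROC/AUPR plus argmax recall, with set-level CIs."""
    labels, scores = pooled_instance_arrays(per_set_labels, per_set_scores)
    report = MetricReport(
        auroc=auroc(labels, scores),
        aupr=aupr(labels, scores),
        recall=_recall_argmax(per_set_labels, per_set_scores),
        n_bootstrap=n_bootstrap,
        n_sets=len(per_set_labels),
    )
    if n_bootstrap > 0:
        ls = list(per_set_labels)
        ss = list(per_set_scores)

        def stat(metric):
            def fn(idx):
                l = np.concatenate([ls[i] for i in idx])
                s = np.concatenate([ss[i] for i in idx])
                if len(np.unique(l)) < 2:
                    return float("nan")
                if metric == "auroc":
                    return auroc(l, s)
                if metric == "aupr":
                    return aupr(l, s)
                return _recall_argmax([ls[i] for i in idx], [ss[i] for i in idx])
            return fn

        for j, m in enumerate(("auroc", "aupr", "recall")):
            report.ci[m] = bootstrap_ci(stat(m), len(ls), n_bootstrap,
                                        seed=seed + j)
    return report


def set_metrics(labels, probs, n_bootstrap: int = 1000,
                seed: int = 0) -> MetricReport:
    """Case-level AUROC/AUPR/recall/accuracy with set-level bootstrap CIs."""
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    preds = (probs >= 0.5).astype(int)       # ties classified positive
    report = MetricReport(
        auroc=auroc(labels, probs),
        aupr=aupr(labels, probs),
        recall=_recall_threshold(labels, probs),
        accuracy=float((preds == labels).mean()),
        n_bootstrap=n_bootstrap,
        n_sets=len(labels),
    )
    if n_bootstrap > 0:
        def stat(metric):
            def fn(idx):
                l, p = labels[idx], probs[idx]
                if len(np.unique(l)) < 2:
                    return float("nan")
                if metric == "auroc":
                    return auroc(l, p)
                if metric == "aupr":
                    return aupr(l, p)
                if metric == "recall":
                    return _recall_threshold(l, p)
                return float(((p >= 0.5).astype(int) == l).mean())
            return fn

        for j, m in enumerate(("auroc", "aupr", "recall", "accuracy")):
            report.ci[m] = bootstrap_ci(stat(m), len(labels), n_bootstrap,
                                        seed=seed + j)
    return report


def paired_bootstrap_pvalue(metric_fn, labels_a, scores_a, labels_b, scores_b,
                            n_resamples: int = 10_000, seed: int = 0) -> float:
    """Two-sided paired-bootstrap p-value for metric(A) - metric(B).

    Both models must be evaluated on the same sets, in the same order
    (``labels_a`` and ``labels_b`` must agree element-wise); each resample
    draws set indices with replacement and recomputes the difference. The
    p-value is ``2 * min(P(diff <= 0), P(diff >= 0))`` clipped to (0, 1],
    so a model compared with itself yields exactly 1.
    """
    la = [np.asarray(x) for x in labels_a]
    lb = [np.asarray(x) for x in labels_b]
    if len(la) != len(lb) or any(not np.array_equal(x, y) for x, y in zip(la, lb)):
        raise ValueError("paired comparison requires identical evaluation sets")
    sa = [np.asarray(x) for x in scores_a]
    sb = [np.asarray(x) for x in scores_b]
    rng = np.random.default_rng(seed)
    n = len(la)
    diffs = np.empty(n_resamples)
    kept = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        l = np.concatenate([la[i] for i in idx])
        if len(np.unique(l)) < 2:
            continue
        va = metric_fn(l, np.concatenate([sa[i] for i in idx]))
        vb = metric_fn(l, np.concatenate([sb[i] for i in idx]))
        diffs[kept] = va - vb
        kept += 1
    d = diffs[:kept]
    p = 2.0 * min((d <= 0).mean(), (d >= 0).mean())
    return float(min(max(p, 1.0 / max(kept, 1)), 1.0))
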
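# picaso

Permutation-invariant cascaded attentional set operators for
multiple-instance problems in histopathology.

## The problem

Many diagnostic questions in nephropathology attach to a *case* — a set of
glomerular image crops from one biopsy — rather than to any single image.
The set has variable size and no meaningful order, so an aggregation
operator must accept any number of instances and be invariant to their
permutation. Typical tasks: find the one crop in a set that carries an
active crescent (C-lesion of IgA nephropathy), or classify a whole case as
antibody-mediated rejection vs not.

## The operator

The package's core is a cascaded attentional set operator. A small matrix
of learnable query vectors μ ∈ R^{N_HV×d} ("histopathologic vectors") is
updated J times by cross-attending over the instance embeddings
E ∈ R^{M×d} of one case:

    μ_{j+1} = Transformer(μ_j, E, E),   j = 0, …, J−1

with μ_0 a trained parameter (Kaiming-initialised) and the transformer
block shared across steps so the parameter count is independent of J.
Because only the N_HV queries attend over the M instances, each step costs
O(M·N_HV) attention scores — linear in the set size — and the output is
permutation invariant by construction. In a simplified form (identity
projections, distance-based scores) the update is soft K-means: at
temperature → 0 one update equals one Lloyd step, which makes the
aggregate interpretable as a weighted mean of the instances.

Baselines behind the same interface: DeepSet pooling (max/mean/sum, with
optional learned gating), simplified equivariant "++" variants, and a Set
Transformer (self-attention + pooling onto learnable seeds). Two task
heads convert the aggregate into predictions: an L1-deviation head scoring
each instance by its distance from the aggregate (one-positive task), and
an affine head on the flattened aggregate (case-level binary task).

All neural components run on a small NumPy reverse-mode autodiff engine
included in the package (`picaso.autodiff`); no deep-learning framework is
required.

## Worked example

```python
import numpy as np
from picaso import (SetModel, TrainConfig, AggregatorConfig, EncoderSpec,
                    LesionImageSpec, gen_lesion_image_sets,
                    build_one_positive_sets, materialize)

# synthetic "glomerulus" image sets: one planted crescent per set
spec = LesionImageSpec(n_cases=200, seed=0)
pool, _, _ = gen_lesion_image_sets(spec, task="one_positive")
groups = sorted({r.group_id for r in pool.values()})
val = set(groups[-40:])
train_recs = [r for r in pool.values() if r.group_id not in val]
val_recs = [r for r in pool.values() if r.group_id in val]
train_sets = [materialize(b, pool)
              for b in build_one_positive_sets(train_recs, 600, seed=1)]
val_sets = [materialize(b, pool)
            for b in build_one_positive_sets(val_recs, 150, seed=2)]

model = SetModel(train_sets, task="one_positive", aggregator="picaso",
                 agg_config=AggregatorConfig(operator="picaso", dim=64,
                                             n_steps=3),
                 encoder=EncoderSpec(name="tiny_cnn", out_dim=64), seed=0)
results = model.fit(TrainConfig(epochs=20, seed=0))
report = results.evaluate(val_sets, n_bootstrap=200)
print(results.summary())
```

On one CPU this trains in a few minutes and prints (abridged):

```
Permutation-invariant set model
==============================================
task:            one_positive
operator:        picaso
dim / heads:     64 / 8
steps J:         3 (shared weights: True)
encoder:         tiny_cnn
parameters:      41,873
training sets:   600
epochs / lr:     20 / 0.0001
final loss:      0.3043
----------------------------------------------
   auroc:       1.0000  (95% CI 1.000-1.000)
    aupr:       1.0000  (95% CI 1.000-1.000)
  recall:       1.0000  (95% CI 1.000-1.000)
```

AUROC/AUPR pool the per-instance lesion scores over all validation sets;
recall is the fraction of sets whose true lesion instance attains the top
score. On this separable synthetic task the trained cascade identifies the
planted crescent essentially perfectly, while an untrained network sits at
chance (AUROC ≈ 0.5).

A command-line pipeline wraps the same steps: `picaso simulate`,
`picaso build-sets`, `picaso train`, `picaso evaluate`,
`picaso sweep-steps`, `picaso sweep-set-size`, `picaso compare`.

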
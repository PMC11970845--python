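# Methods

## Model

The package implements set-level prediction for multiple-instance problems:
a case is an unordered, variable-size set of instances (images or feature
vectors), and the label attaches to the set. The aggregation operator is a
cascade of cross-attention updates of a learnable query state. Writing
E ∈ R^{M×d} for the projected instance embeddings of one case and
μ_j ∈ R^{N_HV×d} for the query state ("histopathologic vectors"),

    μ_{j+1} = Transformer(μ_j, E, E),    j = 0 … J−1,

where the transformer block is multihead cross-attention (queries = μ_j,
keys = values = E) wrapped in the block composition described below. μ_0 is
a trainable parameter initialised from the Kaiming scheme (zero mean,
variance 2/d); the per-input states μ_1 … μ_J are activations and are never
persisted across cases. With weight sharing (the default) one block is
reused at every step, so J does not change the parameter count.

Two properties are guaranteed and tested rather than assumed:

* **Valid set operator.** Softmax attention of N_HV queries over M keys is
  invariant to key order and defined for every M ≥ 1, so the cascade
  accepts variable cardinality and is permutation invariant. The test
  tolerance is 1e-5 in float32 — permutation changes the summation order,
  so exact equality holds only in real arithmetic.
* **K-means limit.** Stripped to identity projections, no feed-forward and
  no residual, with scores −‖x_i − μ_k‖²/τ, the update soft-assigns each
  instance to the nearest query and replaces queries by assignment-weighted
  means. As τ → 0⁺ this is exactly one Lloyd step; the test compares
  against an independent brute-force Lloyd implementation. A dot-product
  score variant is also provided, but the limit statement is exact only for
  the distance form, which is why the oracle test uses it.

### Block composition

The attention block uses pre-normalisation (LayerNorm on the query and on
the keys/values), residual connections around both the attention and the
feed-forward sublayer, a GELU feed-forward of hidden width 2d, and score
scaling 1/√(d/N_h). These choices are not forced by the aggregation idea
itself; pre-norm is the stable modern default for short cascades and the
feed-forward width is exposed in `PicasoConfig.ff_mult`. The query width d
is held constant across steps.

### Baselines

All baselines implement the same `(M, d) → (n_out, d)` contract:

* **DeepSet** — per-instance MLP, then max/mean/sum pooling, then an output
  MLP. The *weighted* variants add a one-hidden-layer gate network whose
  per-instance scalars are softmax-normalised over the set and multiplied
  into the features before pooling — the minimal reading of "weighted
  pooling".
* **DeepSet++ / Set Transformer++ (simplified stand-ins).** The "++"
  variants here are documented approximations, not reproductions of any
  external architecture: DeepSet++ inserts two permutation-equivariant
  layers act(W1·x_i + W2·mean(x)) before pooling; Set Transformer++ adds
  one extra self-attention block.
* **Set Transformer** — self-attention block(s) over the instances followed
  by pooling-by-multihead-attention onto learnable seed vectors. With zero
  self-attention blocks this reduces to plain cross-attention with the
  seeds as query, which the tests exploit as a structural check.

Note the Set Transformer's self-attention is quadratic in M by design; the
linear-cost guarantee (N_h·N_HV·M score entries per step, instrumented and
asserted) applies to the cascade operator.

### Task heads

* **Instance anomaly head** (one-positive task, requires N_HV = 1): the
  aggregate of a one-query attention cascade behaves like a weighted mean
  of the set, so instance i is scored by its deviation from it. The head
  feeds the d-vector of elementwise absolute differences |E_i − μ| through
  a shared affine layer to one logit (sigmoid → probability). This subsumes
  the scalar-L1 reading — uniform weights recover it exactly — and a
  `mode="scalar"` option provides it directly. Training is independent
  per-instance sigmoid + binary cross entropy (not softmax over the set),
  matching a per-instance BCE protocol; a set-softmax mode is deliberately
  not the default.
* **Set classification head** (binary task): flatten the aggregate, one
  affine map, sigmoid. The 0.5 operating point classifies ties as positive
  (documented convention).

## Training

Binary cross entropy, Adam (β = 0.9/0.999), learning rate 1e-4, 20 epochs,
batches of 32 sets — the protocol of the clinical experiments, applied
unchanged at desk scale. All neural computation runs on the package's own
NumPy reverse-mode autodiff engine; every composite layer's gradient is
checked against central finite differences in the test-suite. Training is
deterministic for a fixed seed (single-threaded NumPy kernels; the only
randomness is the seeded shuffle and initialisation).

## Set construction

Training sets are Monte Carlo samples from an instance pool. One-positive
sets draw m ~ Uniform{3..7} lesion-free instances plus exactly one lesion
instance (total 4–8, one-hot target); binary sets draw m ~ Uniform{4..8}
instances from one case and inherit its label. m is drawn uniformly — the
maximum-entropy choice where no distribution is prescribed — and negatives
default to the positive's own group, with a mixed-group option for harder
variants. When a group holds fewer distinct instances than drawn, the set
is completed with augmented copies (random resized crop with area fraction
0.7–1.0, vertical flip p = 0.5, rotation ±30°); augmented members are
flagged so evaluation can exclude them. Cross-validation folds are
group-aware (scikit-learn GroupKFold behind the module surface): a
group's instances never straddle a fold's train/validation boundary.
Crop preprocessing masks the background, zero-pads to a square (centred;
the choice of centring is ours) and resizes isotropically to 256×256, so
the foreground aspect ratio is preserved.

## Synthetic data

The generators provide the statistical structure the pipeline needs
without clinical data:

* **Mixture sets** — cluster means on a sphere of radius `separation` (in
  units of the within-cluster SD), isotropic Gaussian points, true
  assignments returned. Directions are resampled until all pairwise mean
  distances reach the stated radius; without this, two random directions
  can land arbitrarily close and silently void the advertised
  separability.
* **Lesion image sets** — 64×64 RGB images of a noisy ellipse
  ("glomerulus") on a light background; a positive instance carries a
  darker annular arc hugging the ellipse boundary and subtending 90–180°
  (the crescent analogue). Cases belong to one of three simulated
  institutions differing by additive brightness (0, +0.06, −0.06) and a
  mild channel tint, emulating stain/scanner variation. Defaults — contrast
  0.55, pixel noise SD 0.08, 200 cases — are the package's separable study
  conditions, chosen once as a regime where the motif is clearly above the
  noise floor; `contrast=0` is the no-signal null (positives and negatives
  identically distributed).

What the generator does *not* emulate: tissue texture, real stain
chemistry, morphological confounders (other lesion types), annotation
noise, or scale variation. Passing tests therefore demonstrate that the
architecture, optimisation and evaluation machinery are correct and that
the operator can exploit a localised morphological signal under
institution shift — not that any particular clinical performance level
would be reached.

## Evaluation

AUROC and AUPR are rank-based (midrank tie handling; average precision),
computed by scikit-learn and verified against independent O(n²) pairwise
oracles in the tests. For the one-positive task, instance scores are
pooled over all validation sets (a one-vs-rest reading); recall is
reported at the argmax operating point — the fraction of sets whose true
lesion instance attains the maximal score — with a 0.5-threshold recall
available, since the operating point is otherwise a convention. For the
binary task: AUROC/AUPR on set probabilities, accuracy and recall at 0.5
with ties positive.

Uncertainty is a percentile bootstrap over sets (default 1000 resamples;
the set is the sampling unit, so all instances of a resampled set move
together). Pairwise model comparison is a paired bootstrap of the metric
difference (default 10⁴ resamples), two-sided:
p = 2·min(P(Δ ≤ 0), P(Δ ≥ 0)) clipped to (0, 1], so self-comparison gives
exactly 1. Degenerate single-class resamples are dropped.

## Robustness sweeps

* **Steps sweep**: one model trained per (J, seed); the table reports
  metrics per J with J = 1 as baseline. No monotonicity is asserted —
  performance need not improve with more steps.
* **Set-size sweep**: a model trained at maximum set size 8 is evaluated on
  sets rebuilt at M ∈ {4, 8, 16, 32} *without retraining*. On the separable
  synthetic task the AUROC degradation from the training size stays within
  0.05.

## Problem sizes and numerical choices

Default desk-scale runs: 600 Monte Carlo training sets from 160 training
cases, 150 evaluation sets from 40 group-disjoint held-out cases; the
zero-contrast null at 120 cases / 6 epochs (a null has nothing to learn —
the check is only that it stays at chance); the set-size sweep at 60 cases
per M. These sizes are the package's choices for routine runs; all are
configurable. The tiny CNN encoder (2×2 average pool, three 3×3 conv /
max-pool stages at 8/16/32 channels, global average pool, affine to 64)
is a desk-scale default, not a claim about encoder design — the encoder
interface is pluggable and `external` wraps any callable.

Numerical conventions: float32 parameters and activations with gradients
in the same dtype; permutation-invariance tolerance 1e-5 (float32);
K-means-limit oracle tolerance 1e-4 at temperature 1e-6; attention rows
sum to 1 within 1e-6; AUROC/AUPR oracle agreement 1e-9 (float64 metric
path). Ties: midranks in AUROC, ties-positive at the 0.5 threshold,
argmax recall counts a set as hit when the positive attains the maximum
(also under ties).

## Limitations

* The operator ignores spatial relations between instances by design;
  tasks needing spatial context would require positional information.
* The "++" baselines are simplified stand-ins (see above) and should not
  be cited as reproductions.
* The NumPy engine is single-threaded and CPU-bound; it is sized for
  desk-scale experiments, not production training.
* Synthetic results do not transfer to clinical performance claims (see
  the synthetic-data section for what is and is not emulated).
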
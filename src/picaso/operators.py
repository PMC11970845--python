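"""Permutation-invariant set operators.

The centrepiece is the cascaded attentional operator: a small matrix of
learnable query vectors ("histopathologic vectors", HiVe) is repeatedly
updated by cross-attending over the instance embeddings of one case,

    mu_{j+1} = Transformer(mu_j, E, E),   j = 0..J-1,

where E (M x d) are the instance embeddings (keys and values) and mu_j
(N_HV x d) is the query state. Because the queries attend over the set and
never the set over itself, the attention cost per step is N_h * N_HV * M
score entries — linear in the set size — and the output is invariant to any
permutation of the instances. With ``share_weights`` the same transformer
block is applied at every step, so the parameter count does not grow with J.

Baselines implementing the same ``(M, d) -> (n_out, d)`` contract:
DeepSet-style pooling (max / mean / sum, optionally gated), simplified
"++" variants with permutation-equivariant pre-aggregation layers, and a
Set Transformer (self-attention followed by pooling-by-multihead-attention
onto learnable seeds).

``kmeans_limit_update`` exposes the clustering view of the attention
update: with identity projections and distance-based scores, one update at
temperature -> 0 is exactly one Lloyd step of K-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .config import PicasoConfig
from .nn import LayerNorm, Linear, Module, Parameter, kaiming_normal

__all__ = [
    "HiVeState",
    "init_hive",
    "MultiheadCrossAttention",
    "TransformerBlock",
    "PicasoAggregator",
    "DeepSetAggregator",
    "SetTransformerAggregator",
    "kmeans_limit_update",
    "kmeans_limit_iterate",
    "make_aggregator",
    "AGGREGATOR_NAMES",
]


# --------------------------------------------------------------------- HiVe
@dataclass
class HiVeState:
    """Query-vector state of the cascade.

    ``mu`` holds the N_HV x d vectors; ``step_index`` counts applied updates;
    ``learnable`` is true only for the initial state mu_0, which is a trained
    parameter — later states are per-input activations.
    """

    mu: np.ndarray
    step_index: int = 0
    learnable: bool = False

    @property
    def n_hive(self) -> int:
        return self.mu.shape[0]

    @property
    def dim(self) -> int:
        return self.mu.shape[1]


def init_hive(n_hive: int, dim: int, seed: int) -> HiVeState:
    """Kaiming-initialised learnable initial queries (zero mean, var 2/dim)."""
    if n_hive < 1 or dim < 1:
        raise ValueError("n_hive and dim must be >= 1")
    rng = np.random.default_rng(seed)
    mu = kaiming_normal(rng, (n_hive, dim), fan_in=dim)
    return HiVeState(mu=mu, step_index=0, learnable=True)


# ---------------------------------------------------------------- attention
class MultiheadCrossAttention(Module):
    """Scaled dot-product attention of a query matrix over a set.

    Separate query/key/value projections, per-head softmax over the set
    axis, and an output projection. ``last_attention`` holds the
    head-averaged weights (n_query x M) of the most recent call and
    ``last_score_elements`` the number of score entries computed
    (n_heads * n_query * M) — the instrumentation used to verify that no
    quadratic-in-M structure is ever allocated.
    """

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int):
        if dim % n_heads != 0:
            raise ValueError(f"dim={dim} not divisible by n_heads={n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, dim, dim)
        self.wv = Linear(rng, dim, dim)
        self.wo = Linear(rng, dim, dim)
        self.last_attention: np.ndarray | None = None
        self.last_score_elements: int = 0

    def __call__(self, query: Tensor, keys_values: Tensor) -> tuple[Tensor, np.ndarray]:
        nq = query.shape[0]
        m = keys_values.shape[0]
        h, dh = self.n_heads, self.d_head
        q = self.wq(query).reshape(nq, h, dh).transpose(1, 0, 2)   # (h, nq, dh)
        k = self.wk(keys_values).reshape(m, h, dh).transpose(1, 0, 2)
        v = self.wv(keys_values).reshape(m, h, dh).transpose(1, 0, 2)
        scores = (q @ k.swapaxes(1, 2)) * (1.0 / np.sqrt(dh))      # (h, nq, m)
        attn = scores.softmax(axis=-1)
        self.last_score_elements = h * nq * m
        out = attn @ v                                             # (h, nq, dh)
        out = out.transpose(1, 0, 2).reshape(nq, h * dh)
        self.last_attention = attn.data.mean(axis=0)
        return self.wo(out), self.last_attention


class TransformerBlock(Module):
    """Pre-norm cross-attention block with a GELU feed-forward.

    Residual connections wrap both the attention and the feed-forward
    sublayer; the feed-forward hidden width is ``ff_mult * dim``.
    """

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int,
                 ff_mult: int = 2):
        self.attn = MultiheadCrossAttention(rng, dim, n_heads)
        self.ln_q = LayerNorm(dim)
        self.ln_kv = LayerNorm(dim)
        self.ln_ff = LayerNorm(dim)
        self.ff1 = Linear(rng, dim, ff_mult * dim)
        self.ff2 = Linear(rng, ff_mult * dim, dim)

    def __call__(self, mu: Tensor, e: Tensor) -> tuple[Tensor, np.ndarray]:
        a, weights = self.attn(self.ln_q(mu), self.ln_kv(e))
        mu = mu + a
        mu = mu + self.ff2(self.ff1(self.ln_ff(mu)).gelu())
        return mu, weights


# ------------------------------------------------------------------- PICASO
class PicasoAggregator(Module):
    """The J-step cascade of query updates over one instance set."""

    n_out: int

    def __init__(self, config: PicasoConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.mu0 = Parameter(
            kaiming_normal(rng, (config.n_hive, config.dim), fan_in=config.dim)
        )
        n_blocks = 1 if config.share_weights else config.n_steps
        self.blocks = [
            TransformerBlock(rng, config.dim, config.n_heads, config.ff_mult)
            for _ in range(n_blocks)
        ]
        self.n_out = config.n_hive
        self.attention_trace: list[np.ndarray] = []
        self.score_elements_trace: list[int] = []

    def block_at(self, j: int) -> TransformerBlock:
        return self.blocks[0] if self.config.share_weights else self.blocks[j]

    def step(self, state: HiVeState, e: Tensor) -> HiVeState:
        """One functional update of a HiVe state (activations only)."""
        mu = Tensor(state.mu.astype(np.float32))
        out, _ = self.block_at(min(state.step_index, self.config.n_steps - 1))(mu, e)
        return HiVeState(mu=out.data, step_index=state.step_index + 1, learnable=False)

    def __call__(self, e: Tensor) -> Tensor:
        if e.shape[-1] != self.config.dim:
            raise ValueError(
                f"embedding dim {e.shape[-1]} != operator dim {self.config.dim}"
            )
        self.attention_trace = []
        self.score_elements_trace = []
        mu = self.mu0
        for j in range(self.config.n_steps):
            block = self.block_at(j)
            mu, weights = block(mu, e)
            self.attention_trace.append(weights)
            self.score_elements_trace.append(block.attn.last_score_elements)
        return mu


# ----------------------------------------------------------------- DeepSet
class DeepSetAggregator(Module):
    """Per-instance MLP, optional learned gating, then symmetric pooling.

    ``pool`` is one of max / mean / sum. With ``weighted``, a one-hidden-layer
    gate network scores each instance, the scores are softmax-normalised over
    the set and multiplied into the instance features before pooling. With
    ``equivariant`` (the simplified "++" variant), two permutation-equivariant
    pre-aggregation layers of the form act(W1 x_i + W2 mean(x)) precede the
    pooling; this is a documented approximation, not a faithful reproduction
    of any published "++" architecture.
    """

    def __init__(self, rng_or_seed, dim: int, pool: str = "mean",
                 weighted: bool = False, equivariant: bool = False):
        rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
               else np.random.default_rng(rng_or_seed))
        if pool not in ("max", "mean", "sum"):
            raise ValueError(f"unknown pool {pool!r}; expected max|mean|sum")
        self.pool = pool
        self.weighted = weighted
        self.equivariant = equivariant
        self.dim = dim
        self.phi1 = Linear(rng, dim, dim)
        self.phi2 = Linear(rng, dim, dim)
        self.rho = Linear(rng, dim, dim)
        if weighted:
            self.gate1 = Linear(rng, dim, dim)
            self.gate2 = Linear(rng, dim, 1)
        if equivariant:
            self.eq_self = [Linear(rng, dim, dim) for _ in range(2)]
            self.eq_ctx = [Linear(rng, dim, dim) for _ in range(2)]
        self.n_out = 1

    def __call__(self, e: Tensor) -> Tensor:
        x = self.phi2(self.phi1(e).gelu())
        if self.equivariant:
            for ws, wc in zip(self.eq_self, self.eq_ctx):
                ctx = x.mean(axis=0, keepdims=True)
                x = (ws(x) + wc(ctx)).gelu()
        if self.weighted:
            g = self.gate2(self.gate1(x).gelu())        # (M, 1)
            w = g.softmax(axis=0)
            x = x * w
        if self.pool == "max":
            pooled = x.max(axis=0, keepdims=True)
        elif self.pool == "mean":
            pooled = x.mean(axis=0, keepdims=True)
        else:
            pooled = x.sum(axis=0, keepdims=True)
        return self.rho(pooled)                          # (1, d)


# --------------------------------------------------------- Set Transformer
class SetTransformerAggregator(Module):
    """Self-attention over instances, then pooling onto learnable seeds.

    ``n_sab`` self-attention blocks are followed by
    pooling-by-multihead-attention (PMA): cross-attention of ``n_seeds``
    learnable seed vectors over the transformed set. ``extra_equivariant``
    adds one more self-attention block (the simplified "++" stand-in).
    ``n_sab=0`` reduces PMA to plain cross-attention with the seeds as
    query, which the tests exploit as a structural check.
    """

    def __init__(self, rng_or_seed, dim: int, n_heads: int = 8,
                 n_seeds: int = 1, n_sab: int = 1,
                 extra_equivariant: bool = False):
        rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
               else np.random.default_rng(rng_or_seed))
        if extra_equivariant:
            n_sab += 1
        self.sabs = [
            TransformerBlock(rng, dim, n_heads) for _ in range(n_sab)
        ]
        self.seeds = Parameter(kaiming_normal(rng, (n_seeds, dim), fan_in=dim))
        self.pma = MultiheadCrossAttention(rng, dim, n_heads)
        self.n_out = n_seeds

    def __call__(self, e: Tensor) -> Tensor:
        x = e
        for sab in self.sabs:
            x, _ = sab(x, x)
        out, _ = self.pma(self.seeds, x)
        return out


# ------------------------------------------------------------ K-means limit
def kmeans_limit_update(mu: np.ndarray, x: np.ndarray, temperature: float,
                        score: str = "neg_sq_dist") -> np.ndarray:
    """One simplified attention update exposing the K-means limit.

    With identity projections, no feed-forward and no residual, instance i
    is soft-assigned to centroid k by a softmax over
    ``-||x_i - mu_k||^2 / temperature`` (or scaled dot products), and each
    centroid is replaced by its assignment-weighted mean. As temperature
    -> 0+ the softmax hardens to nearest-centroid assignment and the update
    becomes one Lloyd step of K-means.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    mu = np.asarray(mu, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if score == "neg_sq_dist":
        d2 = ((x[:, None, :] - mu[None, :, :]) ** 2).sum(axis=-1)  # (M, K)
        logits = -d2 / temperature
    elif score == "dot":
        logits = (x @ mu.T) / temperature
    else:
        raise ValueError(f"unknown score {score!r}")
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=1, keepdims=True)                              # (M, K)
    mass = w.sum(axis=0)                                           # (K,)
    new_mu = np.where(
        mass[:, None] > 1e-12, (w.T @ x) / np.maximum(mass, 1e-12)[:, None], mu
    )
    return new_mu


def kmeans_limit_iterate(mu0: np.ndarray, x: np.ndarray, temperature: float,
                         max_iter: int = 100, tol: float = 1e-8,
                         score: str = "neg_sq_dist") -> np.ndarray:
    """Iterate :func:`kmeans_limit_update` to a fixed point."""
    mu = np.asarray(mu0, dtype=np.float64)
    for _ in range(max_iter):
        new = kmeans_limit_update(mu, x, temperature, score=score)
        if np.max(np.abs(new - mu)) < tol:
            return new
        mu = new
    return mu


# ----------------------------------------------------------------- registry
AGGREGATOR_NAMES = (
    "picaso",
    "deepset_max", "deepset_mean", "deepset_sum",
    "deepset_max_w", "deepset_mean_w", "deepset_sum_w",
    "deepsetpp_max", "deepsetpp_mean", "deepsetpp_sum",
    "set_transformer", "set_transformerpp",
)


def make_aggregator(name: str, dim: int, n_heads: int = 8, n_hive: int = 1,
                    n_steps: int = 3, share_weights: bool = True,
                    n_seeds: int = 1, seed: int = 0) -> Module:
    """Build any operator behind the common ``(M, d) -> (n_out, d)`` interface."""
    rng = np.random.default_rng(seed)
    if name == "picaso":
        cfg = PicasoConfig(n_hive=n_hive, dim=dim, n_heads=n_heads,
                           n_steps=n_steps, share_weights=share_weights)
        return PicasoAggregator(cfg, seed=seed)
    if name.startswith("deepset"):
        pp = name.startswith("deepsetpp")
        rest = name.split("_", 1)[1]
        weighted = rest.endswith("_w")
        pool = rest[:-2] if weighted else rest
        return DeepSetAggregator(rng, dim, pool=pool, weighted=weighted,
                                 equivariant=pp)
    if name == "set_transformer":
        return SetTransformerAggregator(rng, dim, n_heads=n_heads, n_seeds=n_seeds)
    if name == "set_transformerpp":
        return SetTransformerAggregator(rng, dim, n_heads=n_heads,
                                        n_seeds=n_seeds, extra_equivariant=True)
    raise ValueError(f"unknown aggregator {name!r}; known: {AGGREGATOR_NAMES}")
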
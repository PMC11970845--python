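"""Per-instance encoders: image (or vector) -> d_E embedding.

The encoder is pluggable. ``identity`` passes precomputed vectors through
unchanged; ``tiny_cnn`` is the shipped trainable default — a three-stage
conv/pool network with global average pooling, sized to train end-to-end on
one CPU; ``external`` wraps any user callable. A per-instance linear
projection maps d_E to the operator width d whenever they differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .config import EncoderSpec
from .nn import Linear, Module, Parameter, kaiming_normal

__all__ = ["EncoderSpec", "InstanceEmbeddings", "IdentityEncoder",
           "TinyCNNEncoder", "build_encoder", "encode_instances"]


@dataclass
class InstanceEmbeddings:
    """Embeddings of one case's instance set (M rows, d_E columns)."""

    case_id: object
    E: np.ndarray

    def __post_init__(self):
        self.E = np.asarray(self.E)
        if self.E.ndim != 2 or self.E.shape[0] < 1:
            raise ValueError("E must be a nonempty M x d_E matrix")
        if not np.all(np.isfinite(self.E)):
            raise ValueError("embeddings must be finite")

    @property
    def M(self) -> int:
        return self.E.shape[0]

    @property
    def d(self) -> int:
        return self.E.shape[1]


class _Conv3x3(Module):
    """'Same' 3x3 convolution via im2col, NHWC layout."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int):
        fan_in = 9 * c_in
        self.w = Parameter(kaiming_normal(rng, (fan_in, c_out), fan_in=fan_in))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        cols = x.pad2d(1).im2col(3)          # (N, H, W, 9*c_in)
        return cols @ self.w + self.b


def _maxpool2(x: Tensor) -> Tensor:
    n, h, w, c = x.shape
    x = x.reshape(n, h // 2, 2, w // 2, 2, c)
    return x.max(axis=2).max(axis=3)


def _avgpool2(x: Tensor) -> Tensor:
    n, h, w, c = x.shape
    x = x.reshape(n, h // 2, 2, w // 2, 2, c)
    return x.mean(axis=2).mean(axis=3)


class IdentityEncoder(Module):
    """Pass-through for precomputed embedding vectors."""

    def __init__(self, out_dim: int):
        self.out_dim = out_dim

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.out_dim:
            raise ValueError(
                f"identity encoder expected vectors of width {self.out_dim}, "
                f"got {x.shape[-1]}"
            )
        return x


class TinyCNNEncoder(Module):
    """Three conv/pool stages + global average pool + affine to out_dim.

    An initial 2x2 average pool halves the resolution before the first
    convolution: the structures of interest span many pixels, and the
    downsampling quarters the compute of every later stage. Deterministic
    (no dropout / batch statistics), so identical images map to identical
    rows, and each row depends only on its own image.
    """

    channels = (8, 16, 32)

    def __init__(self, rng_or_seed, in_channels: int = 3, out_dim: int = 64,
                 initial_pool: bool = True):
        rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
               else np.random.default_rng(rng_or_seed))
        cs = (in_channels,) + self.channels
        self.convs = [_Conv3x3(rng, cs[i], cs[i + 1]) for i in range(3)]
        self.head = Linear(rng, self.channels[-1], out_dim)
        self.out_dim = out_dim
        self.initial_pool = initial_pool

    def __call__(self, images: Tensor) -> Tensor:
        x = images                                    # (N, H, W, C)
        if self.initial_pool and x.shape[1] >= 16 and x.shape[1] % 2 == 0:
            x = _avgpool2(x)
        for conv in self.convs:
            x = _maxpool2(conv(x).relu())
        x = x.mean(axis=1).mean(axis=1)               # global average pool
        return self.head(x)                           # (N, out_dim)


class ExternalEncoder(Module):
    """Wraps a user-supplied callable producing (N, out_dim) arrays."""

    def __init__(self, fn, out_dim: int):
        self.fn = fn
        self.out_dim = out_dim

    def __call__(self, images: Tensor) -> Tensor:
        out = np.asarray(self.fn(images.data))
        return Tensor(out.astype(np.float32))


def build_encoder(spec: EncoderSpec, seed: int = 0, external_fn=None) -> Module:
    if spec.name == "identity":
        return IdentityEncoder(spec.out_dim)
    if spec.name == "tiny_cnn":
        return TinyCNNEncoder(np.random.default_rng(seed),
                              in_channels=spec.in_channels, out_dim=spec.out_dim)
    if spec.name == "external":
        if external_fn is None:
            raise ValueError("external encoder requires a callable")
        return ExternalEncoder(external_fn, spec.out_dim)
    raise ValueError(f"unknown encoder {spec.name!r}")


def encode_instances(images, spec: EncoderSpec, encoder: Module | None = None,
                     case_id=None, seed: int = 0) -> InstanceEmbeddings:
    """Encode a case's images (list of H x W x C arrays) into embeddings.

    Order-preserving: row i of the result encodes image i. All images in a
    call must share one spatial size. For the ``identity`` spec, ``images``
    may be an M x d matrix of precomputed vectors, returned unchanged.
    """
    if encoder is None:
        encoder = build_encoder(spec, seed=seed)
    if spec.name == "identity":
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim != 2:
            raise ValueError("identity spec expects an M x d matrix")
        return InstanceEmbeddings(case_id=case_id, E=arr)
    arrs = [np.asarray(im, dtype=np.float32) for im in images]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"mixed image sizes in one batch: {sorted(shapes)}")
    stack = np.stack(arrs)
    if stack.ndim == 3:
        stack = stack[..., None]
    out = encoder(Tensor(stack))
    return InstanceEmbeddings(case_id=case_id, E=out.data)
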
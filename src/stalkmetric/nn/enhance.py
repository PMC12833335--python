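"""Local-structure enhancement blocks inserted between the second and third
set-abstraction levels.

* **RPE** (relative position encoding): per point, the offset to the level's
  center and its Euclidean distance form a 4-vector ``r_i = [dx, dy, dz, d]``
  that is mapped by a 1x1 convolution + batch norm + ReLU into the feature
  space and added residually: ``f' = f + E``.
* **LGRM** (local group rearrangement): the N unordered point features are
  laid out row-major on a ceil(sqrt(N)) square grid; when N is not a perfect
  square, the first ``h*w - N`` point features are appended again (forward
  mirror padding) before reshaping. Flattening inverts this exactly.
* **LRSA** (local-region self-attention): a pre-norm transformer block over
  the grid tokens — multi-head self-attention followed by a convolutional
  feed-forward sublayer (1x1 expansion, depthwise 3x3, 1x1 projection), each
  with a residual connection; the tensor shape is unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat, depthwise_conv3x3
from .modules import BatchNormC, LayerNormC, Module, PointwiseConv
from .pointnet import FeatureMap

__all__ = ["GridFeatureMap", "RelativePositionEncoding", "lgrm_rearrange",
           "lgrm_flatten", "LocalRegionSelfAttention"]


@dataclass
class GridFeatureMap:
    """Point features rearranged on a 2D grid.

    ``grid`` is ``(B, C, h, w)`` with ``h = w = ceil(sqrt(N))``;
    ``valid_count`` remembers the original point count N so the padded tail
    can be dropped on flattening.
    """

    grid: Tensor
    valid_count: int

    def __post_init__(self) -> None:
        _, _, h, w = self.grid.shape
        if h != w:
            raise ValueError("grid must be square")
        if h * w < self.valid_count:
            raise ValueError("grid smaller than valid_count")


def lgrm_rearrange(feats: Tensor) -> GridFeatureMap:
    """Rearrange ``(B, C, N)`` point features into a square grid.

    ``h = w = ceil(sqrt(N))``; if ``N < h*w`` the first ``h*w - N`` point
    features are copied in their original order as padding, then each channel
    is reshaped row-major to ``h x w``.
    """
    b, c, n = feats.shape
    if n < 1:
        raise ValueError("need at least one point")
    h = math.ceil(math.sqrt(n))
    pad = h * h - n
    if pad > 0:
        feats = concat([feats, feats[:, :, :pad]], axis=2)
    return GridFeatureMap(grid=feats.reshape(b, c, h, h), valid_count=n)


def lgrm_flatten(gmap: GridFeatureMap) -> Tensor:
    """Inverse row-major flatten; drops padded positions beyond valid_count.

    ``lgrm_flatten(lgrm_rearrange(F))`` equals ``F`` exactly.
    """
    b, c, h, w = gmap.grid.shape
    flat = gmap.grid.reshape(b, c, h * w)
    if gmap.valid_count < h * w:
        flat = flat[:, :, :gmap.valid_count]
    return flat


class RelativePositionEncoding(Module):
    """Residual spatial encoding relative to the per-sample center.

    The center is the centroid of the level's point set (one center per
    sample, shape ``(B, 3, 1)``). The 4-channel code ``[dx, dy, dz, d]`` is
    mapped to the feature width by a 1x1 convolution with batch
    normalization and rectification, then added to the input features.
    """

    def __init__(self, channels: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.channels = channels
        self.conv = PointwiseConv(4, channels, rng)
        self.bn = BatchNormC(channels)

    def encode(self, coords: np.ndarray) -> np.ndarray:
        """The raw 4-channel code ``R`` (numpy, (B, 4, P))."""
        center = coords.mean(axis=2, keepdims=True)
        rel = coords - center
        dist = np.linalg.norm(rel, axis=1, keepdims=True)
        return np.concatenate([rel, dist], axis=1)

    def __call__(self, fmap: FeatureMap) -> FeatureMap:
        if fmap.feats.shape[1] != self.channels:
            raise ValueError(
                f"feature width {fmap.feats.shape[1]} does not match the "
                f"encoder width {self.channels}"
            )
        code = Tensor(self.encode(fmap.coords))
        e = self.bn(self.conv(code)).relu()
        return FeatureMap(coords=fmap.coords, feats=fmap.feats + e)


class LocalRegionSelfAttention(Module):
    """Shape-preserving attention + ConvFFN block on the rearranged grid.

    Pre-norm residual sublayers; attention runs over all ``h*w`` grid tokens
    with ``heads`` heads. The output projections of both sublayers are
    zero-initialized, so a freshly constructed block is the identity map.
    ``mask_padding`` optionally excludes padded tokens from serving as
    attention keys.
    """

    def __init__(self, channels: int, heads: int, ffn_expansion: int,
                 rng: np.random.Generator, mask_padding: bool = False) -> None:
        super().__init__()
        if channels % heads != 0:
            raise ValueError(f"channels {channels} not divisible by heads {heads}")
        self.channels = channels
        self.heads = heads
        self.mask_padding = mask_padding
        self.norm1 = LayerNormC(channels)
        self.qkv = PointwiseConv(channels, 3 * channels, rng)
        self.attn_out = PointwiseConv(channels, channels, rng, zero_init=True)
        self.norm2 = LayerNormC(channels)
        hidden = channels * ffn_expansion
        self.ffn_in = PointwiseConv(channels, hidden, rng)
        self.ffn_dw = Tensor(np.zeros((hidden, 3, 3)), requires_grad=True)
        self.ffn_dw.data[:, 1, 1] = 1.0                     # start as identity
        self.ffn_out = PointwiseConv(hidden, channels, rng, zero_init=True)
        self.last_attention: np.ndarray | None = None

    def __call__(self, gmap: GridFeatureMap) -> GridFeatureMap:
        x = gmap.grid
        b, c, h, w = x.shape
        t = h * w
        dh = c // self.heads

        tokens = self.norm1(x.reshape(b, c, t))
        qkv = self.qkv(tokens)                              # (B, 3C, T)
        q = qkv[:, 0:c, :].reshape(b, self.heads, dh, t).transpose(0, 1, 3, 2)
        k = qkv[:, c:2 * c, :].reshape(b, self.heads, dh, t)
        v = qkv[:, 2 * c:, :].reshape(b, self.heads, dh, t).transpose(0, 1, 3, 2)
        logits = q.matmul(k) * (1.0 / np.sqrt(dh))          # (B, H, T, T)
        if self.mask_padding and gmap.valid_count < t:
            bias = np.zeros((1, 1, 1, t))
            bias[..., gmap.valid_count:] = -1e9
            logits = logits + Tensor(bias)
        attn = logits.softmax(axis=-1)
        self.last_attention = attn.data.copy()
        mixed = attn.matmul(v)                              # (B, H, T, dh)
        mixed = mixed.transpose(0, 1, 3, 2).reshape(b, c, t)
        x = x + self.attn_out(mixed).reshape(b, c, h, w)

        y = self.norm2(x.reshape(b, c, t)).reshape(b, c, h, w)
        y = self.ffn_in(y).relu()
        y = depthwise_conv3x3(y, self.ffn_dw).relu()
        x = x + self.ffn_out(y)
        return GridFeatureMap(grid=x, valid_count=gmap.valid_count)
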
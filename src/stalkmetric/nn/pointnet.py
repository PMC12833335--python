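"""Hierarchical set-abstraction / feature-propagation primitives.

Sampling and grouping are pure index computations on numpy coordinate
arrays (coordinates are not learned); the learned shared MLPs run through
the autodiff engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .autograd import Tensor, concat, gather_points
from .modules import MLPStack, Module

__all__ = ["FeatureMap", "farthest_point_sample", "group_neighbors",
           "interpolate_features", "SetAbstraction", "FeaturePropagation"]


@dataclass
class FeatureMap:
    """Channel-major activations at one hierarchy level.

    ``coords`` is ``(B, 3, P)`` numpy, ``feats`` is a ``(B, C, P)`` graph
    tensor (or ``None`` at the raw-input level).
    """

    coords: np.ndarray
    feats: Optional[Tensor]

    def __post_init__(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (B, 3, P), got {self.coords.shape}")
        if self.feats is not None:
            if self.feats.shape[0] != self.coords.shape[0] or \
               self.feats.shape[2] != self.coords.shape[2]:
                raise ValueError("coords and feats must share batch and point count")

    @property
    def n_points(self) -> int:
        return self.coords.shape[2]


def farthest_point_sample(coords: np.ndarray, m: int) -> np.ndarray:
    """Greedy farthest-point sampling; deterministic start at index 0.

    ``coords`` is ``(B, 3, P)``; returns ``(B, m)`` integer indices. Each
    subsequent index maximizes the minimum distance to the already-selected
    set, so the selection is a 2-approximation of the optimal covering.
    """
    b, _, p = coords.shape
    if not 1 <= m <= p:
        raise ValueError(f"m={m} must be in [1, {p}]")
    pts = coords.transpose(0, 2, 1)                        # (B, P, 3)
    idx = np.zeros((b, m), dtype=np.int64)
    dist = np.full((b, p), np.inf)
    current = np.zeros(b, dtype=np.int64)
    for i in range(m):
        idx[:, i] = current
        delta = pts - pts[np.arange(b), current][:, None, :]
        dist = np.minimum(dist, np.einsum("bpc,bpc->bp", delta, delta))
        current = dist.argmax(axis=1)
    return idx


def group_neighbors(
    coords: np.ndarray,
    centers: np.ndarray,
    radius: float,
    k: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Ball-query grouping of ``k`` neighbors within ``radius`` of each center.

    Returns ``(rel, idx)`` where ``rel`` is ``(B, 3, m, k)`` neighbor
    coordinates relative to their center and ``idx`` is ``(B, m, k)`` source
    indices. Neighbors are the nearest points within the radius (sorted by
    distance); when fewer than ``k`` exist the nearest one is repeated, and
    when none exist the globally nearest point is used.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    b, _, p = coords.shape
    m = centers.shape[2]
    pts = coords.transpose(0, 2, 1)
    ctr = centers.transpose(0, 2, 1)
    d2 = ((ctr[:, :, None, :] - pts[:, None, :, :]) ** 2).sum(-1)   # (B, m, P)
    if k < p:
        cand = np.argpartition(d2, k - 1, axis=2)[:, :, :k]
    else:
        cand = np.broadcast_to(np.arange(p), d2.shape[:2] + (p,))
    cand_d2 = np.take_along_axis(d2, cand, axis=2)
    inner = np.argsort(cand_d2, axis=2, kind="stable")
    order = np.take_along_axis(cand, inner, axis=2)
    d2_sorted = np.take_along_axis(cand_d2, inner, axis=2)
    within = d2_sorted <= radius * radius
    # the nearest point (order[..., 0]) replaces out-of-radius / missing slots
    idx = np.where(within, order, order[:, :, :1])
    if idx.shape[2] < k:                     # fewer points than neighbors
        pad = np.repeat(idx[:, :, :1], k - idx.shape[2], axis=2)
        idx = np.concatenate([idx, pad], axis=2)
    rel = np.take_along_axis(
        pts[:, None, :, :], idx[..., None].repeat(3, axis=-1), axis=2
    ) - ctr[:, :, None, :]
    return rel.transpose(0, 3, 1, 2), idx


class SetAbstraction(Module):
    """Sample centers, group neighbors, apply a shared MLP, max-pool.

    ``radius`` is interpreted as a fraction of the batch bounding-box
    diagonal so the same configuration works at any scene scale.
    """

    def __init__(self, out_points: int, radius_frac: float, k: int,
                 in_channels: int, mlp, rng: np.random.Generator) -> None:
        super().__init__()
        self.out_points = out_points
        self.radius_frac = radius_frac
        self.k = k
        self.mlp = MLPStack([in_channels + 3] + list(mlp), rng)

    def __call__(self, fmap: FeatureMap) -> FeatureMap:
        coords = fmap.coords
        if self.out_points > fmap.n_points:
            raise ValueError(
                f"cannot sample {self.out_points} centers from {fmap.n_points} points"
            )
        diag = float(np.linalg.norm(coords.max(axis=2) - coords.min(axis=2), axis=1).max())
        radius = max(self.radius_frac * diag, 1e-9)
        idx = farthest_point_sample(coords, self.out_points)
        centers = np.take_along_axis(coords, idx[:, None, :].repeat(3, axis=1), axis=2)
        rel, nidx = group_neighbors(coords, centers, radius, self.k)
        grouped = Tensor(rel)                                   # (B, 3, m, k)
        if fmap.feats is not None:
            neigh_feats = gather_points(fmap.feats, nidx)        # (B, C, m, k)
            grouped = concat([grouped, neigh_feats], axis=1)
        pooled = self.mlp(grouped).max(axis=3)                   # (B, C_out, m)
        return FeatureMap(coords=centers, feats=pooled)


def interpolate_features(coarse: FeatureMap, fine_coords: np.ndarray) -> Tensor:
    """Inverse-distance interpolation of coarse features onto fine points.

    Each fine point receives the weighted average of its 3 nearest coarse
    points' features (weights 1/d, normalized). A fine point coinciding with
    a coarse point reproduces that coarse feature (its weight dominates).
    """
    if coarse.n_points < 1:
        raise ValueError("coarse level is empty")
    pc = coarse.coords.shape[2]
    fine = fine_coords.transpose(0, 2, 1)
    crs = coarse.coords.transpose(0, 2, 1)
    d2 = ((fine[:, :, None, :] - crs[:, None, :, :]) ** 2).sum(-1)  # (B, Pf, Pc)
    nn = min(3, pc)
    if nn < pc:
        cand = np.argpartition(d2, nn - 1, axis=2)[:, :, :nn]
        inner = np.argsort(np.take_along_axis(d2, cand, axis=2), axis=2, kind="stable")
        order = np.take_along_axis(cand, inner, axis=2)
    else:
        order = np.argsort(d2, axis=2, kind="stable")[:, :, :nn]
    d = np.sqrt(np.take_along_axis(d2, order, axis=2))
    w = 1.0 / (d + 1e-8)
    w /= w.sum(axis=2, keepdims=True)
    gathered = gather_points(coarse.feats, order)            # (B, C, Pf, nn)
    return (gathered * Tensor(w[:, None, :, :])).sum(axis=3)


class FeaturePropagation(Module):
    """Interpolate coarse features to the fine level, fuse the skip features,
    and apply a shared MLP."""

    def __init__(self, in_channels: int, mlp, rng: np.random.Generator) -> None:
        super().__init__()
        self.mlp = MLPStack([in_channels] + list(mlp), rng)

    def __call__(self, coarse: FeatureMap, fine_coords: np.ndarray,
                 skip_feats: Optional[Tensor]) -> FeatureMap:
        interp = interpolate_features(coarse, fine_coords)
        if skip_feats is not None:
            interp = concat([skip_feats, interp], axis=1)
        return FeatureMap(coords=fine_coords, feats=self.mlp(interp))
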
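"""The stem/background segmentation network.

Architecture: four set-abstraction (SA) levels progressively downsample the
cloud (N -> 1024 -> 256 -> 64 -> 16 points at 64/128/256/512 channels), with
the three enhancement blocks (relative position encoding, grid
rearrangement, local-region self-attention) inserted between SA2 and SA3;
four feature-propagation (FP) levels restore full resolution at 128
channels, and a point-wise head with dropout emits per-point class scores
``(B, N, num_classes)``. Each enhancement can be toggled independently for
ablation studies; disabled blocks leave all downstream shapes valid.

Input contract: 9 feature channels per point — coordinates (3), color (3)
and normal (3).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .autograd import Tensor
from .enhance import (LocalRegionSelfAttention, RelativePositionEncoding,
                      lgrm_flatten, lgrm_rearrange)
from .modules import BatchNormC, Dropout, Module, ModuleList, PointwiseConv
from .pointnet import FeatureMap, FeaturePropagation, SetAbstraction

__all__ = ["SALevelSpec", "NetworkConfig", "SegmentationNetwork",
           "cross_entropy", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class SALevelSpec:
    """One set-abstraction level: target point count, ball-query radius as a
    fraction of the scene diagonal, neighbor cap, and MLP widths."""

    out_points: int
    radius_frac: float
    neighbors: int
    mlp: Tuple[int, ...]


_DEFAULT_SA: Tuple[SALevelSpec, ...] = (
    SALevelSpec(1024, 0.04, 32, (32, 32, 64)),
    SALevelSpec(256, 0.08, 32, (64, 64, 128)),
    SALevelSpec(64, 0.16, 32, (128, 128, 256)),
    SALevelSpec(16, 0.32, 32, (256, 256, 512)),
)


@dataclass
class NetworkConfig:
    """Hyper-parameters of the segmentation network.

    The defaults reproduce the reference tensor flow exactly: SA1 1024
    points / 64 channels, SA2 256/128 (the enhancement junction, 16x16
    grid), SA3 64/256, SA4 16/512, and an FP chain ending at 128 channels
    per original point.
    """

    sa_levels: Tuple[SALevelSpec, ...] = _DEFAULT_SA
    fp_mlps: Tuple[Tuple[int, ...], ...] = ((256, 256), (256, 256), (128, 128), (128, 128, 128))
    in_extra_channels: int = 6            # color (3) + normal (3)
    enable_rpe: bool = True
    enable_lgrm: bool = True
    enable_lrsa: bool = True
    lrsa_heads: int = 4
    lrsa_ffn_expansion: int = 4
    lrsa_mask_padding: bool = False
    num_classes: int = 2
    dropout: float = 0.5
    seed: int = 0

    @property
    def in_channels(self) -> int:
        return 3 + self.in_extra_channels

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sa_levels"] = [asdict(s) for s in self.sa_levels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["sa_levels"] = tuple(
            SALevelSpec(out_points=s["out_points"], radius_frac=s["radius_frac"],
                        neighbors=s["neighbors"], mlp=tuple(s["mlp"]))
            for s in d["sa_levels"]
        )
        d["fp_mlps"] = tuple(tuple(m) for m in d["fp_mlps"])
        return cls(**d)


class SegmentationNetwork(Module):
    """Hierarchical point-cloud semantic segmentation with local-structure
    enhancements at the SA2/SA3 junction."""

    def __init__(self, cfg: Optional[NetworkConfig] = None) -> None:
        super().__init__()
        self.cfg = cfg = cfg or NetworkConfig()
        rng = np.random.default_rng(cfg.seed)

        sa = []
        in_ch = cfg.in_channels
        for spec in cfg.sa_levels:
            sa.append(SetAbstraction(spec.out_points, spec.radius_frac,
                                     spec.neighbors, in_ch, spec.mlp, rng))
            in_ch = spec.mlp[-1]
        self.sa = ModuleList(sa)

        junction_ch = cfg.sa_levels[1].mlp[-1]
        self.rpe = RelativePositionEncoding(junction_ch, rng) if cfg.enable_rpe else None
        self.lrsa = (LocalRegionSelfAttention(junction_ch, cfg.lrsa_heads,
                                              cfg.lrsa_ffn_expansion, rng,
                                              mask_padding=cfg.lrsa_mask_padding)
                     if cfg.enable_lrsa else None)

        # FP chain, coarsest to finest; skip widths are the SA outputs
        level_ch = [None] + [s.mlp[-1] for s in cfg.sa_levels]   # per level 0..4
        fp = []
        for i, mlp in enumerate(cfg.fp_mlps):
            coarse_ch = level_ch[4 - i] if i == 0 else cfg.fp_mlps[i - 1][-1]
            skip_ch = level_ch[3 - i] or 0
            fp.append(FeaturePropagation(coarse_ch + skip_ch, mlp, rng))
        self.fp = ModuleList(fp)

        head_ch = cfg.fp_mlps[-1][-1]
        self.head_conv = PointwiseConv(head_ch, head_ch, rng)
        self.head_bn = BatchNormC(head_ch)
        self.head_dropout = Dropout(cfg.dropout, np.random.default_rng(cfg.seed + 1))
        self.head_out = PointwiseConv(head_ch, cfg.num_classes, rng)

    def forward(self, coords: np.ndarray, feats: np.ndarray) -> Tensor:
        """Per-point class scores ``(B, N, num_classes)`` (unnormalized).

        ``coords`` is ``(B, 3, N)``; ``feats`` is ``(B, 9, N)`` (coordinates
        + color + normal).
        """
        if feats.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {feats.shape[1]}"
            )
        levels: List[FeatureMap] = [FeatureMap(coords=np.asarray(coords, dtype=float),
                                               feats=Tensor(feats))]
        for i, sa in enumerate(self.sa):
            out = sa(levels[-1])
            if i == 1:
                out = self._enhance(out)
            levels.append(out)

        current = levels[-1]
        for i, fp in enumerate(self.fp):
            fine = levels[3 - i]
            current = fp(current, fine.coords, fine.feats if (3 - i) > 0 else None)

        x = self.head_bn(self.head_conv(current.feats)).relu()
        x = self.head_dropout(x)
        scores = self.head_out(x)                     # (B, K, N)
        return scores.transpose(0, 2, 1)

    __call__ = forward

    def _enhance(self, fmap: FeatureMap) -> FeatureMap:
        if self.rpe is not None:
            fmap = self.rpe(fmap)
        if self.lrsa is not None:
            gmap = lgrm_rearrange(fmap.feats)
            gmap = self.lrsa(gmap)
            fmap = FeatureMap(coords=fmap.coords, feats=lgrm_flatten(gmap))
        elif self.cfg.enable_lgrm:
            # rearrangement alone is its own inverse: shapes pass through
            fmap = FeatureMap(coords=fmap.coords,
                              feats=lgrm_flatten(lgrm_rearrange(fmap.feats)))
        return fmap

    def predict(self, coords: np.ndarray, feats: np.ndarray) -> np.ndarray:
        """Hard labels ``(B, N)`` in evaluation mode."""
        was_training = self.training
        self.eval()
        try:
            scores = self.forward(coords, feats)
        finally:
            if was_training:
                self.train()
        return scores.data.argmax(axis=2)


def cross_entropy(scores: Tensor, labels: np.ndarray,
                  class_weights: Optional[np.ndarray] = None) -> Tensor:
    """Point-wise cross-entropy of ``(B, N, K)`` scores against integer labels.

    With ``class_weights`` the per-point losses are weighted by their true
    class and normalized by the total weight (inverse-frequency weighting
    hook for imbalanced scenes).
    """
    b, n, k = scores.shape
    labels = np.asarray(labels)
    onehot = np.zeros((b, n, k))
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=2)
    logp = scores.log_softmax(axis=2)
    nll = -(logp * Tensor(onehot)).sum(axis=2)            # (B, N)
    if class_weights is None:
        return nll.mean()
    w = np.asarray(class_weights, dtype=float)[labels]
    return (nll * Tensor(w)).sum() * (1.0 / w.sum())


def save_checkpoint(path, model: SegmentationNetwork) -> None:
    """Write config + parameters to a single ``.npz`` file."""
    state = model.state_dict()
    cfg_bytes = np.frombuffer(json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, __config__=cfg_bytes,
             **{k.replace(".", "/"): v for k, v in state.items()})


def load_checkpoint(path) -> SegmentationNetwork:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        cfg = NetworkConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
        state = {k.replace("/", "."): data[k] for k in data.files if k != "__config__"}
    model = SegmentationNetwork(cfg)
    model.load_state_dict(state)
    return model
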
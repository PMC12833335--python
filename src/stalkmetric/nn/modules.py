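"""Neural-network building blocks on top of the autodiff engine.

Minimal module system: parameters are :class:`Tensor` objects with
``requires_grad=True``, modules discover them (and submodules) by attribute
reflection, and ``state_dict``/``load_state_dict`` address them by dotted
path. Layers operate channel-major: activations are ``(B, C, ...)``.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .autograd import Tensor, channel_linear, normalize_affine

__all__ = ["Module", "ModuleList", "PointwiseConv", "BatchNormC", "LayerNormC",
           "Dropout", "MLPStack", "AdamW"]


class Module:
    """Base class: parameter/submodule discovery, train/eval mode, state dict."""

    def __init__(self) -> None:
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, np.ndarray):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_buffers(prefix=full + ".")

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                target = buffers[key[len("buffer:"):]]
                target[...] = value
            else:
                params[key].data[...] = value


class ModuleList(Module):
    """Sequence container whose items participate in reflection."""

    def __init__(self, items) -> None:
        super().__init__()
        self._items = list(items)
        for i, item in enumerate(self._items):
            setattr(self, f"item{i}", item)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)


class PointwiseConv(Module):
    """Shared 1x1 convolution: weight ``(C_out, C_in)`` applied along axis 1."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False) -> None:
        super().__init__()
        if zero_init:
            w = np.zeros((out_channels, in_channels))
        else:
            bound = np.sqrt(6.0 / (in_channels + out_channels))
            w = rng.uniform(-bound, bound, (out_channels, in_channels))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = channel_linear(self.weight, x)
        if self.bias is not None:
            y = y + self.bias.reshape((1, -1) + (1,) * (x.ndim - 2))
        return y


class BatchNormC(Module):
    """Batch normalization over all axes except the channel axis (axis 1).

    Training mode uses batch statistics and updates running estimates;
    evaluation mode uses the running estimates, making inference
    deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        shape = (1, -1) + (1,) * (x.ndim - 2)
        if self.training:
            axes = (0,) + tuple(range(2, x.ndim))
            y, mean, var = normalize_affine(x, self.gamma, self.beta, axes, self.eps)
            self.running_mean += self.momentum * (mean.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.reshape(-1) - self.running_var)
            return y
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.gamma.data * inv).reshape(shape)
        offset = (self.beta.data - self.gamma.data * self.running_mean * inv).reshape(shape)
        return x * Tensor(scale) + Tensor(offset)


class LayerNormC(Module):
    """Layer normalization across the channel axis, per position."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        y, _, _ = normalize_affine(x, self.gamma, self.beta, (1,), self.eps)
        return y


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MLPStack(Module):
    """[PointwiseConv -> BatchNorm -> ReLU] blocks sharing weights per point."""

    def __init__(self, channels, rng: np.random.Generator) -> None:
        super().__init__()
        convs, bns = [], []
        for cin, cout in zip(channels[:-1], channels[1:]):
            convs.append(PointwiseConv(cin, cout, rng))
            bns.append(BatchNormC(cout))
        self.convs = ModuleList(convs)
        self.bns = ModuleList(bns)

    def __call__(self, x: Tensor) -> Tensor:
        for conv, bn in zip(self.convs, self.bns):
            x = bn(conv(x)).relu()
        return x


class AdamW(Module):
    """AdamW optimizer (decoupled weight decay)."""

    def __init__(self, params: List[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01) -> None:
        super().__init__()
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
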
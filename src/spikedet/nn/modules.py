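"""Module/parameter containers and the SGD optimizer."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, batch_norm2d, conv2d

__all__ = ["Parameter", "Module", "ModuleList", "Conv2d", "BatchNorm2d",
           "Linear", "Identity", "SGD"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: attribute-scanned parameter/buffer traversal."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # -- traversal ------------------------------------------------------------
    def _components(self):
        for name, value in vars(self).items():
            if name.startswith("_") and name != "_buffers":
                continue
            yield name, value

    def named_parameters(self, prefix: str = ""):
        for name, value in self._components():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for _, value in self._components():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_buffers(self, prefix: str = ""):
        for name, value in self._components():
            key = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{key}.{i}.")
        for bname, arr in self._buffers.items():
            yield f"{prefix}{bname}", arr

    # -- bookkeeping ----------------------------------------------------------
    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                target = buffers[key[len("buffer:"):]]
                target[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{p.data.shape} vs {value.shape}")
                p.data = np.asarray(value, dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, items=()):
        super().__init__()
        self.items = list(items)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]


class Conv2d(Module):
    """Plain 2-D convolution; He-normal weight init, optional bias."""

    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        std = math.sqrt(2.0 / (c_in * k * k))
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self._buffers = {
            "running_mean": np.zeros(c, dtype=np.float32),
            "running_var": np.ones(c, dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(
            x, self.weight, self.bias,
            self._buffers["running_mean"], self._buffers["running_var"],
            self.training, self.momentum, self.eps,
        )


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / c_in)
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.T
        if self.bias is not None:
            y = y + self.bias
        return y


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay.

    ``param_groups`` is a list of dicts with keys ``params`` and optional
    ``weight_decay``; decay is conventionally disabled for batch-norm affine
    parameters and biases by putting them in a zero-decay group.
    """

    def __init__(self, param_groups, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        if param_groups and isinstance(param_groups[0], Parameter):
            param_groups = [{"params": list(param_groups)}]
        self.groups = []
        for group in param_groups:
            g = {"params": list(group["params"]),
                 "weight_decay": group.get("weight_decay", weight_decay)}
            self.groups.append(g)
        self.lr = lr
        self.momentum = momentum
        self._velocity: dict[int, np.ndarray] = {}

    def zero_grad(self):
        for group in self.groups:
            for p in group["params"]:
                p.grad = None

    def step(self):
        for group in self.groups:
            wd = group["weight_decay"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                g = p.grad
                if wd:
                    g = g + wd * p.data
                v = self._velocity.get(id(p))
                if v is None:
                    v = np.zeros_like(p.data)
                    self._velocity[id(p)] = v
                v *= self.momentum
                v += g
                p.data -= self.lr * v
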
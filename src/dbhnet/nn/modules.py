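"""Layer/module system: parameter registration, state dicts, common layers."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .functional import conv2d, max_pool2d
from .tensor import Parameter, Tensor

__all__ = [
    "Module", "ModuleList", "Sequential", "Identity",
    "Conv2d", "Linear", "BatchNorm2d", "LayerNorm", "MaxPool2d",
    "ReLU", "GELU", "manual_seed", "get_rng",
]

_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the global generator used for parameter initialization."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _RNG


def _trunc_normal(shape, std: float = 0.02) -> np.ndarray:
    vals = _RNG.normal(0.0, std, size=shape)
    return np.clip(vals, -2 * std, 2 * std).astype(np.float32)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # ------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # ------------------------------------------------------------ state dict
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data
        for name, b in self._buffers.items():
            out[prefix + name] = np.asarray(getattr(self, name))
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray],
                        strict: bool = True) -> dict[str, list[str]]:
        own = self.state_dict()
        missing = [k for k in own if k not in state]
        unexpected = [k for k in state if k not in own]
        mismatched = []
        for key, value in state.items():
            if key not in own:
                continue
            if own[key].shape != np.asarray(value).shape:
                mismatched.append(key)
                continue
            self._assign(key, np.asarray(value))
        report = {"missing": missing, "unexpected": unexpected,
                  "mismatched": mismatched}
        if strict and (missing or unexpected or mismatched):
            raise ValueError(f"state dict mismatch: {report}")
        return report

    def _assign(self, key: str, value: np.ndarray) -> None:
        head, _, rest = key.partition(".")
        if rest:
            self._modules[head]._assign(rest, value)
        elif head in self._params:
            self._params[head].data = value.astype(
                self._params[head].data.dtype)
        elif head in self._buffers:
            self._buffers[head] = value
            object.__setattr__(self, head, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._list)


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2, stride: int | None = None,
                 padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class Conv2d(Module):
    """3×3/1×1 convolution with Kaiming-normal weight initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            _RNG.normal(0.0, std, (out_ch, in_ch, kernel, kernel))
            .astype(np.float32))
        self.bias = Parameter(np.zeros(out_ch, np.float32)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.dilation)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_trunc_normal((out_f, in_f)))
        self.bias = Parameter(np.zeros(out_f, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features, np.float32))
        self.bias = Parameter(np.zeros(num_features, np.float32))
        self.register_buffer("running_mean",
                             np.zeros(num_features, np.float32))
        self.register_buffer("running_var", np.ones(num_features, np.float32))
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            rm = (1 - m) * self.running_mean + m * mean.data.ravel()
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            rv = (1 - m) * self.running_var + m * unbiased
            self.register_buffer("running_mean", rm.astype(np.float32))
            self.register_buffer("running_var", rv.astype(np.float32))
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        inv = (var + self.eps) ** -0.5
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return (x - mean) * inv * w + b


class LayerNorm(Module):
    """Normalization over the trailing feature dimension."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim, np.float32))
        self.bias = Parameter(np.zeros(dim, np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mean) * (var + self.eps) ** -0.5 * self.weight + self.bias
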
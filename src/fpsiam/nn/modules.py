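"""Neural-network building blocks over the autodiff engine.

Modules follow the familiar container protocol: ``parameters()``,
``named_parameters()``, ``state_dict()`` / ``load_state_dict()`` and a
train/eval mode switch that controls batch-norm statistics.  Parameter
initialisation is driven by an explicit :class:`numpy.random.Generator`
so every construction is reproducible from a seed.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .tensor import Tensor, conv2d, max_pool2d


class Module:
    def __init__(self) -> None:
        self._modules: Dict[str, "Module"] = {}
        self._params: Dict[str, Tensor] = {}
        self._buffers: Dict[str, np.ndarray] = {}
        self.training = True

    # attribute magic keeps registration implicit, as users expect
    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own_params = dict(self.named_parameters())
        own_bufs = self._named_buffer_owners()
        missing = (set(own_params) | set(own_bufs)) - set(state)
        if missing:
            raise KeyError(f"state dict missing keys: {sorted(missing)}")
        for name, p in own_params.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data[...] = arr
        for name, (mod, local) in own_bufs.items():
            arr = np.asarray(state[name], dtype=np.float32)
            mod._buffers[local][...] = arr

    def _named_buffer_owners(self, prefix: str = "") -> Dict[str, Tuple["Module", str]]:
        out: Dict[str, Tuple[Module, str]] = {}
        for name in self._buffers:
            out[prefix + name] = (self, name)
        for mname, m in self._modules.items():
            out.update(m._named_buffer_owners(prefix + mname + "."))
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def kaiming_normal(rng: np.random.Generator, shape: Tuple[int, ...],
                   fan: int) -> np.ndarray:
    """He-style normal init, std = sqrt(2 / fan)."""
    std = np.sqrt(2.0 / fan)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        fan_out = out_channels * kernel_size * kernel_size
        self.stride, self.padding = stride, padding
        self.weight = Tensor(kaiming_normal(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_out),
            requires_grad=True)
        self.bias = (Tensor(np.zeros(out_channels, dtype=np.float32),
                            requires_grad=True) if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_features, out_features))
            .astype(np.float32), requires_grad=True)
        self.bias = (Tensor(np.zeros(out_features, dtype=np.float32),
                            requires_grad=True) if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class _BatchNorm(Module):
    """Shared train/eval batch-norm logic; subclasses define the reduce axes."""

    reduce_axes: Tuple[int, ...] = (0,)

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 affine: bool = True):
        super().__init__()
        self.num_features = num_features
        self.eps, self.momentum, self.affine = eps, momentum, affine
        if affine:
            self.weight = Tensor(np.ones(num_features, dtype=np.float32),
                                 requires_grad=True)
            self.bias = Tensor(np.zeros(num_features, dtype=np.float32),
                               requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def _param_shape(self, ndim: int) -> Tuple[int, ...]:
        shape = [1] * ndim
        shape[1 if ndim == 4 else -1] = self.num_features
        return tuple(shape)

    def forward(self, x: Tensor) -> Tensor:
        axes = self.reduce_axes if x.ndim == 4 else (0,)
        shape = self._param_shape(x.ndim)
        if self.training:
            n = int(np.prod([x.shape[a] for a in axes]))
            if n < 2:
                raise ValueError(
                    "batch norm in training mode needs at least 2 reduced "
                    f"elements per channel, got {n} (batch of 1?)")
            mean = x.mean(axis=axes, keepdims=True)
            centred = x - mean
            var = (centred * centred).mean(axis=axes, keepdims=True)
            # running stats track the unbiased variance, torch-style
            m = self.momentum
            batch_mean = mean.data.reshape(self.num_features)
            batch_var = var.data.reshape(self.num_features) * n / max(n - 1, 1)
            self._buffers["running_mean"] *= (1 - m)
            self._buffers["running_mean"] += m * batch_mean
            self._buffers["running_var"] *= (1 - m)
            self._buffers["running_var"] += m * batch_var
            xhat = centred * ((var + self.eps) ** -0.5)
        else:
            rm = self._buffers["running_mean"].reshape(shape)
            rv = self._buffers["running_var"].reshape(shape)
            xhat = (x - Tensor(rm)) * Tensor((rv + self.eps) ** -0.5)
        if self.affine:
            return xhat * self.weight.reshape(*shape) + self.bias.reshape(*shape)
        return xhat


class BatchNorm1d(_BatchNorm):
    reduce_axes = (0,)


class BatchNorm2d(_BatchNorm):
    reduce_axes = (0, 2, 3)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
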
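"""Neural-network building blocks on top of the autodiff engine.

Modules follow a torch-like contract: attribute assignment registers
parameters and child modules, ``named_parameters`` yields dotted names,
and ``state_dict``/``load_state_dict`` round-trip all parameters and
buffers (batch-norm running statistics) as plain numpy arrays.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np

from .autodiff import Tensor, conv3d, linear

__all__ = ["Module", "ModuleList", "Conv3d", "BatchNorm3d", "Linear", "SGD"]


class Module:
    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    # -- traversal ------------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[Tuple[str, "Module"]]:
        yield prefix, self
        for name, child in self._modules.items():
            child_prefix = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(child_prefix)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for mod_name, module in self.named_modules(prefix):
            for name, param in module._params.items():
                yield (f"{mod_name}.{name}" if mod_name else name), param

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for mod_name, module in self.named_modules(prefix):
            for name in module._buffers:
                yield (f"{mod_name}.{name}" if mod_name else name), module._buffers[name]

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    # -- train / eval ---------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for _, module in self.named_modules():
            object.__setattr__(module, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- serialization --------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {f"param/{n}": p.data.copy() for n, p in self.named_parameters()}
        state.update({f"buffer/{n}": b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        expected = {f"param/{n}" for n in params}
        buffer_owners = {}
        for mod_name, module in self.named_modules():
            for name in module._buffers:
                full = f"{mod_name}.{name}" if mod_name else name
                buffer_owners[full] = (module, name)
        expected |= {f"buffer/{n}" for n in buffer_owners}
        if set(state) != expected:
            missing = expected - set(state)
            extra = set(state) - expected
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for key, value in state.items():
            kind, name = key.split("/", 1)
            if kind == "param":
                target = params[name]
                if target.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                target.data = np.array(value, dtype=np.float64)
            else:
                module, attr = buffer_owners[name]
                module._set_buffer(attr, np.array(value, dtype=np.float64))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: List[Module] = []
        for module in modules:
            self.append(module)

    def append(self, module: Module) -> None:
        setattr(self, str(len(self._list)), module)
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, index: int) -> Module:
        return self._list[index]

    def __len__(self) -> int:
        return len(self._list)


class Conv3d(Module):
    """3-D convolution with He-normal initialization."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size**3
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels) + (kernel_size,) * 3),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm3d(Module):
    """Per-channel normalization over the spatial axes of a (C, D, H, W) map.

    The network always sees a single sample (batch size 1 throughout), so
    "batch" statistics are the spatial statistics of the current input.
    In training mode the input's own statistics normalize it and running
    statistics are updated unless ``update_running`` is off — adaptation
    reuses training-mode statistics without touching the running buffers.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.update_running = True
        self.weight = Tensor(np.ones(channels), requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        gamma = self.weight.reshape(self.channels, 1, 1, 1)
        beta = self.bias.reshape(self.channels, 1, 1, 1)
        if self.training:
            mean = x.mean(axis=(1, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(1, 2, 3), keepdims=True)
            if self.update_running:
                m = self.momentum
                self._set_buffer(
                    "running_mean",
                    (1 - m) * self.running_mean + m * mean.data.reshape(-1),
                )
                self._set_buffer(
                    "running_var",
                    (1 - m) * self.running_var + m * var.data.reshape(-1),
                )
            xn = (x - mean) * ((var + self.eps) ** -0.5)
        else:
            mean = self.running_mean.reshape(self.channels, 1, 1, 1)
            std_inv = (self.running_var.reshape(self.channels, 1, 1, 1) + self.eps) ** -0.5
            xn = (x - mean) * std_inv
        return gamma * xn + beta


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_features, in_features)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class SGD:
    """Stochastic gradient descent with optional classical momentum."""

    def __init__(self, params: List[Tensor], lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            if self.momentum:
                v *= self.momentum
                v += p.grad
                p.data -= self.lr * v
            else:
                p.data -= self.lr * p.grad
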
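"""Layer/module abstractions over the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module base: parameter discovery, train/eval mode, dtype cast."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for mod in self.modules():
            for v in mod.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def named_parameters(self) -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []

        def visit(mod, prefix):
            for k, v in mod.__dict__.items():
                if isinstance(v, Parameter):
                    out.append((f"{prefix}{k}", v))
                elif isinstance(v, Module):
                    visit(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{k}.{i}.")

        visit(self, "")
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def to_dtype(self, dtype):
        """Cast all parameters and buffers (in place); used by gradient checks."""
        for mod in self.modules():
            for k, v in list(mod.__dict__.items()):
                if isinstance(v, Parameter):
                    v.data = v.data.astype(dtype)
                elif isinstance(v, np.ndarray):
                    mod.__dict__[k] = v.astype(dtype)
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}

        def visit(mod, prefix):
            for k, v in mod.__dict__.items():
                if isinstance(v, np.ndarray):
                    state[f"{prefix}{k}"] = v.copy()
                elif isinstance(v, Module):
                    visit(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{k}.{i}.")

        visit(self, "")
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        for name, p in named.items():
            p.data = np.array(state[name], dtype=p.data.dtype)

        def visit(mod, prefix):
            for k, v in list(mod.__dict__.items()):
                if isinstance(v, np.ndarray):
                    key = f"{prefix}{k}"
                    if key in state:
                        mod.__dict__[k] = np.array(state[key], dtype=v.dtype)
                elif isinstance(v, Module):
                    visit(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{k}.{i}.")

        visit(self, "")


class Conv3d(Module):
    """3x3x3 or 1x1x1 convolution, stride 1, 'same' padding, Kaiming init."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True, zero_init: bool = False):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel ** 3
        if zero_init:
            w = np.zeros((kernel, kernel, kernel, in_channels, out_channels))
        else:
            std = np.sqrt(2.0 / fan_in)
            w = rng.normal(0.0, std, size=(kernel, kernel, kernel, in_channels, out_channels))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv3d(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MaxPool3d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.maxpool3d(x)


class UpsampleNearest3d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.upsample_nearest3d(x)


def conv_bn_relu(cin: int, cout: int, kernel: int, rng: np.random.Generator) -> Sequential:
    # bias omitted: the batch norm's shift makes it redundant
    return Sequential(Conv3d(cin, cout, kernel, rng, bias=False), BatchNorm3d(cout), ReLU())
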
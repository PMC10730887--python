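"""Network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d


class Module:
    """Base class: parameter discovery by attribute walk, like the big
    frameworks but without buffers or training/eval modes (no norm layers)."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        out.append(item)
        return out

    def named_parameters(self, prefix=""):
        out = []
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor):
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(f"{name}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{name}.{i}."))
                    elif isinstance(item, Tensor):
                        out.append((f"{name}.{i}", item))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in self.named_parameters():
            if k not in state:
                raise KeyError(f"missing parameter {k}")
            if state[k].shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            v.data = np.asarray(state[k], dtype=v.data.dtype).copy()

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, pad=None, groups=1,
                 bias=True, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin // groups * k * k
        std = np.sqrt(2.0 / fan_in)  # He init for relu nets
        self.weight = Tensor(rng.normal(0, std, (cout, cin // groups, k, k))
                             .astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride, self.pad, self.groups = stride, pad, groups

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad,
                      self.groups)


class Linear(Module):
    def __init__(self, cin, cout, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin)
        self.weight = Tensor(rng.normal(0, std, (cin, cout)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x):
        return x.matmul(self.weight) + self.bias


class SqueezeExcite(Module):
    """Global pooling -> bottleneck MLP -> per-channel sigmoid gate."""

    def __init__(self, channels, reduction=8, rng=None):
        hidden = max(4, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x):
        n, c = x.shape[0], x.shape[1]
        s = x.global_avg_pool().reshape(n, c)
        s = self.fc2(self.fc1(s).relu()).sigmoid().reshape(n, c, 1, 1)
        return x * s


class SEResNeXtBlock(Module):
    """1x1 reduce -> grouped 3x3 -> 1x1 expand -> SE gate -> residual."""

    def __init__(self, channels, cardinality=8, se_reduction=8, rng=None):
        mid = max(cardinality, channels // 2)
        mid -= mid % cardinality  # grouped conv needs divisibility
        self.reduce = Conv2d(channels, mid, k=1, rng=rng)
        self.grouped = Conv2d(mid, mid, k=3, groups=cardinality, rng=rng)
        self.expand = Conv2d(mid, channels, k=1, rng=rng)
        self.se = SqueezeExcite(channels, se_reduction, rng)

    def forward(self, x):
        y = self.reduce(x).relu()
        y = self.grouped(y).relu()
        y = self.expand(y)
        y = self.se(y)
        return (y + x).relu()


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
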
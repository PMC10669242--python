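"""Neural-network modules built on the autograd engine.

Layout convention is NCHW throughout. Weight initialisation draws from a
`numpy.random.Generator` passed to ``init_parameters`` so that model
construction is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import (Tensor, Parameter, conv2d, max_pool2d,
                       adaptive_avg_pool2d, interpolate_bilinear, concat)

__all__ = [
    "Module", "Sequential", "Identity", "Conv2d", "Linear", "LayerNorm",
    "ChannelLayerNorm", "BatchNorm2d", "GELU", "ReLU", "MaxPool2d", "GRN",
]

_PROFILE_STACK: list[dict] = []


def profiling_scope(counter: dict):
    """Internal: collect per-layer multiply-accumulate counts into `counter`."""

    class _Scope:
        def __enter__(self):
            _PROFILE_STACK.append(counter)
            return counter

        def __exit__(self, *exc):
            _PROFILE_STACK.pop()
            return False

    return _Scope()


def _record_macs(kind: str, macs: int):
    if _PROFILE_STACK:
        counter = _PROFILE_STACK[-1]
        counter[kind] = counter.get(kind, 0) + int(macs)


class Module:
    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()

    def init_parameters(self, rng: np.random.Generator):
        """Re-initialise all parameters from `rng` (depth-first, deterministic)."""
        self._init_self(rng)
        for _, m in sorted(self._modules.items()):
            m.init_parameters(rng)
        return self

    def _init_self(self, rng):  # overridden by leaf layers
        pass

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.items = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.items)


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, groups=1,
                 bias=True, pad_mode="zeros"):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.padding, self.groups = stride, padding, groups
        self.pad_mode = pad_mode
        self.weight = Parameter(np.zeros((out_ch, in_ch // groups, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self._init_self(np.random.default_rng(0))

    def _init_self(self, rng):
        fan_in = (self.in_ch // self.groups) * self.kernel ** 2
        std = np.sqrt(2.0 / fan_in)
        self.weight.data = rng.normal(0.0, std, self.weight.shape).astype(np.float64)
        if self.bias is not None:
            self.bias.data = np.zeros(self.out_ch, dtype=np.float64)

    def forward(self, x):
        out = conv2d(x, self.weight, self.bias, self.stride, self.padding,
                     self.groups, self.pad_mode)
        _record_macs("conv", (self.kernel ** 2) * (self.in_ch // self.groups)
                     * self.out_ch * out.shape[-2] * out.shape[-1] * out.shape[0])
        return out


class Linear(Module):
    def __init__(self, in_f, out_f, bias=True):
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        self.weight = Parameter(np.zeros((in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None
        self._init_self(np.random.default_rng(0))

    def _init_self(self, rng):
        std = np.sqrt(1.0 / self.in_f)
        self.weight.data = rng.uniform(-std, std, self.weight.shape).astype(np.float64)
        if self.bias is not None:
            self.bias.data = rng.uniform(-std, std, self.out_f).astype(np.float64)

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        _record_macs("linear", self.in_f * self.out_f * int(np.prod(x.shape[:-1])))
        return out


class LayerNorm(Module):
    """Normalisation over the trailing feature axis (token layout)."""

    def __init__(self, dim, eps=1e-6):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def _init_self(self, rng):
        self.weight.data = np.ones(self.dim, dtype=np.float64)
        self.bias.data = np.zeros(self.dim, dtype=np.float64)

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.weight + self.bias


class ChannelLayerNorm(Module):
    """LayerNorm across the channel axis of an NCHW map (per position)."""

    def __init__(self, dim, eps=1e-6):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def _init_self(self, rng):
        self.weight.data = np.ones(self.dim, dtype=np.float64)
        self.bias.data = np.zeros(self.dim, dtype=np.float64)

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xn = xc / ((var + self.eps) ** 0.5)
        w = self.weight.reshape(1, self.dim, 1, 1)
        b = self.bias.reshape(1, self.dim, 1, 1)
        return xn * w + b


class BatchNorm2d(Module):
    def __init__(self, dim, eps=1e-5, momentum=0.1):
        super().__init__()
        self.dim, self.eps, self.momentum = dim, eps, momentum
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim, dtype=np.float64)
        self.running_var = np.ones(dim, dtype=np.float64)

    def _init_self(self, rng):
        self.weight.data = np.ones(self.dim, dtype=np.float64)
        self.bias.data = np.zeros(self.dim, dtype=np.float64)
        self.running_mean[:] = 0.0
        self.running_var[:] = 1.0

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xc = x - mu
        xn = xc / ((var + self.eps) ** 0.5)
        w = self.weight.reshape(1, self.dim, 1, 1)
        b = self.bias.reshape(1, self.dim, 1, 1)
        return xn * w + b


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel, stride, padding=0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class GRN(Module):
    """Global response normalisation.

    Each channel's spatial L2 norm is divided by the mean norm over channels;
    the input is rescaled by that ratio (times ``gamma``), shifted by ``beta``
    and added back residually.  With both parameters at their zero
    initialisation the layer is the identity.
    """

    def __init__(self, dim, eps=1e-6):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.gamma = Parameter(np.zeros(dim))
        self.beta = Parameter(np.zeros(dim))

    def _init_self(self, rng):
        self.gamma.data = np.zeros(self.dim, dtype=np.float64)
        self.beta.data = np.zeros(self.dim, dtype=np.float64)

    def forward(self, x):
        # tiny constant inside the root keeps the gradient finite for a
        # channel that is exactly zero
        gx = ((x * x).sum(axis=(2, 3), keepdims=True) + 1e-24) ** 0.5  # (N,C,1,1)
        nx = gx / (gx.mean(axis=1, keepdims=True) + self.eps)
        g = self.gamma.reshape(1, self.dim, 1, 1)
        b = self.beta.reshape(1, self.dim, 1, 1)
        return g * (x * nx) + b + x
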
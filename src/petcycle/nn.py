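"""Convolutional building blocks on top of the autodiff engine.

Layers follow the conventions of image-translation GANs: 3x3 convolutions,
stride-2 downsampling, zero-insertion + convolution for stride-2
transposed convolution, instance/batch normalization, leaky rectifiers,
and spectral normalization for critics.  Parameters are float32 numpy
arrays (CPU throughput) initialized from an explicit RNG so construction
is deterministic.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


#: dtype for layer parameters; float32 keeps CPU training throughput up
DTYPE = np.float32


class Module:
    """Base class: tracks parameters of itself and registered children."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self._buffer_names: list[str] = []

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        t = ad.parameter(np.asarray(array, dtype=DTYPE))
        self._params[name] = t
        return t

    def register_buffer(self, name: str, array: np.ndarray) -> np.ndarray:
        """Non-learnable state that still belongs in checkpoints
        (power-iteration vectors, running statistics)."""
        object.__setattr__(self, name, array)
        self._buffer_names.append(name)
        return array

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for cname, child in self._children.items():
            out.update(child.named_parameters(prefix + cname + "."))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + "buf:" + n: getattr(self, n)
               for n in self._buffer_names}
        for cname, child in self._children.items():
            out.update(child.named_buffers(prefix + cname + "."))
        return out

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            mod = mod._children[part]
        object.__setattr__(mod, parts[-1].removeprefix("buf:"), value.copy())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters().items()}
        out.update({k: np.asarray(v).copy()
                    for k, v in self.named_buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = self.named_parameters()
        buffers = self.named_buffers()
        missing = (set(named) | set(buffers)) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]}")
        for k, t in named.items():
            if t.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data[...] = state[k]
        for k in buffers:
            self._set_buffer(k, state[k])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._children[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# convolutions (im2col + batched matmul)
# ---------------------------------------------------------------------------

def _patch_indices(c: int, h: int, w: int, kh: int, kw: int,
                   stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Flat gather indices into a zero-padded (c, h+2p, w+2p) image giving
    rows of shape (oh*ow, c*kh*kw)."""
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    ci, ki, kj = np.meshgrid(np.arange(c), np.arange(kh), np.arange(kw),
                             indexing="ij")
    patch = (ci * hp * wp + ki * wp + kj).reshape(-1)          # c*kh*kw
    oi, oj = np.meshgrid(np.arange(oh) * stride, np.arange(ow) * stride,
                         indexing="ij")
    origin = (oi * wp + oj).reshape(-1)                        # oh*ow
    return origin[:, None] + patch[None, :], oh, ow


class Conv2d(Module):
    """2-D convolution (cross-correlation), square kernel, zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: int = 1, pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 init_std: float | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        # fan-in-scaled init preserves signal magnitude through deep
        # stacks regardless of channel width (a fixed small std starves
        # narrow test-scale networks)
        std = init_std if init_std is not None else np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(fan_in, out_ch))
        self.weight = self.register("weight", w)
        self.bias = self.register("bias", np.zeros(out_ch)) if bias else None
        self._idx_cache: dict[tuple, tuple] = {}

    def _weight(self) -> Tensor:
        return self.weight

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        key = (h, w)
        if key not in self._idx_cache:
            self._idx_cache[key] = _patch_indices(
                c, h, w, self.kernel, self.kernel, self.stride, self.pad)
        idx, oh, ow = self._idx_cache[key]
        xp = ad.pad2d(x, self.pad)
        flat = ad.reshape(xp, (b, c * xp.shape[2] * xp.shape[3]))
        cols = ad.take_patches(flat, idx)            # (b, oh*ow, c*k*k)
        out = ad.matmul(cols, self._weight())        # (b, oh*ow, out_ch)
        if self.bias is not None:
            out = out + self.bias
        out = ad.transpose(out, (0, 2, 1))
        return ad.reshape(out, (b, self.out_ch, oh, ow))


class ConvTranspose2d(Module):
    """Stride-2 learned upsampling: zero insertion followed by a stride-1
    convolution (equivalent parameterization of a transposed convolution)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 factor: int = 2, rng: np.random.Generator | None = None):
        super().__init__()
        self.factor = factor
        self.conv = Conv2d(in_ch, out_ch, kernel=kernel, stride=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(ad.dilate2d(x, self.factor))


class SpectralNorm(Module):
    """Spectral normalization wrapper for Conv2d.

    Divides the (flattened) kernel by its top singular value, estimated by
    one power-iteration step per forward call; the u/v vectors are buffers,
    not parameters, and the division is part of the differentiable graph.
    """

    def __init__(self, conv: Conv2d, n_power_iter: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv = conv
        self.n_power_iter = n_power_iter
        u = rng.normal(size=conv.weight.shape[1]).astype(DTYPE)
        self.register_buffer("u", u / np.linalg.norm(u))
        conv._weight = self._normalized_weight  # patch the kernel source

    def _normalized_weight(self) -> Tensor:
        w = self.conv.weight
        wd = w.data
        u = self.u
        for _ in range(self.n_power_iter):
            v = wd @ u
            v = v / (np.linalg.norm(v) + 1e-12)
            u = wd.T @ v
            u = u / (np.linalg.norm(u) + 1e-12)
        self.u = u
        # sigma = v^T W u with u, v treated as constants
        sigma = ad.sum_(ad.mul(ad.matmul(Tensor(v[None, :]), w),
                               Tensor(u[None, :])))
        return ad.div(w, sigma + 1e-12)

    def sigma(self) -> float:
        """Current top-singular-value estimate of the raw kernel."""
        return float(np.linalg.svd(self.conv.weight.data, compute_uv=False)[0])

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


# ---------------------------------------------------------------------------
# normalization / pooling / activations
# ---------------------------------------------------------------------------

class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        if affine:
            self.gamma = self.register("gamma", np.ones((1, channels, 1, 1)))
            self.beta = self.register("beta", np.zeros((1, channels, 1, 1)))
        else:
            self.gamma = self.beta = None

    def forward(self, x: Tensor) -> Tensor:
        mu = ad.mean_(x, axis=(2, 3), keepdims=True)
        xc = x - mu
        var = ad.mean_(xc * xc, axis=(2, 3), keepdims=True)
        y = xc / ad.sqrt(var + self.eps)
        if self.gamma is not None:
            y = y * self.gamma + self.beta
        return y


class BatchNorm2d(Module):
    """Batch-statistics normalization (training-mode statistics throughout;
    running averages are kept for inference)."""

    def __init__(self, channels: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = self.register("gamma", np.ones((1, channels, 1, 1)))
        self.beta = self.register("beta", np.zeros((1, channels, 1, 1)))
        self.register_buffer("running_mean",
                             np.zeros((1, channels, 1, 1), dtype=DTYPE))
        self.register_buffer("running_var",
                             np.ones((1, channels, 1, 1), dtype=DTYPE))
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = ad.mean_(x, axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = ad.mean_(xc * xc, axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data - self.running_mean)
            self.running_var += self.momentum * (var.data - self.running_var)
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
            xc = x - mu
        y = xc / ad.sqrt(var + self.eps)
        return y * self.gamma + self.beta


class AvgPool2d(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        f = self.factor
        if h % f or w % f:
            raise ValueError("spatial size not divisible by pool factor")
        y = ad.reshape(x, (b, c, h // f, f, w // f, f))
        return ad.mean_(y, axis=(3, 5))


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return ad.leaky_relu(x, self.slope)


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class Tanh(Module):
    def forward(self, x):
        return ad.tanh(x)


def make_norm(kind: str, channels: int) -> Module:
    if kind == "instance":
        return InstanceNorm2d(channels)
    if kind == "batch":
        return BatchNorm2d(channels)
    raise ValueError(f"unknown norm kind {kind!r}")


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the (0.5, 0.999) moment defaults of adversarial training."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.5, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {"m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v], "t": self.t}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src
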
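"""Neural-network layers, modules, and optimizers on the autodiff engine.

The module system mirrors the familiar stateful-layer idiom (parameters are
attributes, ``train()``/``eval()`` toggle batch-norm and dropout) with one
addition that the meta-learning stage relies on: *parameter substitution*.
``substituted(mapping)`` is a context manager that makes every layer resolve a
parameter through an override table, so a frozen pretrained network can be run
with scale/shift-modulated weights without copying or mutating the network
itself.
"""

from __future__ import annotations

import json
from contextlib import contextmanager

import numpy as np

from .autodiff import Tensor, conv1d, conv2d

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


# --------------------------------------------------------------- substitution
_OVERRIDES: list[dict[int, Tensor]] = []


@contextmanager
def substituted(mapping: dict):
    """Run a forward pass with parameters replaced by other tensors.

    ``mapping`` maps Parameter objects (or their ``id``) to replacement
    Tensors; replacement shapes must broadcast against the original.
    """
    table = {(k if isinstance(k, int) else id(k)): v for k, v in mapping.items()}
    _OVERRIDES.append(table)
    try:
        yield
    finally:
        _OVERRIDES.pop()


def P(param: Tensor) -> Tensor:
    """Resolve a parameter through the active substitution tables."""
    if _OVERRIDES:
        key = id(param)
        for table in reversed(_OVERRIDES):
            if key in table:
                return table[key]
    return param


# --------------------------------------------------------------------- module
class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield (prefix + name, p)
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # ---- persistence: parameters plus non-trainable buffers (running stats)
    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield (prefix + name, getattr(self, name))
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for k, v in self.named_buffers():
            if k in state:
                v[...] = state[k]
        for k, p in params.items():
            p.data = np.asarray(state[k], dtype=p.data.dtype).reshape(p.shape)

    def save(self, path, extra: dict | None = None):
        arrays = self.state_dict()
        meta = json.dumps(extra or {})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    def load(self, path) -> dict:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode()) if "__meta__" in z else {}
            self.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
        return meta


# --------------------------------------------------------------------- layers
def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    scale = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * scale).astype(DTYPE)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (out_dim, in_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ P(self.weight).swapaxes(-1, -2)
        if self.bias is not None:
            out = out + P(self.bias)
        return out


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.pad = stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, P(self.weight), P(self.bias) if self.bias is not None else None,
                      stride=self.stride, pad=self.pad)


class Conv1d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.pad = stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, P(self.weight), P(self.bias) if self.bias is not None else None,
                      stride=self.stride, pad=self.pad)


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis.

    ``channel_axis=1`` covers both (N, C, ...) convolutional maps and (N, C)
    feature matrices.  Running statistics are tracked for evaluation mode.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)
        object.__setattr__(self, "_buffer_names", ("running_mean", "running_var"))
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(x.ndim) if i != 1)
        shape = [1] * x.ndim
        shape[1] = x.shape[1]
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean.data.reshape(-1)).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1)).astype(DTYPE)
        else:
            mean = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xn = (x - mean) / ((var + self.eps) ** 0.5)
        return xn * P(self.gamma).reshape(shape) + P(self.beta).reshape(shape)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        return (x - mean) / ((var + self.eps) ** 0.5) * P(self.gamma) + P(self.beta)


class Dropout(Module):
    """Inverted dropout; the mask stream is seeded per model for determinism."""

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.max(axis=axis, keepdims=True).detach()
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def sinusoidal_positions(n: int, d: int) -> np.ndarray:
    """Standard fixed sinusoidal positional encoding table (n, d)."""
    pos = np.arange(n)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table.astype(DTYPE)


class MultiHeadSelfAttention(Module):
    def __init__(self, rng, d_model: int, n_heads: int):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads, self.d_head = d_model, n_heads, d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, T, d_model)
        b, t, _ = x.shape
        def split(h):  # (B, T, D) -> (B, H, T, dh)
            return h.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)
        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        out = attn @ v                                  # (B, H, T, dh)
        out = out.transpose(0, 2, 1, 3).reshape(b, t, self.d_model)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer block: x + MHA(LN(x)); x + FFN(LN(x)).

    The pre-norm arrangement keeps the residual stream on the scale of the
    input tokens, so modality amplitude differences survive encoding — the
    condition the knowledge-sharing transforms exist to repair.
    """

    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int):
        super().__init__()
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(rng, d_model, n_heads)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(rng, d_model, d_ff)
        self.ff2 = Linear(rng, d_ff, d_model)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).relu())


# ------------------------------------------------------------------ optimizer
def global_grad_norm(params) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    return float(np.sqrt(total))


def clip_grad_norm(params, max_norm: float) -> float:
    norm = global_grad_norm(params)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
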
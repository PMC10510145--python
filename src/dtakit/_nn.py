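"""Neural-network building blocks on top of the autodiff core.

Parameter containers are plain dicts name -> Tensor(requires_grad=True),
which makes checkpointing (`dtakit.train`) a direct dict-of-arrays dump.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "glorot", "Linear", "LayerNorm", "GRU", "SelfAttentionBlock",
    "Adam", "dropout", "ParamModule",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class ParamModule:
    """Base class: collects Tensor parameters of self and sub-modules."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, ParamModule):
                for sub, t in val.parameters().items():
                    out[f"{name}.{sub}"] = t
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, ParamModule):
                        for sub, t in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = t
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{name}.{i}"] = item
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, t in self.parameters().items():
            key = prefix + name
            if key not in state:
                raise KeyError(f"missing parameter in checkpoint: {key}")
            arr = np.asarray(state[key], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(
                    f"shape mismatch for {key}: checkpoint {arr.shape} "
                    f"vs model {t.data.shape}")
            t.data = arr.copy()

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        return {prefix + k: t.data.copy() for k, t in self.parameters().items()}


class Linear(ParamModule):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 bias: bool = True):
        self.W = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class LayerNorm(ParamModule):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class GRU(ParamModule):
    """Single-layer gated recurrent unit, unrolled over the time axis."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_hidden: int):
        self.d_hidden = d_hidden
        self.Wz = Tensor(glorot(rng, d_in, d_hidden), requires_grad=True)
        self.Uz = Tensor(glorot(rng, d_hidden, d_hidden), requires_grad=True)
        self.bz = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.Wr = Tensor(glorot(rng, d_in, d_hidden), requires_grad=True)
        self.Ur = Tensor(glorot(rng, d_hidden, d_hidden), requires_grad=True)
        self.br = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.Wn = Tensor(glorot(rng, d_in, d_hidden), requires_grad=True)
        self.Un = Tensor(glorot(rng, d_hidden, d_hidden), requires_grad=True)
        self.bn = Tensor(np.zeros(d_hidden), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        """x: [T, d_in] -> hidden states [T, d_hidden] (causal)."""
        T = x.shape[0]
        h = Tensor(np.zeros(self.d_hidden))
        outs = []
        for t in range(T):
            xt = x.take(np.array(t))
            z = (xt @ self.Wz + h @ self.Uz + self.bz).sigmoid()
            r = (xt @ self.Wr + h @ self.Ur + self.br).sigmoid()
            n = (xt @ self.Wn + (r * h) @ self.Un + self.bn).tanh()
            h = (1.0 - z) * n + z * h
            outs.append(h.reshape(1, -1))
        return concat(outs, axis=0)


class SelfAttentionBlock(ParamModule):
    """Pre-norm transformer block: multi-head self-attention + 2-layer FFN."""

    def __init__(self, rng: np.random.Generator, d: int, n_heads: int,
                 d_ff: int):
        if d % n_heads:
            raise ValueError("model width must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.q = Linear(rng, d, d)
        self.k = Linear(rng, d, d)
        self.v = Linear(rng, d, d)
        self.o = Linear(rng, d, d)
        self.ff1 = Linear(rng, d, d_ff)
        self.ff2 = Linear(rng, d_ff, d)

    def __call__(self, x: Tensor) -> Tensor:
        L, d = x.shape
        h, dh = self.n_heads, self.d_head
        xn = self.ln1(x)
        # [L, d] -> [h, L, dh]
        q = self.q(xn).reshape(L, h, dh).transpose(1, 0, 2)
        k = self.k(xn).reshape(L, h, dh).transpose(1, 0, 2)
        v = self.v(xn).reshape(L, h, dh).transpose(1, 0, 2)
        att = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
        att = att.softmax(axis=-1)
        ctx = (att @ v).transpose(1, 0, 2).reshape(L, d)
        x = x + self.o(ctx)
        xn = self.ln2(x)
        return x + self.ff2(self.ff1(xn).relu())


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode needs an rng")
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            p.data = p.data - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)
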
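"""Transformer building blocks on top of the autograd engine."""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .autograd import Tensor, add_const, embedding

NEG_INF = -1e9  # additive mask value; large enough that exp underflows to 0.0


class Module:
    """Tiny module base: named parameters, state dict, train/eval is a no-op
    (no dropout anywhere — determinism is part of the contract)."""

    def parameters(self) -> Iterator[Tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield name, value
            elif isinstance(value, Module):
                for sub, p in value.parameters():
                    yield f"{name}.{sub}", p
            elif isinstance(value, list):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters():
                            yield f"{name}.{i}.{sub}", p

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.grad = None

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()


def _init(rng: np.random.Generator, *shape: int, scale: Optional[float] = None) -> Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape).astype(np.float32), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True,
                 scale: Optional[float] = None):
        self.weight = _init(rng, d_in, d_out, scale=scale)
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, d: int):
        self.weight = Tensor(np.ones(d, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(d, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.weight, self.bias)


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0, 0.02, size=(n, d)).astype(np.float32), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding(self.weight, idx)


class MultiHeadAttention(Module):
    """Standard scaled dot-product attention.

    ``mask`` is an additive array broadcastable to (B, H, Tq, Tk); masked
    entries use ``NEG_INF`` whose softmax weight underflows to exactly 0, so
    masked positions cannot leak into the output even at the bit level.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 d_kv: Optional[int] = None):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        d_kv = d_kv if d_kv is not None else d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_kv, d_model, rng)
        self.v = Linear(d_kv, d_model, rng)
        self.o = Linear(d_model, d_model, rng)

    def __call__(self, x_q: Tensor, x_kv: Tensor, mask: Optional[np.ndarray] = None) -> Tensor:
        B, Tq, _ = x_q.shape
        Tk = x_kv.shape[1]
        H, Dh = self.n_heads, self.d_head

        def split(t: Tensor, T: int) -> Tensor:
            return t.reshape(B, T, H, Dh).swapaxes(1, 2)  # (B,H,T,Dh)

        q = split(self.q(x_q), Tq)
        k = split(self.k(x_kv), Tk)
        v = split(self.v(x_kv), Tk)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(Dh))
        if mask is not None:
            scores = add_const(scores, mask)
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (B,H,Tq,Dh)
        out = out.swapaxes(1, 2).reshape(B, Tq, H * Dh)
        return self.o(out)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class BridgeLayer(Module):
    """One bridge block: shared self-attention, optional cross-attention to
    the frozen protein features (query stream only), then a feed-forward."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, d_protein: int,
                 has_cross: bool, rng: np.random.Generator):
        self.ln_self = LayerNorm(d_model)
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.has_cross = has_cross
        if has_cross:
            self.ln_cross = LayerNorm(d_model)
            self.cross_attn = MultiHeadAttention(d_model, n_heads, rng, d_kv=d_protein)
        self.ln_ff = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)

    def attend_self(self, x: Tensor, mask: Optional[np.ndarray] = None,
                    kv: Optional[Tensor] = None) -> Tensor:
        h = self.ln_self(x)
        h_kv = h if kv is None else kv
        return x + self.self_attn(h, h_kv, mask)

    def attend_cross(self, x: Tensor, protein: Tensor, mask: Optional[np.ndarray]) -> Tensor:
        if not self.has_cross:
            return x
        return x + self.cross_attn(self.ln_cross(x), protein, mask)

    def feed_forward(self, x: Tensor) -> Tensor:
        return x + self.ff(self.ln_ff(x))


class AdamW(Module):
    """Decoupled weight-decay Adam."""

    def __init__(self, params: List[Tuple[str, Tensor]], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in params}
        self.v = {n: np.zeros_like(p.data) for n, p in params}

    def step(self) -> None:
        self.t += 1
        for name, p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            m = self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            v = self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.grad = None


def causal_mask(T: int) -> np.ndarray:
    """(T, T) additive mask forbidding attention to future positions."""
    m = np.zeros((T, T), dtype=np.float32)
    m[np.triu_indices(T, k=1)] = NEG_INF
    return m


def padding_mask(pad: np.ndarray) -> np.ndarray:
    """(B, Tk) boolean padding flags -> (B, 1, 1, Tk) additive mask."""
    return np.where(pad[:, None, None, :], np.float32(NEG_INF), np.float32(0.0))
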
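"""Minimal NumPy neural-network engine used by the sequence models.

Implements exactly the pieces the splicing models need — dense layers,
embeddings, layer norm, multi-head self-attention, pre-LN transformer
blocks, Adam with linear warm-up — with hand-written backward passes.
All computation is float32 and deterministic given the seeding
``numpy.random.Generator``.

Layers cache their most recent forward activations, so a layer instance
participates in one forward/backward pair at a time (the training loops
here are strictly sequential).
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import numpy as np

F32 = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def _rand_init(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    return (rng.standard_normal(shape) * scale).astype(F32)


# ---------------------------------------------------------------------------
# elementary layers
# ---------------------------------------------------------------------------


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Param(_rand_init(rng, (d_in, d_out), (2.0 / (d_in + d_out)) ** 0.5))
        self.b = Param(np.zeros(d_out)) if bias else None
        self._x: np.ndarray | None = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])


class Embedding:
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.W = Param(_rand_init(rng, (n, dim), 0.02))
        self._ids: np.ndarray | None = None

    def __call__(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.W.value[ids]

    def backward(self, d: np.ndarray) -> None:
        np.add.at(self.W.grad, self._ids.reshape(-1), d.reshape(-1, d.shape[-1]))

    def params(self) -> list[Param]:
        return [self.W]


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Param(np.ones(dim))
        self.b = Param(np.zeros(dim))
        self.eps = eps
        self._cache = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xn = xc * inv
        self._cache = (xn, inv)
        return xn * self.g.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xn, inv = self._cache
        d = dy.reshape(-1, dy.shape[-1])
        xn2 = xn.reshape(-1, xn.shape[-1])
        self.g.grad += (d * xn2).sum(axis=0)
        self.b.grad += d.sum(axis=0)
        dxn = dy * self.g.value
        m = dxn.mean(axis=-1, keepdims=True)
        mx = (dxn * xn).mean(axis=-1, keepdims=True)
        return (dxn - m - xn * mx) * inv

    def params(self) -> list[Param]:
        return [self.g, self.b]


def gelu(x: np.ndarray) -> np.ndarray:
    c = np.float32(0.7978845608028654)  # sqrt(2/pi)
    return 0.5 * x * (1.0 + np.tanh(c * (x + 0.044715 * x * x * x)))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    c = np.float32(0.7978845608028654)
    t = np.tanh(c * (x + 0.044715 * x * x * x))
    dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x * x)
    return 0.5 * (1.0 + t) + 0.5 * x * dt


class FeedForward:
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Dense(dim, hidden, rng)
        self.fc2 = Dense(hidden, dim, rng)
        self._h: np.ndarray | None = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        h = self.fc1(x)
        self._h = h
        return self.fc2(gelu(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dg = self.fc2.backward(dy)
        return self.fc1.backward(dg * gelu_grad(self._h))

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()


class MultiHeadSelfAttention:
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"heads ({heads}) must divide width ({dim})")
        self.dim, self.heads, self.dh = dim, heads, dim // heads
        self.qkv = Dense(dim, 3 * dim, rng)
        self.out = Dense(dim, dim, rng)
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.heads, self.dh).transpose(0, 2, 1, 3)

    def __call__(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        B, T, _ = x.shape
        qkv = self.qkv(x)
        q, k, v = (self._split(a) for a in np.split(qkv, 3, axis=-1))
        s = q @ k.transpose(0, 1, 3, 2) / np.float32(self.dh**0.5)
        if mask is not None:
            s = s + np.where(mask, 0.0, -1e9).astype(F32)[:, None, None, :]
        s -= s.max(axis=-1, keepdims=True)
        a = np.exp(s)
        a /= a.sum(axis=-1, keepdims=True)
        ctx = a @ v  # (B,H,T,dh)
        self._cache = (q, k, v, a)
        merged = ctx.transpose(0, 2, 1, 3).reshape(B, T, self.dim)
        return self.out(merged)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, a = self._cache
        B, H, T, dh = q.shape
        dmerged = self.out.backward(dy)
        dctx = dmerged.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        da = dctx @ v.transpose(0, 1, 3, 2)
        dv = a.transpose(0, 1, 3, 2) @ dctx
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        ds /= np.float32(dh**0.5)
        dq = ds @ k
        dk = ds.transpose(0, 1, 3, 2) @ q
        merge = lambda x: x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)
        dqkv = np.concatenate([merge(dq), merge(dk), merge(dv)], axis=-1)
        return self.qkv.backward(dqkv)

    def params(self) -> list[Param]:
        return self.qkv.params() + self.out.params()


class Block:
    """Pre-LN transformer block: x + attn(ln(x)), then x + ffn(ln(x))."""

    def __init__(self, dim: int, heads: int, ffn_mult: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_mult * dim, rng)

    def __call__(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        x = x + self.attn(self.ln1(x), mask)
        return x + self.ffn(self.ln2(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy + self.ln2.backward(self.ffn.backward(dy))
        return dy + self.ln1.backward(self.attn.backward(dy))

    def params(self) -> list[Param]:
        return self.ln1.params() + self.attn.params() + self.ln2.params() + self.ffn.params()


class TransformerEncoder:
    """Token + learned-position embeddings, optional per-token scalar
    channel (e.g. conservation), a stack of pre-LN blocks, final norm."""

    def __init__(
        self,
        vocab: int,
        dim: int,
        heads: int,
        layers: int,
        max_len: int,
        rng: np.random.Generator,
        ffn_mult: int = 4,
        channel: bool = False,
    ):
        self.tok = Embedding(vocab, dim, rng)
        self.pos = Param(_rand_init(rng, (max_len, dim), 0.02))
        self.chan = Param(_rand_init(rng, (dim,), 0.02)) if channel else None
        self.blocks = [Block(dim, heads, ffn_mult, rng) for _ in range(layers)]
        self.ln_f = LayerNorm(dim)
        self.dim, self.max_len = dim, max_len
        self._cache = None

    def embed(self, ids: np.ndarray) -> np.ndarray:
        T = ids.shape[1]
        if T > self.max_len:
            raise ValueError(f"sequence of {T} tokens exceeds max length {self.max_len}")
        return self.tok(ids) + self.pos.value[:T]

    def forward_hidden(
        self,
        emb: np.ndarray,
        cons: np.ndarray | None = None,
        mask: np.ndarray | None = None,
    ) -> np.ndarray:
        if cons is not None:
            if self.chan is None:
                raise ValueError("encoder built without a scalar channel")
            emb = emb + cons[..., None].astype(F32) * self.chan.value
        self._cache = (cons, mask, emb.shape[1])
        x = emb
        for b in self.blocks:
            x = b(x, mask)
        return self.ln_f(x)

    def __call__(
        self,
        ids: np.ndarray,
        cons: np.ndarray | None = None,
        mask: np.ndarray | None = None,
    ) -> np.ndarray:
        return self.forward_hidden(self.embed(ids), cons, mask)

    def backward_hidden(self, dy: np.ndarray) -> np.ndarray:
        """Backprop to the (pre-channel) embedding; returns d_emb."""
        cons, _, _ = self._cache
        dx = self.ln_f.backward(dy)
        for b in reversed(self.blocks):
            dx = b.backward(dx)
        if cons is not None and self.chan is not None:
            self.chan.grad += (dx * cons[..., None]).sum(axis=(0, 1))
        return dx

    def backward(self, dy: np.ndarray, skip_token_grad: np.ndarray | None = None) -> None:
        """Full backward: routes d_emb into token/position tables.

        skip_token_grad: optional boolean (T,) marking positions whose token
        embedding was overwritten by the caller (gradient skipped there).
        """
        d_emb = self.backward_hidden(dy)
        T = d_emb.shape[1]
        self.pos.grad[:T] += d_emb.sum(axis=0)
        if skip_token_grad is not None:
            d_emb = d_emb * (~skip_token_grad)[None, :, None]
        self.tok.backward(d_emb)

    def params(self) -> list[Param]:
        ps = self.tok.params() + [self.pos]
        if self.chan is not None:
            ps.append(self.chan)
        for b in self.blocks:
            ps += b.params()
        return ps + self.ln_f.params()


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean CE over rows; returns (loss, dlogits)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=-1, keepdims=True)
    n = logits.shape[0]
    ll = -np.log(np.maximum(p[np.arange(n), targets], 1e-12))
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return float(ll.mean()), (dlogits / n).astype(F32)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def soft_bce(logits: np.ndarray, targets: np.ndarray):
    """Binary cross-entropy against soft targets in [0,1].

    Returns (mean loss, dlogits); the gradient is simply sigmoid(x) - t.
    """
    p = sigmoid(logits)
    eps = 1e-7
    loss = -(targets * np.log(p + eps) + (1.0 - targets) * np.log(1.0 - p + eps))
    n = logits.size
    return float(loss.mean()), ((p - targets) / n).astype(F32)


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            np.clip(p.grad, -10.0, 10.0, out=p.grad)
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.value -= (lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(F32)


def linear_warmup_lr(step: int, total_steps: int, warmup: int, base_lr: float) -> float:
    """Linear warm-up to base_lr, then linear decay to zero."""
    if warmup > 0 and step < warmup:
        return base_lr * (step + 1) / warmup
    if total_steps <= warmup:
        return base_lr
    frac = (step - warmup) / max(1, total_steps - warmup)
    return base_lr * max(0.0, 1.0 - frac)


# ---------------------------------------------------------------------------
# checkpointing: config JSON + flat weight archive
# ---------------------------------------------------------------------------


def save_checkpoint(directory: str, config: dict, params: Sequence[Param]) -> None:
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump(config, fh, indent=1, sort_keys=True)
    np.savez(os.path.join(directory, "weights.npz"),
             **{f"p{i}": p.value for i, p in enumerate(params)})


def load_weights(directory: str, params: Sequence[Param]) -> None:
    with np.load(os.path.join(directory, "weights.npz")) as z:
        if len(z.files) != len(params):
            raise ValueError(
                f"checkpoint holds {len(z.files)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = z[f"p{i}"]
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {i}: "
                                 f"{arr.shape} vs {p.value.shape}")
            p.value = arr.astype(F32)


def load_config(directory: str) -> dict:
    with open(os.path.join(directory, "config.json")) as fh:
        return json.load(fh)
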
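"""Transformer VAE over fixed-length nucleotide sequences.

Provides the continuous latent space used by the design optimizer: an
encoder maps a sequence to a Gaussian over R^d, the decoder maps a
latent vector back to per-position base probabilities. Decoding is
non-autoregressive (per-position argmax), so decoded sequences always
have the task's fixed length and a well-defined edit distance to the
start sequence; the tokens are single nucleotides, which guarantees any
decode is a valid sequence.

Two latent layouts are supported. The global layout pools the whole
sequence into one code. The block-factorized layout splits the sequence
into contiguous blocks, each with its own sub-code; because a block's
decode depends mainly on its own sub-code, moving a few latent
dimensions edits a localized stretch of sequence. That locality is what
makes edit-budgeted latent-space optimization effective: candidate moves
translate into small Levenshtein distances instead of resampling the
entire sequence.

Training maximises the ELBO (per-position cross-entropy plus
beta-weighted KL), with beta annealed linearly from zero over the first
tenth of training so the reconstruction term shapes the space first. A
linear z -> logits shortcut head accelerates memorisation of the
training corpus while the transformer decoder refines context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .tokenizer import BASES

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class VaeConfig:
    encoder_layers: int = 6
    decoder_layers: int = 6
    hidden: int = 256
    heads: int = 8
    latent_dim: int = 256
    beta: float = 1e-3
    max_len: int = 128
    ffn_mult: int = 4
    steps: int = 20_000
    batch_size: int = 32
    lr: float = 1e-3
    direct_head: bool = True  # linear z -> per-position logits shortcut
    block_size: int | None = None  # contiguous nt per latent block (None = global)
    block_latent: int = 4  # latent dims per block
    # fraction of training examples built by recombining blocks of two
    # corpus sequences; makes block contents independent in the training
    # distribution so codes stay local and transplantable
    block_shuffle_p: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.block_size is not None:
            if self.max_len % self.block_size:
                raise ValueError("block_size must divide max_len")
            self.latent_dim = (self.max_len // self.block_size) * self.block_latent
        if self.latent_dim < 1 or self.beta < 0:
            raise ValueError("latent_dim must be >= 1 and beta >= 0")

    @property
    def n_blocks(self) -> int:
        return 0 if self.block_size is None else self.max_len // self.block_size

    @classmethod
    def tiny(cls, **kw) -> "VaeConfig":
        base = dict(encoder_layers=1, decoder_layers=2, hidden=64, heads=4,
                    ffn_mult=2, steps=2500, batch_size=32, lr=5e-3, beta=1e-3,
                    max_len=100, block_size=10, block_latent=6)
        base.update(kw)
        return cls(**base)


def _encode_ids(seqs: list[str]) -> np.ndarray:
    return np.array([[_BASE_IDX[b] for b in s] for s in seqs], dtype=np.int64)


class SequenceVae:
    """Encoder Phi (sequence -> latent Gaussian) and decoder Gamma."""

    def __init__(self, config: VaeConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        c = config
        self.encoder = nn.TransformerEncoder(
            vocab=4, dim=c.hidden, heads=c.heads, layers=c.encoder_layers,
            max_len=c.max_len, rng=rng, ffn_mult=c.ffn_mult)
        if c.block_size:
            # block codes read the block's own one-hot content alongside the
            # contextual pooled hidden state, and decode through a shared
            # local head — a shared codebook, so equal content gets equal
            # codes in any block and code transplants move content
            z_in, enc_in = c.block_latent, c.hidden + 4 * c.block_size
            self.local_dec = nn.Dense(c.block_latent, 4 * c.block_size, rng)
        else:
            z_in, enc_in = c.latent_dim, c.hidden
            self.local_dec = None
        self.to_mu = nn.Dense(enc_in, z_in, rng)
        self.to_logvar = nn.Dense(enc_in, z_in, rng)
        # start with a small posterior scale (sigma ~ e^-2) so the
        # reparameterization noise does not drown the latent code early
        self.to_logvar.b.value[:] = -4.0
        self.from_z = nn.Dense(z_in, c.hidden, rng)
        self.dec_pos = nn.Param((rng.standard_normal((c.max_len, c.hidden)) * 0.02
                                 ).astype(np.float32))
        self.dec_blocks = [nn.Block(c.hidden, c.heads, c.ffn_mult, rng)
                           for _ in range(c.decoder_layers)]
        self.dec_ln = nn.LayerNorm(c.hidden)
        self.out = nn.Dense(c.hidden, 4, rng)
        self.direct = (nn.Dense(c.latent_dim, c.max_len * 4, rng, bias=False)
                       if (c.direct_head and not c.block_size) else None)

    def params(self) -> list[nn.Param]:
        ps = self.encoder.params() + self.to_mu.params() + self.to_logvar.params()
        ps += self.from_z.params() + [self.dec_pos]
        for b in self.dec_blocks:
            ps += b.params()
        ps += self.dec_ln.params() + self.out.params()
        if self.direct is not None:
            ps += self.direct.params()
        if self.local_dec is not None:
            ps += self.local_dec.params()
        return ps

    # -- encoder -----------------------------------------------------------
    def _pool(self, h: np.ndarray) -> np.ndarray:
        c = self.config
        if c.block_size:
            B, L, H = h.shape
            return h.reshape(B, c.n_blocks, c.block_size, H).mean(axis=2)
        return h.mean(axis=1)

    def _onehot_blocks(self, ids: np.ndarray) -> np.ndarray:
        c = self.config
        B, L = ids.shape
        oh = np.zeros((B, L, 4), dtype=np.float32)
        oh[np.arange(B)[:, None], np.arange(L)[None, :], ids] = 1.0
        return oh.reshape(B, c.n_blocks, 4 * c.block_size)

    def encode_ids(self, ids: np.ndarray):
        c = self.config
        if c.block_size and ids.shape[1] != c.max_len:
            raise ValueError("block-latent VAE requires full-length input")
        h = self.encoder(ids)
        pooled = self._pool(h)
        if c.block_size:
            pooled = np.concatenate([pooled, self._onehot_blocks(ids)], axis=-1)
        mu, lv = self.to_mu(pooled), self.to_logvar(pooled)
        if c.block_size:
            mu = mu.reshape(len(ids), -1)
            lv = lv.reshape(len(ids), -1)
        return mu, lv

    def encode_seq(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """Latent Gaussian (mean, scale) for one sequence."""
        if len(seq) > self.config.max_len:
            raise ValueError("sequence longer than the VAE maximum length")
        mu, lv = self.encode_ids(_encode_ids([seq]))
        return mu[0], np.exp(0.5 * lv[0])

    def encode_batch(self, seqs: list[str]) -> np.ndarray:
        mus = []
        for i in range(0, len(seqs), 64):
            mu, _ = self.encode_ids(_encode_ids(seqs[i:i + 64]))
            mus.append(mu)
        return np.concatenate(mus, axis=0)

    # -- decoder -----------------------------------------------------------
    def _decode_hidden(self, z: np.ndarray, length: int) -> np.ndarray:
        c = self.config
        if c.block_size:
            if length != c.max_len:
                raise ValueError("block-latent VAE decodes full-length only")
            zb = z.reshape(len(z), c.n_blocks, c.block_latent)
            hb = self.from_z(zb)  # (B, n_blocks, hidden)
            h0 = np.repeat(hb, c.block_size, axis=1)
        else:
            h0 = self.from_z(z)[:, None, :]
        x = h0 + self.dec_pos.value[:length][None, :, :]
        for b in self.dec_blocks:
            x = b(x)
        logits = self.out(self.dec_ln(x))  # (B, L, 4)
        if self.direct is not None:
            logits = logits + self.direct(z).reshape(len(z), -1, 4)[:, :length, :]
        if self.local_dec is not None:
            zb = z.reshape(len(z), c.n_blocks, c.block_latent)
            logits = logits + self.local_dec(zb).reshape(len(z), length, 4)
        return logits

    def decode_latent(self, z: np.ndarray, length: int) -> str:
        """Most probable sequence for a latent vector (greedy argmax)."""
        z = np.asarray(z, dtype=np.float32)
        if z.ndim == 1:
            z = z[None, :]
        if z.shape[1] != self.config.latent_dim:
            raise ValueError(f"latent dimension {z.shape[1]} != {self.config.latent_dim}")
        logits = self._decode_hidden(z, length)
        return "".join(BASES[i] for i in logits[0].argmax(axis=-1))

    def decode_batch(self, Z: np.ndarray, length: int) -> list[str]:
        logits = self._decode_hidden(np.asarray(Z, dtype=np.float32), length)
        return ["".join(BASES[i] for i in row.argmax(axis=-1)) for row in logits]

    def reconstruct(self, seq: str) -> str:
        mu, _ = self.encode_seq(seq)
        return self.decode_latent(mu, len(seq))

    # -- persistence ---------------------------------------------------------
    def save(self, directory: str) -> None:
        from dataclasses import asdict

        nn.save_checkpoint(directory, asdict(self.config), self.params())

    @classmethod
    def load(cls, directory: str) -> "SequenceVae":
        model = cls(VaeConfig(**nn.load_config(directory)))
        nn.load_weights(directory, model.params())
        return model


def train_vae(corpus: list[str], config: VaeConfig) -> tuple[SequenceVae, pd.DataFrame]:
    """Fit the VAE by ELBO descent; returns model + (step, recon, kl) log."""
    if not corpus:
        raise ValueError("empty corpus")
    lengths = {len(s) for s in corpus}
    if len(lengths) != 1:
        raise ValueError("corpus sequences must share one length")
    L = lengths.pop()
    if L > config.max_len:
        raise ValueError("corpus sequences exceed max_len")
    rng = np.random.default_rng(config.seed)
    model = SequenceVae(config, rng)
    ids = _encode_ids(corpus)
    n = len(corpus)
    c = config
    opt = nn.Adam(model.params(), lr=c.lr)
    anneal = max(1, c.steps // 10)
    warmup = max(1, c.steps // 20)
    log = []
    for step in range(c.steps):
        lr = nn.linear_warmup_lr(step, c.steps, warmup, c.lr)
        beta = c.beta * min(1.0, step / anneal)
        idx = rng.integers(0, n, size=min(c.batch_size, n))
        batch = ids[idx].copy()
        B = len(idx)
        if c.block_size and c.block_shuffle_p > 0:
            mix = rng.random(B) < c.block_shuffle_p
            if mix.any():
                partners = rng.integers(0, n, size=int(mix.sum()))
                take = rng.random((int(mix.sum()), c.n_blocks)) < 0.5
                bb = batch[mix].reshape(-1, c.n_blocks, c.block_size)
                pp = ids[partners].reshape(-1, c.n_blocks, c.block_size)
                bb[take] = pp[take]
                batch[mix] = bb.reshape(-1, L)
        # encoder forward
        h = model.encoder(batch)
        pooled = model._pool(h)
        if c.block_size:
            pooled = np.concatenate([pooled, model._onehot_blocks(batch)], axis=-1)
        mu2 = model.to_mu(pooled)
        lv2 = np.clip(model.to_logvar(pooled), -8.0, 8.0)
        mu = mu2.reshape(B, -1)
        lv = lv2.reshape(B, -1)
        eps = rng.standard_normal(mu.shape).astype(np.float32)
        z = mu + eps * np.exp(0.5 * lv)
        logits = model._decode_hidden(z, L)
        recon, dflat = nn.softmax_cross_entropy(
            logits.reshape(B * L, 4), batch.reshape(-1))
        kl = float(0.5 * (np.exp(lv) + mu * mu - 1.0 - lv).sum(axis=1).mean())
        opt.zero_grad()
        # decoder backward
        dlogits = dflat.reshape(B, L, 4)
        dz_direct = 0.0
        if model.direct is not None:
            dfull = np.zeros((B, c.max_len * 4), dtype=np.float32)
            dfull[:, :L * 4] = dlogits.reshape(B, -1)
            dz_direct = model.direct.backward(dfull)
        if model.local_dec is not None:
            dzb = model.local_dec.backward(
                dlogits.reshape(B, c.n_blocks, 4 * c.block_size))
            dz_direct = dz_direct + dzb.reshape(B, -1)
        dx = model.out.backward(dlogits)
        dx = model.dec_ln.backward(dx)
        for blk in reversed(model.dec_blocks):
            dx = blk.backward(dx)
        model.dec_pos.grad[:L] += dx.sum(axis=0)
        if c.block_size:
            dhb = dx.reshape(B, c.n_blocks, c.block_size, -1).sum(axis=2)
            dz = model.from_z.backward(dhb).reshape(B, -1)
        else:
            dz = model.from_z.backward(dx.sum(axis=1))
        dz = dz + dz_direct
        # KL gradients (mean over batch)
        dmu = dz + beta * mu / B
        dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + beta * 0.5 * (np.exp(lv) - 1.0) / B
        if c.block_size:
            dmu = dmu.reshape(B, c.n_blocks, c.block_latent)
            dlv = dlv.reshape(B, c.n_blocks, c.block_latent)
        dpooled = model.to_mu.backward(dmu.astype(np.float32))
        dpooled = dpooled + model.to_logvar.backward(dlv.astype(np.float32))
        if c.block_size:
            dpooled = dpooled[..., :c.hidden]  # one-hot part carries no gradient
            dh = np.repeat(dpooled / c.block_size, c.block_size, axis=1)
        else:
            dh = np.repeat(dpooled[:, None, :] / h.shape[1], h.shape[1], axis=1)
        model.encoder.backward(dh.astype(np.float32))
        opt.step(lr)
        if step % 100 == 0 or step == c.steps - 1:
            log.append((step, recon, kl, beta))
    return model, pd.DataFrame(log, columns=["step", "recon", "kl", "beta"])


def reconstruction_rate(model: SequenceVae, seqs: list[str]) -> float:
    """Fraction of sequences reproduced exactly via Gamma(mean(Phi(s)))."""
    if not seqs:
        raise ValueError("no sequences")
    Z = model.encode_batch(seqs)
    ok = 0
    for i in range(0, len(seqs), 64):
        dec = model.decode_batch(Z[i:i + 64], len(seqs[0]))
        ok += sum(d == s for d, s in zip(dec, seqs[i:i + 64]))
    return ok / len(seqs)
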
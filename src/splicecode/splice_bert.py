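"""Masked-LM pre-training of the splice-site window encoder.

A BERT-style transformer is trained on fixed-length windows centred on
splice sites (3' and 5' sites mixed in one corpus; the centring
convention itself carries the site-type signal). Corruption uses the
span-masking scheme from :mod:`splicecode.tokenizer`: 15% seed tokens
plus three masked neighbours on each side, loss at the seeds only.

The published training profile (6 layers, 12 heads, 110k steps, batch
40, lr 4e-4 with 10k warm-up steps) is the default configuration; the
``tiny`` profile exists so the whole pipeline trains in seconds on one
CPU.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import nn
from .tokenizer import TokenSequence, Vocabulary, apply_mlm_mask, tokenize


@dataclass
class EncoderConfig:
    layers: int = 6
    heads: int = 12
    hidden: int = 768
    max_tokens: int = 512
    ffn_mult: int = 4
    k: int = 6

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ValueError("heads must divide hidden width")

    @classmethod
    def tiny(cls, **kw) -> "EncoderConfig":
        base = dict(layers=2, heads=4, hidden=64, max_tokens=128, ffn_mult=2)
        base.update(kw)
        return cls(**base)


@dataclass
class PretrainConfig:
    steps: int = 110_000
    batch_size: int = 40
    lr: float = 4e-4
    warmup: int = 10_000
    seed: int = 0
    mask_rate: float = 0.15
    mask_span: int = 3
    log_every: int = 50

    def __post_init__(self):
        if self.warmup > self.steps and self.steps > 0:
            raise ValueError("warm-up must not exceed total steps")
        if min(self.batch_size, self.lr) <= 0 or self.steps < 0:
            raise ValueError("steps, batch size and learning rate must be positive")


class SpliceBert:
    """Transformer encoder over k-mer tokens with an MLM head."""

    def __init__(self, config: EncoderConfig, vocab: Vocabulary,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.vocab = vocab
        self.encoder = nn.TransformerEncoder(
            vocab=len(vocab), dim=config.hidden, heads=config.heads,
            layers=config.layers, max_len=config.max_tokens, rng=rng,
            ffn_mult=config.ffn_mult, channel=True)
        self.mlm_head = nn.Dense(config.hidden, len(vocab), rng)

    # -- inference ---------------------------------------------------------
    def params(self) -> list[nn.Param]:
        return self.encoder.params() + self.mlm_head.params()

    def _ids_with_cls(self, tokens: np.ndarray) -> np.ndarray:
        return np.concatenate([[self.vocab.cls_id], tokens])

    def encode(self, seq_or_tokens, mask: np.ndarray | None = None):
        """Per-token embeddings and the CLS vector (eval mode; deterministic)."""
        if isinstance(seq_or_tokens, str):
            tokens = tokenize(seq_or_tokens, self.vocab).tokens
        elif isinstance(seq_or_tokens, TokenSequence):
            tokens = seq_or_tokens.tokens
        else:
            tokens = np.asarray(seq_or_tokens)
        ids = self._ids_with_cls(tokens)[None, :]
        if ids.shape[1] > self.config.max_tokens:
            raise ValueError(
                f"{ids.shape[1]} tokens exceed the encoder maximum {self.config.max_tokens}")
        h = self.encoder(ids, mask=mask)
        return h[0], h[0, 0]

    def mlm_logits(self, ids: np.ndarray) -> np.ndarray:
        return self.mlm_head(self.encoder(ids))

    # -- persistence -------------------------------------------------------
    def save(self, directory: str) -> None:
        cfg = {"encoder": asdict(self.config),
               "vocab": {"k": self.vocab.k,
                         "n_length_bins": self.vocab.n_length_bins,
                         "conditions": list(self.vocab.conditions)}}
        nn.save_checkpoint(directory, cfg, self.params())

    @classmethod
    def load(cls, directory: str) -> "SpliceBert":
        cfg = nn.load_config(directory)
        vocab = Vocabulary(**cfg["vocab"])
        model = cls(EncoderConfig(**cfg["encoder"]), vocab)
        nn.load_weights(directory, model.params())
        return model


def pretrain(
    corpus: list[str],
    enc_config: EncoderConfig,
    pre_config: PretrainConfig,
    vocab: Vocabulary | None = None,
) -> tuple[SpliceBert, pd.DataFrame]:
    """Masked-LM pre-training; returns the model and a (step, loss, lr) log.

    All corpus windows must have equal length. With steps=0 the model is
    returned at initialisation with an empty log.
    """
    if not corpus:
        raise ValueError("pre-training corpus is empty")
    lengths = {len(s) for s in corpus}
    if len(lengths) != 1:
        raise ValueError(f"corpus windows differ in length: {sorted(lengths)[:5]}")
    vocab = vocab or Vocabulary(k=enc_config.k)
    rng = np.random.default_rng(pre_config.seed)
    model = SpliceBert(enc_config, vocab, rng)
    tokens = np.stack([tokenize(s, vocab).tokens for s in corpus])
    n, t = tokens.shape
    if t + 1 > enc_config.max_tokens:
        raise ValueError("windows tokenize past the encoder maximum length")
    opt = nn.Adam(model.params(), lr=pre_config.lr)
    log_rows = []
    for step in range(pre_config.steps):
        idx = rng.integers(0, n, size=pre_config.batch_size)
        batch = tokens[idx]
        corrupted = np.empty((pre_config.batch_size, t + 1), dtype=np.int64)
        loss_pos, loss_tok = [], []
        for b in range(pre_config.batch_size):
            corr, plan = apply_mlm_mask(
                batch[b], rng, rate=pre_config.mask_rate,
                span=pre_config.mask_span, vocab=vocab)
            corrupted[b] = np.concatenate([[vocab.cls_id], corr])
            for p in plan.loss_positions:
                loss_pos.append((b, p + 1))  # +1 for the CLS prefix
                loss_tok.append(batch[b, p])
        h = model.encoder(corrupted)
        if loss_pos:
            rows = np.array([p[0] for p in loss_pos])
            cols = np.array([p[1] for p in loss_pos])
            hsel = h[rows, cols]
            logits = model.mlm_head(hsel)
            loss, dlogits = nn.softmax_cross_entropy(logits, np.array(loss_tok))
            opt.zero_grad()
            dh_sel = model.mlm_head.backward(dlogits)
            dh = np.zeros_like(h)
            np.add.at(dh, (rows, cols), dh_sel)
            model.encoder.backward(dh)
            lr = nn.linear_warmup_lr(step, pre_config.steps, pre_config.warmup,
                                     pre_config.lr)
            opt.step(lr)
        else:
            loss, lr = float("nan"), 0.0
        if step % pre_config.log_every == 0 or step == pre_config.steps - 1:
            log_rows.append((step, loss, lr))
    return model, pd.DataFrame(log_rows, columns=["step", "loss", "lr"])


def masked_token_accuracy(
    model: SpliceBert,
    corpus: list[str],
    offset: int,
    span: int = 3,
    rng: np.random.Generator | None = None,
) -> float:
    """Accuracy of recovering the token at ``offset`` when its span
    neighbourhood is masked — used to probe what pre-training learned."""
    rng = rng or np.random.default_rng(0)
    vocab = model.vocab
    correct = 0
    for s in corpus:
        tokens = tokenize(s, vocab).tokens
        corrupted = tokens.copy()
        lo, hi = max(0, offset - span), min(len(tokens), offset + span + 1)
        corrupted[lo:hi] = vocab.mask_id
        ids = np.concatenate([[vocab.cls_id], corrupted])[None, :]
        logits = model.mlm_logits(ids)[0, offset + 1]
        if int(np.argmax(logits)) == int(tokens[offset]):
            correct += 1
    return correct / len(corpus)
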
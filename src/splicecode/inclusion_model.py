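"""Four-tower cassette-exon inclusion model.

One transformer tower per splice-site window (upstream-exon donor,
cassette acceptor, cassette donor, downstream-exon acceptor); the four
CLS vectors are concatenated with an event-feature block and fed into a
two-hidden-layer MLP ending in three sigmoid heads that predict the
supervision targets

    t_psi        = E[PSI_{e,c}]
    t_dpsi_plus  = |max(eps, E[dPSI_{e,c,c'}])|
    t_dpsi_minus = |min(eps, E[dPSI_{e,c,c'}])|

with eps drawn fresh per example per epoch from U(0.001, 0.002) so that
unchanging events still provide a small, non-zero gradient to the dPSI
heads. Training minimises soft binary cross-entropy (each target in
[0,1] treated as a Bernoulli mean), which outperformed squared error in
the original ablations.

Event features enter twice: as extra prefix tokens on every tower
(condition tokens and binned exon/intron lengths) and as a dense block
concatenated with the CLS vectors. Per-base conservation enters each
tower as a scalar channel added to the token embeddings, with exonic
positions replaced by the exon mean (exon conservation mostly reflects
coding constraint, so only its level is informative).

Conditions are represented either as learned tokens or, for
generalisation to unseen conditions, by the latent code of an RBP
expression autoencoder (RBP-AE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .data_model import EventWindows, SpliceEvent
from .splice_bert import EncoderConfig, SpliceBert
from .tokenizer import Vocabulary, tokenize

# ---------------------------------------------------------------------------
# supervision targets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SupervisionTarget:
    t_psi: float
    t_dpsi_plus: float
    t_dpsi_minus: float
    eps: float

    def as_array(self) -> np.ndarray:
        return np.array([self.t_psi, self.t_dpsi_plus, self.t_dpsi_minus], dtype=np.float32)


def target_transform(psi_c: float, psi_cprime: float,
                     rng: np.random.Generator) -> SupervisionTarget:
    """The three-part target for a condition pair (exact formulas)."""
    for p in (psi_c, psi_cprime):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"psi={p} outside [0,1]")
    eps = float(rng.uniform(0.001, 0.002))
    dpsi = psi_c - psi_cprime
    # the minus head clamps at -eps so an unchanged event still supplies a
    # small non-zero target to both direction heads
    return SupervisionTarget(
        t_psi=float(psi_c),
        t_dpsi_plus=abs(max(eps, dpsi)),
        t_dpsi_minus=abs(min(-eps, dpsi)),
        eps=eps,
    )


# ---------------------------------------------------------------------------
# event features
# ---------------------------------------------------------------------------

LENGTH_BIN_COUNT = 32
_LEN_LO, _LEN_HI = 10.0, 500_000.0


def length_bin(length: int) -> int:
    """Log-spaced bin index over [10, 500000] nt, clamped to edge bins."""
    x = np.log10(max(float(length), 1.0))
    lo, hi = np.log10(_LEN_LO), np.log10(_LEN_HI)
    b = int(np.floor((x - lo) / (hi - lo) * LENGTH_BIN_COUNT))
    return min(max(b, 0), LENGTH_BIN_COUNT - 1)


def event_lengths(event: SpliceEvent, half_window: int) -> tuple[int, int, int, int, int]:
    """(E1, I1, cassette, I2, E2) lengths; unknown flanking exon lengths
    fall back to the half window the model actually sees."""
    i1, i2 = event.intron_lens
    e1, e2 = event.flank_exon_lens or (half_window, half_window)
    return e1, i1, event.cassette_len, i2, e2


def _token_conservation(per_base: np.ndarray, k: int) -> np.ndarray:
    """Mean conservation of each k-mer token (length L-k+1)."""
    cs = np.concatenate([[0.0], np.cumsum(per_base)])
    return (cs[k:] - cs[:-k]) / k


def exon_filled_conservation(windows: EventWindows, event: SpliceEvent) -> list[np.ndarray]:
    """Per-base conservation per tower with exon positions set to the
    exon mean (towers are in transcript orientation)."""
    half = windows.width // 2
    e1, _, cas, _, e2 = event_lengths(event, half)
    spans = [  # (start, end) of the exonic part of each window
        (half - min(e1, half), half),
        (half, half + min(cas, half)),
        (half - min(cas, half), half),
        (half, half + min(e2, half)),
    ]
    out = []
    for cv, (a, b) in zip(windows.cons, spans):
        cv = cv.astype(np.float32).copy()
        if b > a:
            cv[a:b] = cv[a:b].mean()
        out.append(cv)
    return out


@dataclass
class EventFeatures:
    """Tokenised tower inputs plus the dense feature block for one
    (event, condition-pair) example."""

    tower_tokens: np.ndarray  # (4, T_kmer) k-mer ids
    tower_cons: np.ndarray  # (4, T_kmer) per-token conservation
    length_bins: np.ndarray  # (5,) bin indices: E1, I1, cassette, I2, E2
    raw_lengths: np.ndarray  # (5,) log10 lengths / 6 (dense block input)
    condition: str
    condition_prime: str


def featurize(event: SpliceEvent, windows: EventWindows, vocab: Vocabulary,
              condition: str, condition_prime: str,
              use_conservation: bool = True) -> EventFeatures:
    k = vocab.k
    toks = np.stack([tokenize(s, vocab).tokens for s in windows.seqs])
    if use_conservation:
        cons = np.stack([_token_conservation(cv, k)
                         for cv in exon_filled_conservation(windows, event)])
    else:
        cons = np.zeros_like(toks, dtype=np.float32)
    lens = event_lengths(event, windows.width // 2)
    return EventFeatures(
        tower_tokens=toks,
        tower_cons=cons.astype(np.float32),
        length_bins=np.array([length_bin(x) for x in lens]),
        raw_lengths=(np.log10(np.maximum(lens, 1.0)) / 6.0).astype(np.float32),
        condition=condition,
        condition_prime=condition_prime,
    )


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class InclusionConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    mlp_hidden: tuple[int, int] = (3080, 768)
    feat_dim: int = 8
    lr: float = 2e-5
    batch_size: int = 32
    epochs: int = 10
    share_towers: bool = False
    condition_mode: str = "token"  # "token" | "rbp_ae"
    rbp_latent_dim: int = 16
    use_conservation: bool = True
    lr_decay: bool = False  # linear per-epoch decay to 10% of lr
    # tower readout: "cls" | "cls_mean" | "cls_center" (CLS + mean-pool +
    # hidden states at the tokens tiling the splice-site region, which the
    # centring convention puts at fixed offsets)
    tower_pool: str = "cls"
    center_offsets: tuple = (-21, -15, -9, -3, 3)
    head_weights: tuple = (1.0, 1.0, 1.0)  # loss weights: t_psi, t_dpsi+, t_dpsi-
    seed: int = 0

    def __post_init__(self):
        if min(self.mlp_hidden) <= 0 or self.lr <= 0:
            raise ValueError("MLP widths and learning rate must be positive")

    @classmethod
    def tiny(cls, **kw) -> "InclusionConfig":
        base = dict(
            encoder=EncoderConfig.tiny(layers=1, heads=4, hidden=32,
                                       max_tokens=128, ffn_mult=2),
            mlp_hidden=(128, 64), lr=2e-3, batch_size=64, epochs=8, lr_decay=True,
            tower_pool="cls_center", head_weights=(3.0, 1.0, 1.0))
        base.update(kw)
        return cls(**base)


N_PREFIX = 8  # CLS + 2 condition tokens + 5 length-bin tokens


@dataclass
class TrainExample:
    event_id: str
    features: EventFeatures
    psi_c: float
    psi_cprime: float


class InclusionModel:
    """Four splice-site towers + feature block + MLP with three heads."""

    def __init__(self, config: InclusionConfig, vocab: Vocabulary,
                 rng: np.random.Generator | None = None,
                 pretrained: SpliceBert | None = None):
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.vocab = vocab
        ec = config.encoder
        n_towers = 1 if config.share_towers else 4
        self.towers = [
            nn.TransformerEncoder(len(vocab), ec.hidden, ec.heads, ec.layers,
                                  ec.max_tokens, rng, ffn_mult=ec.ffn_mult, channel=True)
            for _ in range(n_towers)]
        if pretrained is not None:
            for t in self.towers:
                self._copy_encoder(pretrained.encoder, t)
        h = ec.hidden
        if config.condition_mode == "rbp_ae":
            self.cond_proj = nn.Param(
                (rng.standard_normal((config.rbp_latent_dim, h)) * 0.05).astype(np.float32))
            feat_in = 5 + 2 * config.rbp_latent_dim
        else:
            self.cond_proj = None
            feat_in = 5 + 2 * len(vocab.conditions)
        self.feat_dense = nn.Dense(feat_in, config.feat_dim, rng)
        m1, m2 = config.mlp_hidden
        if config.tower_pool == "cls":
            self._tower_dim = h
        elif config.tower_pool == "cls_mean":
            self._tower_dim = 2 * h
        elif config.tower_pool == "cls_center":
            self._tower_dim = (2 + len(config.center_offsets)) * h
        else:
            raise ValueError(f"unknown tower_pool {config.tower_pool!r}")
        self.mlp1 = nn.Dense(4 * self._tower_dim + config.feat_dim, m1, rng)
        self.mlp2 = nn.Dense(m1, m2, rng)
        self.head = nn.Dense(m2, 3, rng)
        self._cache = None
        # condition -> RBP-AE latent, populated via set_condition_embedder
        self._cond_latents: dict[str, np.ndarray] = {}
        self._rbp_ae = None

    @staticmethod
    def _copy_encoder(src: nn.TransformerEncoder, dst: nn.TransformerEncoder) -> None:
        sp, dp = src.params(), dst.params()
        if len(sp) != len(dp):
            raise ValueError("pre-trained encoder architecture does not match towers")
        for s, d in zip(sp, dp):
            if s.value.shape == d.value.shape:
                d.value = s.value.copy()
            elif s.value.ndim == 2 and s.value.shape[1] == d.value.shape[1]:
                r = min(s.value.shape[0], d.value.shape[0])  # vocab/posn overlap
                d.value[:r] = s.value[:r]
            else:
                raise ValueError(f"incompatible parameter shapes {s.value.shape} "
                                 f"vs {d.value.shape}")

    # -- condition embedding ------------------------------------------------
    def set_condition_embedder(self, rbp_ae, expression: pd.DataFrame) -> None:
        """Attach an RBP-AE and the expression matrix (conditions x RBPs)."""
        self._rbp_ae = rbp_ae
        self._cond_latents = {
            c: rbp_ae.embed(expression.loc[c]).astype(np.float32)
            for c in expression.index}

    def add_condition(self, name: str, expression_vector) -> None:
        if self._rbp_ae is None:
            raise ValueError("no RBP-AE attached; unknown condition needs an "
                             "expression vector and an embedder")
        self._cond_latents[name] = self._rbp_ae.embed(expression_vector).astype(np.float32)

    def _cond_latent(self, name: str) -> np.ndarray:
        if name not in self._cond_latents:
            raise KeyError(f"condition {name!r} unknown to the RBP-AE embedder")
        return self._cond_latents[name]

    # -- batching -----------------------------------------------------------
    def _assemble(self, feats: list[EventFeatures]):
        B = len(feats)
        t_kmer = feats[0].tower_tokens.shape[1]
        T = N_PREFIX + t_kmer
        ids = np.zeros((B, 4, T), dtype=np.int64)
        cons = np.zeros((B, 4, T), dtype=np.float32)
        v = self.vocab
        token_mode = self.config.condition_mode == "token"
        lat = np.zeros((B, 2, self.config.rbp_latent_dim), dtype=np.float32) \
            if not token_mode else None
        raw = np.zeros((B, self.feat_dense.W.value.shape[0]), dtype=np.float32)
        for b, f in enumerate(feats):
            if token_mode:
                c_id, cp_id = v.condition_id(f.condition), v.condition_id(f.condition_prime)
            else:
                c_id = cp_id = v.pad_id
                lat[b, 0] = self._cond_latent(f.condition)
                lat[b, 1] = self._cond_latent(f.condition_prime)
            prefix = [v.cls_id, c_id, cp_id] + [v.length_bin_id(i) for i in f.length_bins]
            for i in range(4):
                ids[b, i, :N_PREFIX] = prefix
                ids[b, i, N_PREFIX:] = f.tower_tokens[i]
                cons[b, i, N_PREFIX:] = f.tower_cons[i]
            raw[b, :5] = f.raw_lengths
            if token_mode:
                nc = len(v.conditions)
                raw[b, 5 + v.conditions.index(f.condition)] = 1.0
                raw[b, 5 + nc + v.conditions.index(f.condition_prime)] = 1.0
            else:
                d = self.config.rbp_latent_dim
                raw[b, 5:5 + d] = lat[b, 0]
                raw[b, 5 + d:5 + 2 * d] = lat[b, 1]
        return ids, cons, lat, raw

    # -- forward / backward --------------------------------------------------
    def forward(self, feats: list[EventFeatures]) -> np.ndarray:
        """Predicted (t_psi, t_dpsi_plus, t_dpsi_minus) in [0,1], (B,3)."""
        ids, cons, lat, raw = self._assemble(feats)
        B = ids.shape[0]
        pool = self.config.tower_pool

        def readout(h):
            if pool == "cls":
                return h[:, 0]
            parts = [h[:, 0], h.mean(axis=1)]
            if pool == "cls_center":
                for idx in self._center_token_indices(h.shape[1]):
                    parts.append(h[:, idx])
            return np.concatenate(parts, axis=1)

        cls = []
        if self.config.share_towers:
            flat_ids = ids.transpose(1, 0, 2).reshape(4 * B, -1)
            flat_cons = cons.transpose(1, 0, 2).reshape(4 * B, -1)
            emb = self.towers[0].embed(flat_ids)
            emb = self._inject_conditions(emb, lat, B, shared=True)
            h = self.towers[0].forward_hidden(emb, cons=flat_cons)
            ro = readout(h)
            cls = list(ro.reshape(4, B, -1))
        else:
            for i, enc in enumerate(self.towers):
                emb = enc.embed(ids[:, i])
                emb = self._inject_conditions(emb, lat, B, shared=False)
                h = enc.forward_hidden(emb, cons=cons[:, i])
                cls.append(readout(h))
        fv = self.feat_dense(raw)
        x = np.concatenate(cls + [fv], axis=1)
        a1 = self.mlp1(x)
        h1 = nn.gelu(a1)
        a2 = self.mlp2(h1)
        h2 = nn.gelu(a2)
        logits = self.head(h2)
        self._cache = (lat, B, a1, a2)
        self.last_logits = logits
        return nn.sigmoid(logits)

    def _center_token_indices(self, T: int) -> list[int]:
        """Token indices tiling the splice-site region around the centre.

        A window of W bases yields W-k+1 k-mer tokens after the prefix;
        the junction is at base W/2, so the token starting at base
        W/2 + off sits at a fixed, length-independent position."""
        t_kmer = T - N_PREFIX
        half = (t_kmer + self.vocab.k - 1) // 2
        out = []
        for off in self.config.center_offsets:
            idx = half + off
            out.append(N_PREFIX + min(max(idx, 0), t_kmer - 1))
        return out

    def _inject_conditions(self, emb, lat, B, shared: bool):
        if lat is None:
            return emb
        proj = lat @ self.cond_proj.value  # (B,2,H)
        if shared:
            tiled = np.repeat(proj[None, :, :, :], 4, axis=0).reshape(4 * B, 2, -1)
            emb[:, 1:3, :] = tiled
        else:
            emb[:, 1:3, :] = proj
        return emb

    def backward(self, dlogits: np.ndarray) -> None:
        lat, B, a1, a2 = self._cache
        d2 = self.head.backward(dlogits) * nn.gelu_grad(a2)
        d1 = self.mlp2.backward(d2) * nn.gelu_grad(a1)
        dx = self.mlp1.backward(d1)
        h = self.config.encoder.hidden
        td = self._tower_dim
        dro = [dx[:, i * td:(i + 1) * td] for i in range(4)]
        self.feat_dense.backward(dx[:, 4 * td:])
        pool = self.config.tower_pool

        def fill(dh, d):
            T = dh.shape[1]
            dh[:, 0] += d[:, :h]
            if pool in ("cls_mean", "cls_center"):
                dh += d[:, None, h:2 * h] / T
            if pool == "cls_center":
                for j, idx in enumerate(self._center_token_indices(T)):
                    dh[:, idx] += d[:, (2 + j) * h:(3 + j) * h]

        if self.config.share_towers:
            enc = self.towers[0]
            T = enc._cache[2]
            dh = np.zeros((4 * B, T, h), dtype=np.float32)
            for i in range(4):
                fill(dh[i * B:(i + 1) * B], dro[i])
            self._tower_backward(enc, dh, lat, B, shared=True)
        else:
            for i in reversed(range(4)):
                enc = self.towers[i]
                T = enc._cache[2]
                dh = np.zeros((B, T, h), dtype=np.float32)
                fill(dh, dro[i])
                self._tower_backward(enc, dh, lat, B, shared=False)

    def _tower_backward(self, enc, dh, lat, B, shared: bool) -> None:
        demb = enc.backward_hidden(dh)
        T = demb.shape[1]
        enc.pos.grad[:T] += demb.sum(axis=0)
        skip = None
        if lat is not None:
            dproj = demb[:, 1:3, :]
            if shared:
                dproj = dproj.reshape(4, B, 2, -1).sum(axis=0)
            self.cond_proj.grad += np.einsum("bcd,bch->dh", lat, dproj)
            skip = np.zeros(T, dtype=bool)
            skip[1:3] = True
            demb = demb * (~skip)[None, :, None]
        enc.tok.backward(demb)

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for t in self.towers:
            ps += t.params()
        if self.cond_proj is not None:
            ps.append(self.cond_proj)
        return ps + self.feat_dense.params() + self.mlp1.params() + \
            self.mlp2.params() + self.head.params()

    # -- persistence ---------------------------------------------------------
    def save(self, directory: str) -> None:
        from dataclasses import asdict

        cfg = asdict(self.config)
        cfg["encoder"] = asdict(self.config.encoder)
        meta = {"config": cfg,
                "vocab": {"k": self.vocab.k,
                          "n_length_bins": self.vocab.n_length_bins,
                          "conditions": list(self.vocab.conditions)}}
        nn.save_checkpoint(directory, meta, self.params())

    @classmethod
    def load(cls, directory: str) -> "InclusionModel":
        meta = nn.load_config(directory)
        cfg_d = dict(meta["config"])
        cfg_d["encoder"] = EncoderConfig(**cfg_d["encoder"])
        cfg_d["mlp_hidden"] = tuple(cfg_d["mlp_hidden"])
        model = cls(InclusionConfig(**cfg_d), Vocabulary(**meta["vocab"]))
        nn.load_weights(directory, model.params())
        return model

    # -- prediction ----------------------------------------------------------
    def predict(self, event: SpliceEvent, windows: EventWindows,
                condition: str, condition_prime: str) -> np.ndarray:
        f = featurize(event, windows, self.vocab, condition, condition_prime,
                      use_conservation=self.config.use_conservation)
        return self.forward([f])[0]

    def predict_psi(self, event: SpliceEvent, windows: EventWindows,
                    condition: str, condition_prime: str | None = None) -> float:
        """PSI from the t_psi head. The model is trained on ordered pairs
        with c' != c, so prediction pairs the condition with another known
        one by default; t_psi targets depend on c only."""
        if condition_prime is None:
            known = list(self.vocab.conditions) or list(self._cond_latents)
            others = [c for c in known if c != condition]
            condition_prime = others[0] if others else condition
        return float(self.predict(event, windows, condition, condition_prime)[0])

    def predict_dpsi(self, event: SpliceEvent, windows: EventWindows,
                     c: str, c_prime: str) -> float:
        """Predicted dPSI as the difference of the two direction heads.

        The self-pair (c, c) is identically zero by definition and is
        excluded from training, so it is answered definitionally instead
        of by extrapolating the heads."""
        if c == c_prime:
            return 0.0
        out = self.predict(event, windows, c, c_prime)
        return float(np.clip(out[1] - out[2], -1.0, 1.0))


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------


def build_examples(
    events: list[SpliceEvent],
    windows_by_id: dict[str, EventWindows],
    psi: pd.DataFrame,
    vocab: Vocabulary,
    use_conservation: bool = True,
) -> list[TrainExample]:
    """All ordered condition pairs (c, c') with c' != c per event."""
    table = psi.set_index(["event_id", "condition"]).psi
    conditions = sorted(psi.condition.unique())
    out = []
    for ev in events:
        if ev.event_id not in windows_by_id:
            continue
        have = [c for c in conditions if (ev.event_id, c) in table.index]
        for c in have:
            for cp in have:
                if c == cp:
                    continue
                out.append(TrainExample(
                    event_id=ev.event_id,
                    features=featurize(ev, windows_by_id[ev.event_id], vocab, c, cp,
                                       use_conservation=use_conservation),
                    psi_c=float(table[(ev.event_id, c)]),
                    psi_cprime=float(table[(ev.event_id, cp)]),
                ))
    return out


def finetune(
    model: InclusionModel,
    examples: list[TrainExample],
    rng: np.random.Generator | None = None,
    validation: list[tuple[EventFeatures, float]] | None = None,
    keep_best: bool = True,
) -> pd.DataFrame:
    """Train on the three-part targets; returns (epoch, loss, val_r) log.

    Epsilon is resampled per example per epoch; with epochs=0 the model
    is left at initialisation. When a validation set is supplied and
    ``keep_best`` is on, the parameters from the best-validation epoch
    are restored at the end.
    """
    if not examples:
        raise ValueError("empty training set")
    cfg = model.config
    rng = rng or np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    n = len(examples)
    log = []
    best_r, best_state = -np.inf, None
    steps_per_epoch = (n + cfg.batch_size - 1) // cfg.batch_size
    total_steps = max(1, cfg.epochs * steps_per_epoch)
    warmup = max(1, total_steps // 10)
    gstep = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total, nb = 0.0, 0
        for s in range(0, n, cfg.batch_size):
            batch = [examples[i] for i in order[s:s + cfg.batch_size]]
            targets = np.stack([
                target_transform(ex.psi_c, ex.psi_cprime, rng).as_array()
                for ex in batch])
            model.forward([ex.features for ex in batch])
            loss, dlogits = nn.soft_bce(model.last_logits, targets)
            hw = np.asarray(cfg.head_weights, dtype=np.float32)
            if not np.allclose(hw, 1.0):
                dlogits = dlogits * hw[None, :]
            opt.zero_grad()
            model.backward(dlogits)
            if cfg.lr_decay:
                lr = nn.linear_warmup_lr(gstep, total_steps, warmup, cfg.lr)
            else:
                lr = cfg.lr
            opt.step(lr)
            gstep += 1
            total += loss
            nb += 1
        val_r = np.nan
        if validation:
            preds = predict_batch(model, [f for f, _ in validation])[:, 0]
            truth = np.array([t for _, t in validation])
            val_r = float(np.corrcoef(preds, truth)[0, 1])
            if keep_best and val_r > best_r:
                best_r = val_r
                best_state = [p.value.copy() for p in model.params()]
        log.append((epoch, total / max(nb, 1), val_r))
    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.value = v
    return pd.DataFrame(log, columns=["epoch", "loss", "val_r"])


def predict_batch(model: InclusionModel, feats: list[EventFeatures],
                  batch_size: int = 128) -> np.ndarray:
    outs = [model.forward(feats[i:i + batch_size])
            for i in range(0, len(feats), batch_size)]
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# RBP expression autoencoder (condition embedder)
# ---------------------------------------------------------------------------


class RbpAutoencoder:
    """Symmetric MLP autoencoder on log-scaled RBP expression.

    The bottleneck is the condition embedding; an unseen condition is
    embeddable from its expression vector alone, which is what lets the
    splicing model generalise beyond the training conditions.
    """

    def __init__(self, columns: list[str], latent_dim: int = 16, hidden: int = 32,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.columns = list(columns)
        self.latent_dim = latent_dim
        r = len(columns)
        self.enc1 = nn.Dense(r, hidden, rng)
        self.enc2 = nn.Dense(hidden, latent_dim, rng)
        self.dec1 = nn.Dense(latent_dim, hidden, rng)
        self.dec2 = nn.Dense(hidden, r, rng)
        self._mu = np.zeros(r, dtype=np.float32)
        self._sd = np.ones(r, dtype=np.float32)

    def params(self) -> list[nn.Param]:
        return (self.enc1.params() + self.enc2.params()
                + self.dec1.params() + self.dec2.params())

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (np.log1p(X) - self._mu) / self._sd

    def _forward(self, Xs: np.ndarray):
        a1 = self.enc1(Xs)
        z = self.enc2(nn.gelu(a1))
        a2 = self.dec1(z)
        out = self.dec2(nn.gelu(a2))
        return a1, z, a2, out

    def fit(self, X: np.ndarray, steps: int = 2000, lr: float = 1e-2,
            seed: int = 0) -> list[float]:
        X = np.asarray(X, dtype=np.float32)
        if X.shape[0] < 2:
            raise ValueError("need at least two conditions to train the RBP-AE")
        if (X < 0).any():
            raise ValueError("expression must be nonnegative")
        lx = np.log1p(X)
        self._mu = lx.mean(axis=0).astype(np.float32)
        self._sd = np.maximum(lx.std(axis=0), 1e-3).astype(np.float32)
        Xs = self._scale(X)
        opt = nn.Adam(self.params(), lr=lr)
        losses = []
        for _ in range(steps):
            a1, z, a2, out = self._forward(Xs)
            diff = out - Xs
            loss = float((diff * diff).mean())
            dout = (2.0 * diff / diff.size).astype(np.float32)
            opt.zero_grad()
            da2 = self.dec2.backward(dout) * nn.gelu_grad(a2)
            dz = self.dec1.backward(da2)
            da1 = self.enc2.backward(dz) * nn.gelu_grad(a1)
            self.enc1.backward(da1)
            opt.step()
            losses.append(loss)
        return losses

    def embed(self, expression_vector) -> np.ndarray:
        if isinstance(expression_vector, pd.Series):
            missing = [c for c in self.columns if c not in expression_vector.index]
            if missing:
                raise ValueError(f"expression vector lacks RBPs: {missing[:5]}")
            expression_vector = expression_vector[self.columns].to_numpy()
        x = np.asarray(expression_vector, dtype=np.float32)
        if x.shape[-1] != len(self.columns):
            raise ValueError(f"expected {len(self.columns)} RBPs, got {x.shape[-1]}")
        xs = self._scale(x[None, :])
        return self.enc2(nn.gelu(self.enc1(xs)))[0]


def train_rbp_ae(expression: pd.DataFrame, latent_dim: int = 16, hidden: int = 32,
                 steps: int = 2000, lr: float = 1e-2, seed: int = 0
                 ) -> tuple[RbpAutoencoder, list[float]]:
    """Fit the condition autoencoder on a (conditions x RBPs) matrix."""
    ae = RbpAutoencoder(list(expression.columns), latent_dim=latent_dim,
                        hidden=hidden, seed=seed)
    losses = ae.fit(expression.to_numpy(), steps=steps, lr=lr, seed=seed)
    return ae, losses
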
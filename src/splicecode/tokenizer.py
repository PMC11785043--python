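"""Overlapping k-mer tokenization and the span-masking MLM corruption scheme.

Sequences over {A,C,G,T,N} are converted to overlapping k-mers (default
k=6), so a window of L bases yields L-k+1 tokens. Any k-mer containing N
maps to UNK. For masked-LM pre-training, seed tokens are drawn at rate
rho and a neighbourhood of ``span`` tokens on each side is masked along
with each seed, because neighbouring overlapping k-mers share bases with
the seed and would otherwise leak it; the loss is computed at the seeds
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class Vocabulary:
    """Deterministic k-mer vocabulary.

    Layout: [PAD, CLS, MASK, UNK] + 4^k k-mers (lexicographic) + feature
    tokens (length bins, then condition tokens), appended in a fixed order.
    """

    SPECIALS = ("PAD", "CLS", "MASK", "UNK")

    def __init__(self, k: int = 6, n_length_bins: int = 32, conditions: tuple[str, ...] = ()):
        self.k = k
        self.n_length_bins = n_length_bins
        self.conditions = tuple(conditions)
        self._tokens: list[str] = list(self.SPECIALS)
        self._tokens += ["".join(p) for p in product(BASES, repeat=k)]
        self._tokens += [f"LEN_BIN_{i}" for i in range(n_length_bins)]
        self._tokens += [f"COND_{c}" for c in self.conditions]
        self._index = {t: i for i, t in enumerate(self._tokens)}
        # base-4 encoding for fast k-mer lookup
        self._base_code = np.full(128, -1, dtype=np.int64)
        for i, b in enumerate(BASES):
            self._base_code[ord(b)] = i
        self.kmer_offset = len(self.SPECIALS)

    # -- ids ---------------------------------------------------------------
    @property
    def pad_id(self) -> int:
        return 0

    @property
    def cls_id(self) -> int:
        return 1

    @property
    def mask_id(self) -> int:
        return 2

    @property
    def unk_id(self) -> int:
        return 3

    def __len__(self) -> int:
        return len(self._tokens)

    def length_bin_id(self, bin_index: int) -> int:
        if not 0 <= bin_index < self.n_length_bins:
            raise ValueError(f"length bin {bin_index} outside [0, {self.n_length_bins})")
        return self.kmer_offset + 4**self.k + bin_index

    def condition_id(self, condition: str) -> int:
        try:
            j = self.conditions.index(condition)
        except ValueError:
            raise KeyError(f"unknown condition {condition!r}") from None
        return self.kmer_offset + 4**self.k + self.n_length_bins + j

    def token(self, idx: int) -> str:
        return self._tokens[idx]

    def is_kmer_id(self, idx: int) -> bool:
        return self.kmer_offset <= idx < self.kmer_offset + 4**self.k

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("token\tid\n")
            for i, t in enumerate(self._tokens):
                fh.write(f"{t}\t{i}\n")


@dataclass
class TokenSequence:
    """Token ids for one sequence; ``n_special`` prefix tokens (CLS and
    any feature tokens) precede the k-mer tokens."""

    tokens: np.ndarray
    k: int
    n_special: int = 0

    def kmer_part(self) -> np.ndarray:
        return self.tokens[self.n_special:]


@dataclass
class MaskPlan:
    seed_positions: np.ndarray
    masked_positions: np.ndarray
    loss_positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.loss_positions is None:
            self.loss_positions = self.seed_positions


def tokenize(seq: str, vocab: Vocabulary) -> TokenSequence:
    """Convert a DNA sequence into overlapping k-mer token ids."""
    k = vocab.k
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    codes = vocab._base_code[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    bad = codes < 0
    if bad.any() and not set(seq.upper()) <= set("ACGTN"):
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    codes_safe = np.where(bad, 0, codes)
    n = len(seq) - k + 1
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes_safe, k)
    ids = windows @ powers + vocab.kmer_offset
    has_n = np.lib.stride_tricks.sliding_window_view(bad, k).any(axis=1)
    ids = np.where(has_n, vocab.unk_id, ids)
    assert len(ids) == n
    return TokenSequence(tokens=ids.astype(np.int64), k=k, n_special=0)


def detokenize(tokens: TokenSequence | np.ndarray, vocab: Vocabulary) -> str:
    """Rebuild the sequence from overlapping k-mer tokens.

    Raises if any token is UNK/special or if consecutive k-mers disagree
    on their overlap (i.e. the tokens cannot come from a real sequence).
    """
    ids = tokens.kmer_part() if isinstance(tokens, TokenSequence) else np.asarray(tokens)
    if len(ids) == 0:
        return ""
    kmers = []
    for i, t in enumerate(ids):
        if not vocab.is_kmer_id(int(t)):
            raise ValueError(f"token at position {i} ({vocab.token(int(t))}) is not a k-mer")
        kmers.append(vocab.token(int(t)))
    out = [kmers[0]]
    for i in range(1, len(kmers)):
        if kmers[i][:-1] != kmers[i - 1][1:]:
            raise ValueError(f"inconsistent k-mer overlap at position {i}")
        out.append(kmers[i][-1])
    return "".join(out)


def apply_mlm_mask(
    tokens: np.ndarray,
    rng: np.random.Generator,
    rate: float = 0.15,
    span: int = 3,
    vocab: Vocabulary | None = None,
    n_special: int = 0,
    bert_8020: bool = False,
) -> tuple[np.ndarray, MaskPlan]:
    """Corrupt a token array for masked-LM training.

    Seeds are drawn per token as Bernoulli(rate) over the non-special
    positions; each seed masks the index range [i-span, i+span] clipped to
    the non-special region. The loss positions are the seeds alone. With
    ``bert_8020`` the classic 80/10/10 replacement is applied to masked
    positions instead of always writing MASK.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if span < 0:
        raise ValueError("span must be >= 0")
    mask_id = vocab.mask_id if vocab is not None else 2
    tokens = np.asarray(tokens)
    n = len(tokens)
    valid = np.arange(n_special, n)
    seeds = valid[rng.random(len(valid)) < rate]
    masked = np.zeros(n, dtype=bool)
    for s in seeds:
        masked[max(n_special, s - span): min(n, s + span + 1)] = True
    masked_idx = np.flatnonzero(masked)
    corrupted = tokens.copy()
    if bert_8020 and vocab is not None:
        r = rng.random(len(masked_idx))
        for j, i in enumerate(masked_idx):
            if r[j] < 0.8:
                corrupted[i] = mask_id
            elif r[j] < 0.9:
                corrupted[i] = rng.integers(vocab.kmer_offset, vocab.kmer_offset + 4**vocab.k)
            # else: keep original
    else:
        corrupted[masked_idx] = mask_id
    return corrupted, MaskPlan(seed_positions=np.sort(seeds), masked_positions=masked_idx)
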
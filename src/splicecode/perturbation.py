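"""In-silico mutagenesis of splice-site windows.

All operations act on :class:`EventWindows` and score effects through a
caller-supplied oracle ``psi(windows) -> float`` for a fixed condition
(pair) — either a trained inclusion model or the synthetic grammar's
noiseless rule. Effects are dPSI relative to the unmutated windows.

The "no change" cutoff for mutation effects is the nearest-rank 95th
percentile of |dPSI| under random same-length substitutions, mirroring
how short random mutations rarely move PSI unless they hit a core
splicing signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import EventWindows
from .tokenizer import BASES

PsiOracle = Callable[[EventWindows], float]

# site geometry relative to the window centre (transcript orientation)
DONOR_SPAN = (-3, 6)  # exon 3 nt | GT + 4 intronic nt
ACCEPTOR_SPAN = (-20, 3)  # polypyrimidine/branch region + AG | exon 3 nt
DONOR_TOWER, ACCEPTOR_TOWER = 2, 1  # cassette donor / cassette acceptor


@dataclass(frozen=True)
class MutationSpec:
    tower: int
    offset: int
    replacement: str

    def __post_init__(self):
        if not 0 <= self.tower < 4:
            raise ValueError("tower index must be 0..3")


@dataclass(frozen=True)
class NullThreshold:
    threshold: float
    n_events: int = 100
    n_mutations_per_position: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def mutate(windows: EventWindows, spec: MutationSpec) -> EventWindows:
    """Substitute a same-length span; everything else is untouched."""
    seq = windows.seqs[spec.tower]
    end = spec.offset + len(spec.replacement)
    if spec.offset < 0 or end > len(seq):
        raise ValueError(
            f"span [{spec.offset},{end}) outside window of length {len(seq)}")
    return windows.replace_seq(spec.tower, seq[:spec.offset] + spec.replacement + seq[end:])


def perturb_splice_site(
    windows: EventWindows,
    direction: str,
    pwm: np.ndarray,
    site: str = "donor",
) -> EventWindows:
    """Strengthen (write the PWM consensus) or weaken (break the
    invariant GT/AG dinucleotide) a cassette splice site."""
    if direction not in ("strengthen", "weaken"):
        raise ValueError("direction must be 'strengthen' or 'weaken'")
    if site == "donor":
        tower, (lo, hi) = DONOR_TOWER, DONOR_SPAN
        core_at = 0  # GT begins at the centre (first intronic base)
    elif site == "acceptor":
        tower, (lo, hi) = ACCEPTOR_TOWER, ACCEPTOR_SPAN
        core_at = -2  # AG are the last two intronic bases
    else:
        raise ValueError("site must be 'donor' or 'acceptor'")
    half = windows.width // 2
    if pwm.shape[0] != hi - lo:
        raise ValueError(f"PWM length {pwm.shape[0]} incompatible with the "
                         f"{site} site region of {hi - lo} nt")
    if direction == "strengthen":
        consensus = "".join(BASES[i] for i in pwm.argmax(axis=1))
        return mutate(windows, MutationSpec(tower, half + lo, consensus))
    # weaken: replace the core dinucleotide with its lowest-scoring alternative
    pos0 = (core_at - lo)  # index of the first core base within the PWM
    repl = "".join(BASES[int(pwm[pos0 + i].argmin())] for i in range(2))
    return mutate(windows, MutationSpec(tower, half + core_at, repl))


def random_substitution(seq: str, offset: int, length: int,
                        rng: np.random.Generator,
                        avoid_motifs: Sequence[str] = (),
                        max_tries: int = 20) -> str:
    """A random same-length substitution: each base uniformly replaced by
    one of its three alternatives. Draws that create an instance of any
    motif in ``avoid_motifs`` near the edited span are rejected."""
    for _ in range(max_tries):
        repl = "".join(
            BASES[(BASES.index(b) + int(rng.integers(1, 4))) % 4] if b in BASES
            else "ACGT"[int(rng.integers(0, 4))]
            for b in seq[offset:offset + length])
        new = seq[:offset] + repl + seq[offset + length:]
        if not avoid_motifs:
            return repl
        pad = max(len(m) for m in avoid_motifs)
        context = new[max(0, offset - pad): offset + length + pad]
        if not any(m in context for m in avoid_motifs):
            return repl
    return repl  # give up on avoidance rather than loop forever


def nearest_rank_percentile(values: Sequence[float], p: float = 0.95) -> float:
    """The ceil(p*n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empty sample")
    rank = int(np.ceil(p * len(v)))
    return float(v[max(rank - 1, 0)])


def compute_null_threshold(
    oracle: PsiOracle,
    events_windows: Sequence[EventWindows],
    offsets: Sequence[tuple[int, int]],
    n_events: int = 100,
    n_mutations: int = 5,
    mutation_length: int = 6,
    seed: int = 0,
    percentile: float = 0.95,
    avoid_motifs: Sequence[str] = (),
) -> NullThreshold:
    """Null |dPSI| threshold from random mutations at fixed offsets.

    For each (tower, offset), ``n_events`` windows are sampled and each
    receives ``n_mutations`` random same-length substitutions; the
    threshold is the nearest-rank 95th percentile of all |dPSI|.
    """
    if not events_windows or not offsets:
        raise ValueError("need at least one event and one offset")
    rng = np.random.default_rng(seed)
    effects = []
    for tower, offset in offsets:
        idx = rng.choice(len(events_windows), size=min(n_events, len(events_windows)),
                         replace=False)
        for i in idx:
            w = events_windows[i]
            base = oracle(w)
            for _ in range(n_mutations):
                repl = random_substitution(w.seqs[tower], offset, mutation_length,
                                           rng, avoid_motifs)
                effects.append(abs(oracle(mutate(w, MutationSpec(tower, offset, repl)))
                                   - base))
    return NullThreshold(
        threshold=nearest_rank_percentile(effects, percentile),
        n_events=n_events, n_mutations_per_position=n_mutations, seed=seed)


def call_effect(dpsi_hat: float, null: NullThreshold) -> str:
    """Classify a predicted effect against the random-mutation null."""
    if abs(dpsi_hat) < null.threshold:
        return "no_change"
    return "increase" if dpsi_hat > 0 else "decrease"


def sliding_window_scan(
    oracle: PsiOracle,
    windows: EventWindows,
    tower: int,
    window_len: int = 6,
    reps: int = 5,
    seed: int = 0,
    stride: int = 1,
    avoid_motifs: Sequence[str] = (),
) -> pd.DataFrame:
    """Mean dPSI of ``reps`` random substitutions per sliding offset.

    Returns a frame (tower, offset, mean_dpsi, sd) rankable by
    |mean_dpsi| to localise regulatory regions.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seq = windows.seqs[tower]
    if window_len >= len(seq):
        raise ValueError("window_len must be shorter than the sequence")
    rng = np.random.default_rng(seed)
    base = oracle(windows)
    rows = []
    for offset in range(0, len(seq) - window_len + 1, stride):
        vals = []
        for _ in range(reps):
            repl = random_substitution(seq, offset, window_len, rng, avoid_motifs)
            vals.append(oracle(mutate(windows, MutationSpec(tower, offset, repl))) - base)
        rows.append((tower, offset, float(np.mean(vals)), float(np.std(vals))))
    return pd.DataFrame(rows, columns=["tower", "offset", "mean_dpsi", "sd"])


def top_scan_offsets(scan: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    return scan.reindex(scan.mean_dpsi.abs().sort_values(ascending=False).index).head(n)
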
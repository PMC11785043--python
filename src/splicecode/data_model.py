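"""Cassette-exon event structures, genomic I/O and the train/test split.

Coordinates are 0-based, half-open internally; GTF input (1-based,
inclusive) is converted at the boundary. Each of the four splice sites is
stored as the exon/intron *boundary coordinate*: the genomic position of
the first base to the right of the junction. A window of width W around a
boundary b is genome[b - W/2, b + W/2), so the junction always sits at
window offset W/2; on the minus strand windows are reverse-complemented,
which preserves that convention in transcript orientation.

Splice sites are kept in *role* order — upstream-exon donor, cassette
acceptor, cassette donor, downstream-exon acceptor — which is genomically
increasing on the plus strand and decreasing on the minus strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tokenizer import reverse_complement

WINDOW_DEFAULT = 400


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpliceEvent:
    """A cassette exon defined by its four splice-site boundaries."""

    event_id: str
    chrom: str
    strand: str
    ss: tuple[int, int, int, int]  # role order: E1 donor, A acceptor, A donor, E2 acceptor
    gene_id: str = ""
    flank_exon_lens: tuple[int, int] | None = None  # upstream, downstream exon lengths if known

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.event_id}: strand must be + or -, got {self.strand!r}")
        s = self.ss
        if len(s) != 4:
            raise ValueError(f"{self.event_id}: need four splice sites")
        diffs = np.diff(s)
        ok = (diffs > 0).all() if self.strand == "+" else (diffs < 0).all()
        if not ok:
            raise ValueError(
                f"{self.event_id}: splice sites {s} not ordered for strand {self.strand} "
                "(cassette acceptor must precede cassette donor in transcript orientation)")

    @property
    def intron_lens(self) -> tuple[int, int]:
        s = self.ss
        return abs(s[1] - s[0]), abs(s[3] - s[2])

    @property
    def cassette_len(self) -> int:
        return abs(self.ss[2] - self.ss[1])

    def cassette_interval(self) -> tuple[int, int]:
        lo, hi = sorted((self.ss[1], self.ss[2]))
        return lo, hi


@dataclass(frozen=True)
class Quantification:
    event_id: str
    condition: str
    psi: float

    def __post_init__(self):
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError(f"{self.event_id}/{self.condition}: psi={self.psi} outside [0,1]")


@dataclass
class EventWindows:
    """Four splice-site-centred sequences with per-base conservation."""

    seqs: tuple[str, str, str, str]
    cons: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    width: int

    def __post_init__(self):
        for i, (s, c) in enumerate(zip(self.seqs, self.cons)):
            if len(s) != self.width or len(c) != self.width:
                raise ValueError(f"window {i}: length {len(s)}/{len(c)} != {self.width}")

    def replace_seq(self, tower: int, seq: str) -> "EventWindows":
        seqs = list(self.seqs)
        seqs[tower] = seq
        return EventWindows(tuple(seqs), self.cons, self.width)


@dataclass
class DatasetSplit:
    train_ids: list[str]
    test_ids: list[str]
    held_out_chroms: list[str]
    similarity_threshold: float
    discarded_test_ids: list[str] = field(default_factory=list)


@dataclass
class LoadResult:
    events: list[SpliceEvent]
    quantifications: list[Quantification]
    errors: list[str] = field(default_factory=list)

    def psi_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(q.event_id, q.condition, q.psi) for q in self.quantifications],
            columns=["event_id", "condition", "psi"],
        )


# ---------------------------------------------------------------------------
# genome / conservation access
# ---------------------------------------------------------------------------


def open_genome(path_or_mapping):
    """Accepts a FASTA path (via pyfaidx) or an in-memory {chrom: seq} mapping."""
    if isinstance(path_or_mapping, (str, os.PathLike)):
        import pyfaidx

        return pyfaidx.Fasta(str(path_or_mapping), sequence_always_upper=True)
    return path_or_mapping


def _chrom_seq(genome, chrom: str) -> tuple[int, "object"]:
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    rec = genome[chrom]
    return len(rec), rec


def fetch_padded(genome, chrom: str, start: int, end: int) -> str:
    """Genome slice [start, end) with out-of-bounds overhang padded with N."""
    n, rec = _chrom_seq(genome, chrom)
    lo, hi = max(0, start), min(n, end)
    core = ""
    if hi > lo:
        piece = rec[lo:hi]
        core = str(piece.seq if hasattr(piece, "seq") else piece).upper()
    return "N" * (lo - start) + core + "N" * (end - hi)


class ConservationTrack:
    """Per-base conservation in [0,1]; positions without data score 0."""

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None):
        # chrom -> (sorted positions, scores), positions 0-based
        self._data = dict(data or {})
        self._bw = None

    @classmethod
    def from_tsv(cls, path: str) -> "ConservationTrack":
        """Two/three-column TSV: [chrom] pos score, 0-based positions."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] == 2:
            df.insert(0, "chrom", "chr1")
        df.columns = ["chrom", "pos", "score"]
        out = {}
        for chrom, grp in df.groupby("chrom"):
            pos = grp["pos"].to_numpy(dtype=np.int64)
            order = np.argsort(pos)
            out[str(chrom)] = (pos[order], grp["score"].to_numpy(dtype=float)[order])
        return cls(out)

    @classmethod
    def from_wig(cls, path: str) -> "ConservationTrack":
        """Fixed-step / variable-step wiggle (1-based, converted here)."""
        chunks: dict[str, list[tuple[int, float]]] = {}
        mode = chrom = None
        start = step = span = 1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                if line.startswith(("fixedStep", "variableStep")):
                    fields = dict(kv.split("=") for kv in line.split()[1:])
                    mode = line.split()[0]
                    chrom = fields["chrom"]
                    start = int(fields.get("start", 1)) - 1
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                    chunks.setdefault(chrom, [])
                    continue
                if mode == "fixedStep":
                    val = float(line)
                    for s in range(span):
                        chunks[chrom].append((start + s, val))
                    start += step
                else:
                    p, v = line.split()
                    base = int(p) - 1
                    for s in range(span):
                        chunks[chrom].append((base + s, float(v)))
        data = {}
        for chrom, pairs in chunks.items():
            pairs.sort()
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            sc = np.array([v for _, v in pairs], dtype=float)
            data[chrom] = (pos, sc)
        return cls(data)

    @classmethod
    def from_bigwig(cls, path: str) -> "ConservationTrack":
        import pyBigWig  # optional dependency

        t = cls()
        t._bw = pyBigWig.open(path)
        return t

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start, dtype=float)
        if self._bw is not None:
            if chrom in self._bw.chroms():
                n = self._bw.chroms()[chrom]
                lo, hi = max(0, start), min(n, end)
                if hi > lo:
                    vals = np.nan_to_num(np.array(self._bw.values(chrom, lo, hi)))
                    out[lo - start: hi - start] = vals
            return out
        if chrom not in self._data:
            return out
        pos, sc = self._data[chrom]
        i0, i1 = np.searchsorted(pos, (start, end))
        out[pos[i0:i1] - start] = sc[i0:i1]
        return out


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

EVENT_TSV_COLUMNS = ["event_id", "chrom", "strand", "ss1", "ss2", "ss3", "ss4"]


def _events_from_tsv(path: str, errors: list[str]) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    events = []
    for row in df.itertuples():
        flanks = None
        if "e1_len" in df.columns and "e2_len" in df.columns:
            flanks = (int(row.e1_len), int(row.e2_len))
        events.append(
            SpliceEvent(
                event_id=str(row.event_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                ss=(int(row.ss1), int(row.ss2), int(row.ss3), int(row.ss4)),
                gene_id=str(getattr(row, "gene_id", "")),
                flank_exon_lens=flanks,
            ))
    return events


def _events_from_gtf(path: str, errors: list[str]) -> list[SpliceEvent]:
    """Each transcript with exactly three exons defines one cassette event."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True)
    events = []
    for tx in db.features_of_type("transcript"):
        exons = sorted(db.children(tx, featuretype="exon"), key=lambda e: e.start)
        if len(exons) != 3:
            continue
        e1, e2, e3 = exons  # genomic order
        # GTF 1-based inclusive -> 0-based half-open: start-1, end stays
        if tx.strand == "+":
            ss = (e1.end, e2.start - 1, e2.end, e3.start - 1)
            flanks = (e1.end - e1.start + 1, e3.end - e3.start + 1)
        else:
            ss = (e3.start - 1, e2.end, e2.start - 1, e1.end)
            flanks = (e3.end - e3.start + 1, e1.end - e1.start + 1)
        events.append(
            SpliceEvent(
                event_id=tx.id, chrom=tx.seqid, strand=tx.strand, ss=ss,
                gene_id=tx.attributes.get("gene_id", [""])[0],
                flank_exon_lens=flanks,
            ))
    return events


def load_events(
    annotation_path: str,
    quantification_path: str,
    genome=None,
) -> LoadResult:
    """Load cassette events (GTF or event TSV) plus PSI quantifications.

    Quantification rows with PSI outside [0,1] or an unknown event id are
    rejected and reported in ``errors`` with their line number; events with
    inconsistent splice-site geometry raise immediately.
    """
    for p in (annotation_path, quantification_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    errors: list[str] = []
    if str(annotation_path).endswith((".gtf", ".gff", ".gtf.gz")):
        events = _events_from_gtf(annotation_path, errors)
    else:
        events = _events_from_tsv(annotation_path, errors)
    if genome is not None:
        for ev in events:
            if ev.chrom not in genome:
                raise KeyError(f"event {ev.event_id} references unknown chromosome {ev.chrom!r}")
    known = {e.event_id for e in events}
    quants: list[Quantification] = []
    qdf = pd.read_csv(quantification_path, sep="\t")
    for i, row in enumerate(qdf.itertuples(), start=2):  # line 1 = header
        ev_id, cond, psi = str(row.event_id), str(row.condition), float(row.psi)
        if ev_id not in known:
            errors.append(f"line {i}: unknown event_id {ev_id!r}")
            continue
        if not 0.0 <= psi <= 1.0:
            errors.append(f"line {i}: event {ev_id!r} psi={psi} outside [0,1], row rejected")
            continue
        quants.append(Quantification(ev_id, cond, psi))
    seen = set()
    for q in quants:
        key = (q.event_id, q.condition)
        if key in seen:
            raise ValueError(f"duplicate quantification for {key}")
        seen.add(key)
    quantified = {q.event_id for q in quants}
    events = [e for e in events if e.event_id in quantified]
    return LoadResult(events=events, quantifications=quants, errors=errors)


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------


def extract_windows(
    event: SpliceEvent,
    genome,
    conservation: ConservationTrack | None = None,
    width: int = WINDOW_DEFAULT,
) -> EventWindows:
    """Four width-W windows centred on the event's splice-site boundaries.

    Out-of-chromosome overhang is padded with N (conservation 0); minus
    strand windows are reverse-complemented so that all four are in
    transcript orientation with the junction at offset W/2.
    """
    if width % 2:
        raise ValueError("window width must be even")
    half = width // 2
    seqs, cons = [], []
    for b in event.ss:
        seq = fetch_padded(genome, event.chrom, b - half, b + half)
        cv = (conservation.values(event.chrom, b - half, b + half)
              if conservation is not None else np.zeros(width))
        n, _ = _chrom_seq(genome, event.chrom)
        cv[np.array([c == "N" for c in seq])] = 0.0
        if event.strand == "-":
            seq = reverse_complement(seq)
            cv = cv[::-1].copy()
        seqs.append(seq)
        cons.append(cv)
    return EventWindows(seqs=tuple(seqs), cons=tuple(cons), width=width)


# ---------------------------------------------------------------------------
# train/test split with paralog filtering
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_jaccard(a: str, b: str, k: int = 11) -> float:
    sa, sb = _kmer_set(a, k), _kmer_set(b, k)
    if not sa and not sb:
        return 1.0
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


def cassette_sequence(event: SpliceEvent, genome) -> str:
    lo, hi = event.cassette_interval()
    seq = fetch_padded(genome, event.chrom, lo, hi)
    return reverse_complement(seq) if event.strand == "-" else seq


def split_train_test(
    events: Sequence[SpliceEvent],
    genome,
    held_out_chroms: Iterable[str],
    similarity_threshold: float = 0.8,
    k: int = 11,
) -> DatasetSplit:
    """Chromosome-held-out split; test exons too similar to any training
    exon (k-mer Jaccard on the cassette sequence) are discarded."""
    held = sorted(set(held_out_chroms))
    if not held:
        raise ValueError("held_out_chroms must be nonempty")
    evs = sorted(events, key=lambda e: e.event_id)  # order-invariant output
    train = [e for e in evs if e.chrom not in held]
    test = [e for e in evs if e.chrom in held]
    train_seqs = [cassette_sequence(e, genome) for e in train]
    train_kmers = [_kmer_set(s, k) for s in train_seqs]
    kept, discarded = [], []
    for ev in test:
        s = _kmer_set(cassette_sequence(ev, genome), k)
        similar = False
        for tk in train_kmers:
            union = s | tk
            if union and len(s & tk) / len(union) > similarity_threshold:
                similar = True
                break
        (discarded if similar else kept).append(ev.event_id)
    if test and not kept:
        import warnings

        warnings.warn("all test events discarded by the similarity filter")
    return DatasetSplit(
        train_ids=[e.event_id for e in train],
        test_ids=kept,
        held_out_chroms=held,
        similarity_threshold=similarity_threshold,
        discarded_test_ids=discarded,
    )
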
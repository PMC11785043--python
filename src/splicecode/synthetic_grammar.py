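"""Synthetic splicing grammar: generator and noiseless PSI oracle.

Generates genomes containing cassette exons whose inclusion follows a
fully specified logistic rule, so that every downstream component —
window extraction, model training, mutagenesis scans, sequence design —
can be scored against exact ground truth.

The generative rule for event e in condition c is

    Psi(e, c) = sigmoid( beta0 + beta_ss * (s3 + s5) + sum_m w_{m,c} * count_m(e) )

where s3, s5 are min-max normalised PWM log-odds scores of the cassette
acceptor and donor sites, and count_m counts occurrences of regulatory
motif m inside its allowed region and positional window. Observed
quantifications add truncated-normal noise; the noiseless rule doubles as
the design-time oracle. Conservation is elevated over exons and planted
motifs, and each motif has a pseudo-RBP whose per-condition expression
increases with the motif's effect weight, mimicking an RBP expression
matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .data_model import ConservationTrack, SpliceEvent
from .tokenizer import BASES, reverse_complement

# regions a motif may occupy, anchored at the cassette splice sites
REGIONS = ("upstream_intron", "cassette_exon", "downstream_intron")


@dataclass(frozen=True)
class Motif:
    name: str
    seq: str
    weights: dict  # condition -> effect on the log-odds scale
    region: str
    window: tuple[int, int]  # allowed start offsets relative to the region anchor

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"motif {self.name}: unknown region {self.region!r}")
        if not 6 <= len(self.seq) <= 8:
            raise ValueError(f"motif {self.name}: length must be 6-8 nt")

    def weight(self, condition: str) -> float:
        return float(self.weights.get(condition, 0.0))


def _pwm(consensus: str, core: tuple[int, ...], p_consensus: float = 0.7,
         p_core: float = 0.997) -> np.ndarray:
    """Simple PWM: consensus base gets p, the rest share 1-p; core
    positions (the GT/AG dinucleotide) are near-invariant."""
    m = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        p = p_core if i in core else p_consensus
        m[i, :] = (1.0 - p) / 3.0
        m[i, BASES.index(b)] = p
    return m


DONOR_CONSENSUS = "CAGGTAAGT"  # exon 3 nt | intron 6 nt, GT at offsets 3-4
DONOR_CORE = (3, 4)
DONOR_EXONIC = 3  # bases of the PWM left of the boundary
ACCEPTOR_CONSENSUS = "TTTTTTTTTTCTTTTCCTAGGTT"  # intron 20 nt (ends AG) | exon 3 nt
ACCEPTOR_CORE = (18, 19)
ACCEPTOR_INTRONIC = 20


def pwm_log_odds(seq: str, pwm: np.ndarray, background: float = 0.25) -> float:
    if len(seq) != pwm.shape[0]:
        raise ValueError(f"sequence length {len(seq)} != PWM length {pwm.shape[0]}")
    score = 0.0
    for i, b in enumerate(seq):
        p = pwm[i, BASES.index(b)] if b in BASES else background
        score += np.log2(max(p, 1e-4) / background)
    return float(score)


def pwm_score_range(pwm: np.ndarray, background: float = 0.25) -> tuple[float, float]:
    lo = float(np.log2(np.maximum(pwm.min(axis=1), 1e-4) / background).sum())
    hi = float(np.log2(np.maximum(pwm.max(axis=1), 1e-4) / background).sum())
    return lo, hi


def normalized_score(seq: str, pwm: np.ndarray) -> float:
    lo, hi = pwm_score_range(pwm)
    if hi - lo < 1e-12:  # flat PWM: every sequence scores the same
        return 0.5
    return (pwm_log_odds(seq, pwm) - lo) / (hi - lo)


@dataclass
class GrammarSpec:
    """Full specification of the generative splicing rule."""

    donor_pwm: np.ndarray = field(default_factory=lambda: _pwm(DONOR_CONSENSUS, DONOR_CORE))
    acceptor_pwm: np.ndarray = field(
        default_factory=lambda: _pwm(ACCEPTOR_CONSENSUS, ACCEPTOR_CORE))
    motifs: list[Motif] = field(default_factory=list)
    beta0: float = -8.5
    beta_ss: float = 4.0
    noise_sd: float = 0.02
    upstream_reach: int = 48  # intronic bases upstream of the acceptor that carry signal
    downstream_reach: int = 48
    cassette_len_range: tuple[int, int] = (28, 44)
    intron_len_range: tuple[int, int] = (90, 160)
    flank_len_range: tuple[int, int] = (40, 70)
    spacer_range: tuple[int, int] = (60, 120)
    n_chroms: int = 10
    p_motif: float = 0.4
    minus_strand_prob: float = 0.5
    # conservation gating: a motif instance is functional only where the
    # conservation over its span is high; decoy instances (same sequence,
    # background conservation) are planted alongside. This makes the
    # conservation track informative rather than decorative.
    conservation_gated: bool = False
    p_decoy: float = 0.6
    cons_gate: float = 0.6

    def __post_init__(self):
        for pwm in (self.donor_pwm, self.acceptor_pwm):
            if not np.allclose(pwm.sum(axis=1), 1.0):
                raise ValueError("PWM columns must sum to 1")
        for m in self.motifs:
            lo, hi = m.window
            reach = {"upstream_intron": self.upstream_reach,
                     "downstream_intron": self.downstream_reach,
                     "cassette_exon": self.cassette_len_range[0]}[m.region]
            if not (0 <= lo < hi <= reach):
                raise ValueError(
                    f"motif {m.name}: window {m.window} incompatible with region reach {reach}")

    def conditions_used(self) -> list[str]:
        seen: list[str] = []
        for m in self.motifs:
            for c in m.weights:
                if c not in seen:
                    seen.append(c)
        return seen


def default_spec(conditions: tuple[str, str] = ("liverlike", "cerebellumlike")) -> GrammarSpec:
    """Two-condition grammar with shared and condition-specific motifs.

    Motif windows are kept disjoint from the splice-site PWM footprints
    (20 intronic + 3 exonic nt at the acceptor, 3 + 6 at the donor), so
    site strength and regulatory-motif content are controlled by
    different bases and site perturbations cannot silently create or
    destroy counted motif instances."""
    c0, c1 = conditions
    motifs = [
        Motif("NEUR_ENH", "TGCATG", {c1: 2.5, c0: 0.0}, "downstream_intron", (12, 40)),
        Motif("LIV_ENH", "CTAACC", {c0: 2.0, c1: 0.0}, "upstream_intron", (26, 40)),
        Motif("GEN_ESE", "GAAGAA", {c0: 1.5, c1: 1.5}, "cassette_exon", (4, 18)),
        Motif("GEN_ISS", "TCCGCT", {c0: -1.5, c1: -1.5}, "upstream_intron", (26, 40)),
    ]
    return GrammarSpec(motifs=motifs)


# ---------------------------------------------------------------------------
# the oracle
# ---------------------------------------------------------------------------


@dataclass
class EventRegions:
    """Transcript-orientation sequences carrying all grammar signal."""

    acceptor_site: str  # [b2-20, b2+3)
    donor_site: str  # [b3-3, b3+6)
    upstream_intron: str  # the ``upstream_reach`` bases ending at b2
    cassette_exon: str  # [b2, b3)
    downstream_intron: str  # the ``downstream_reach`` bases starting at b3
    # matching conservation (required only for conservation-gated grammars)
    upstream_cons: np.ndarray | None = None
    exon_cons: np.ndarray | None = None
    downstream_cons: np.ndarray | None = None


def _count_motif(m: Motif, regions: EventRegions, spec: GrammarSpec) -> int:
    if m.region == "upstream_intron":
        s, cv = regions.upstream_intron, regions.upstream_cons
        # window (lo, hi) = allowed distances of the motif start upstream of b2
        lo, hi = m.window
        rs, re = len(s) - hi, len(s) - lo
    elif m.region == "cassette_exon":
        s, cv = regions.cassette_exon, regions.exon_cons
        rs, re = m.window
    else:
        s, cv = regions.downstream_intron, regions.downstream_cons
        rs, re = m.window
    count = 0
    for i in range(max(0, rs), min(len(s), re)):
        if s[i:i + len(m.seq)] != m.seq:
            continue
        if spec.conservation_gated:
            if cv is None:
                raise ValueError("conservation-gated grammar needs region conservation")
            if float(np.mean(cv[i:i + len(m.seq)])) <= spec.cons_gate:
                continue
        count += 1
    return count


def true_psi(regions: EventRegions, condition: str, spec: GrammarSpec) -> float:
    """Exact evaluation of the logistic splicing rule (noiseless oracle)."""
    s3 = normalized_score(regions.acceptor_site, spec.acceptor_pwm)
    s5 = normalized_score(regions.donor_site, spec.donor_pwm)
    logit = spec.beta0 + spec.beta_ss * (s3 + s5)
    for m in spec.motifs:
        w = m.weight(condition)
        if w:
            logit += w * _count_motif(m, regions, spec)
    return float(1.0 / (1.0 + np.exp(-logit)))


def regions_from_genome(event: SpliceEvent, genome, spec: GrammarSpec,
                        conservation: ConservationTrack | None = None) -> EventRegions:
    """Extract the grammar-relevant regions for an event (strand-aware)."""
    from .data_model import fetch_padded

    def seg(b_from: int, b_to: int) -> str:
        # transcript-orientation segment between boundary offsets
        if event.strand == "+":
            return fetch_padded(genome, event.chrom, b_from, b_to)
        return reverse_complement(fetch_padded(genome, event.chrom, b_to, b_from))

    def cv(b_from: int, b_to: int):
        if conservation is None:
            return None
        if event.strand == "+":
            return conservation.values(event.chrom, b_from, b_to)
        return conservation.values(event.chrom, b_to, b_from)[::-1]

    b2, b3 = event.ss[1], event.ss[2]
    sgn = 1 if event.strand == "+" else -1
    return EventRegions(
        acceptor_site=seg(b2 - sgn * ACCEPTOR_INTRONIC, b2 + sgn * 3),
        donor_site=seg(b3 - sgn * DONOR_EXONIC, b3 + sgn * 6),
        upstream_intron=seg(b2 - sgn * spec.upstream_reach, b2),
        cassette_exon=seg(b2, b3),
        downstream_intron=seg(b3, b3 + sgn * spec.downstream_reach),
        upstream_cons=cv(b2 - sgn * spec.upstream_reach, b2),
        exon_cons=cv(b2, b3),
        downstream_cons=cv(b3, b3 + sgn * spec.downstream_reach),
    )


def regions_from_windows(windows, cassette_len: int, spec: GrammarSpec) -> EventRegions:
    """Rebuild grammar regions from splice-site windows (tiny profile:
    requires cassette_len and the reaches to fit in a half-window)."""
    half = windows.width // 2
    if cassette_len > half or max(spec.upstream_reach, spec.downstream_reach) > half:
        raise ValueError("window too narrow to cover the grammar regions")
    acc, don = windows.seqs[1], windows.seqs[2]
    acc_cv, don_cv = windows.cons[1], windows.cons[2]
    return EventRegions(
        acceptor_site=acc[half - ACCEPTOR_INTRONIC: half + 3],
        donor_site=don[half - DONOR_EXONIC: half + 6],
        upstream_intron=acc[half - spec.upstream_reach: half],
        cassette_exon=acc[half: half + cassette_len],
        downstream_intron=don[half: half + spec.downstream_reach],
        upstream_cons=acc_cv[half - spec.upstream_reach: half],
        exon_cons=acc_cv[half: half + cassette_len],
        downstream_cons=don_cv[half: half + spec.downstream_reach],
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


@dataclass
class GrammarDataset:
    spec: GrammarSpec
    conditions: tuple[str, ...]
    genome: dict
    events: list[SpliceEvent]
    quantifications: pd.DataFrame  # event_id, condition, psi (noisy)
    truth: pd.DataFrame  # event_id, condition, true_psi
    placements: pd.DataFrame  # event_id, motif, chrom, start, end
    conservation: ConservationTrack
    rbp_expression: pd.DataFrame  # conditions x pseudo-RBPs

    def event(self, event_id: str) -> SpliceEvent:
        return next(e for e in self.events if e.event_id == event_id)

    def true_psi_of(self, event_id: str, condition: str) -> float:
        t = self.truth
        row = t[(t.event_id == event_id) & (t.condition == condition)]
        return float(row.true_psi.iloc[0])

    def write(self, out_dir: str) -> dict:
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        paths["genome"] = os.path.join(out_dir, "genome.fa")
        with open(paths["genome"], "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                s = self.genome[chrom]
                for i in range(0, len(s), 80):
                    fh.write(s[i:i + 80] + "\n")
        paths["events"] = os.path.join(out_dir, "events.tsv")
        rows = []
        for e in self.events:
            rows.append((e.event_id, e.chrom, e.strand, *e.ss, e.gene_id,
                         e.flank_exon_lens[0], e.flank_exon_lens[1]))
        pd.DataFrame(rows, columns=["event_id", "chrom", "strand", "ss1", "ss2",
                                    "ss3", "ss4", "gene_id", "e1_len", "e2_len"]
                     ).to_csv(paths["events"], sep="\t", index=False)
        paths["quant"] = os.path.join(out_dir, "quantifications.tsv")
        self.quantifications.to_csv(paths["quant"], sep="\t", index=False)
        paths["truth"] = os.path.join(out_dir, "truth.tsv")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["motifs"] = os.path.join(out_dir, "planted_motifs.bed")
        with open(paths["motifs"], "w") as fh:
            for r in self.placements.itertuples():
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.motif};{r.event_id}\n")
        paths["rbp"] = os.path.join(out_dir, "rbp_expression.tsv")
        self.rbp_expression.to_csv(paths["rbp"], sep="\t")
        return paths


def _sample_site(pwm: np.ndarray, core: tuple[int, ...], quality: float,
                 rng: np.random.Generator) -> str:
    """Sample a splice-site sequence; ``quality`` interpolates between
    PWM-random and pure consensus. Core (GT/AG) positions stay consensus."""
    out = []
    for i in range(pwm.shape[0]):
        if i in core or rng.random() < quality:
            out.append(BASES[int(np.argmax(pwm[i]))])
        else:
            out.append(BASES[int(rng.choice(4, p=pwm[i]))])
    return "".join(out)


def generate_dataset(
    spec: GrammarSpec,
    n_events: int,
    conditions: tuple[str, ...],
    seed: int,
    out_dir: str | None = None,
) -> GrammarDataset:
    """Generate a genome, events, quantifications, conservation and RBP
    expression from the grammar; byte-identical for a fixed seed."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_parts: dict[str, list[str]] = {f"chr{i+1}": [] for i in range(spec.n_chroms)}
    chrom_len: dict[str, int] = {c: 0 for c in chrom_parts}
    chrom_cons: dict[str, list[np.ndarray]] = {c: [] for c in chrom_parts}
    events: list[SpliceEvent] = []
    quant_rows, truth_rows, placement_rows = [], [], []

    for idx in range(n_events):
        eid = f"ev{idx:05d}"
        chrom = f"chr{idx % spec.n_chroms + 1}"
        f1 = int(rng.integers(*spec.flank_len_range))
        f2 = int(rng.integers(*spec.flank_len_range))
        i1 = int(rng.integers(*spec.intron_len_range))
        i2 = int(rng.integers(*spec.intron_len_range))
        L = int(rng.integers(*spec.cassette_len_range))
        total = f1 + i1 + L + i2 + f2
        locus = list(rng.choice(list(BASES), size=total))
        # transcript-orientation boundary offsets
        t1, t2 = f1, f1 + i1
        t3, t4 = f1 + i1 + L, f1 + i1 + L + i2
        # write splice sites; cassette-site quality drives baseline PSI spread
        q_cas = float(rng.beta(3.0, 1.2))
        q_flank = float(rng.beta(6.0, 1.0))

        def write(seq: str, start: int) -> None:
            locus[start:start + len(seq)] = list(seq)

        write(_sample_site(spec.donor_pwm, DONOR_CORE, q_flank, rng), t1 - DONOR_EXONIC)
        write(_sample_site(spec.acceptor_pwm, ACCEPTOR_CORE, q_cas, rng),
              t2 - ACCEPTOR_INTRONIC)
        write(_sample_site(spec.donor_pwm, DONOR_CORE, q_cas, rng), t3 - DONOR_EXONIC)
        write(_sample_site(spec.acceptor_pwm, ACCEPTOR_CORE, q_flank, rng),
              t4 - ACCEPTOR_INTRONIC)
        # plant motifs (and, for conservation-gated grammars, decoys)
        motif_spans: list[tuple[int, int, str]] = []
        decoy_spans: list[tuple[int, int]] = []

        def sample_start(m: Motif) -> int:
            lo, hi = m.window
            if m.region == "upstream_intron":
                return t2 - int(rng.integers(lo + len(m.seq), hi + 1))
            if m.region == "cassette_exon":
                return t2 + int(rng.integers(lo, min(hi, L - len(m.seq) + 1)))
            return t3 + int(rng.integers(lo, hi - len(m.seq) + 1))

        for m in spec.motifs:
            if rng.random() < spec.p_motif:
                start = sample_start(m)
                write(m.seq, start)
                motif_spans.append((start, start + len(m.seq), m.name))
            if spec.conservation_gated and rng.random() < spec.p_decoy:
                start = sample_start(m)
                # decoys must not overwrite a functional instance
                if not any(a < start + len(m.seq) and start < b for a, b, _ in motif_spans):
                    write(m.seq, start)
                    decoy_spans.append((start, start + len(m.seq)))
        locus_str = "".join(locus)
        # conservation in transcript orientation
        cons = rng.uniform(0.05, 0.30, size=total)
        for a, b in ((0, t1), (t2, t3), (t4, total)):  # exons
            cons[a:b] = rng.uniform(0.85, 0.98, size=b - a)
        for a, b, _ in motif_spans:
            cons[a:b] = rng.uniform(0.85, 0.98, size=b - a)
        for a, b in decoy_spans:  # decoys stay at background conservation
            cons[a:b] = rng.uniform(0.05, 0.30, size=b - a)
        # place on chromosome
        strand = "-" if rng.random() < spec.minus_strand_prob else "+"
        spacer = int(rng.integers(*spec.spacer_range))
        g0 = chrom_len[chrom] + spacer
        chrom_parts[chrom].append("".join(rng.choice(list(BASES), size=spacer)))
        chrom_cons[chrom].append(rng.uniform(0.05, 0.30, size=spacer))
        if strand == "+":
            chrom_parts[chrom].append(locus_str)
            chrom_cons[chrom].append(cons)
            ss = (g0 + t1, g0 + t2, g0 + t3, g0 + t4)
            spans = [(g0 + a, g0 + b, nm) for a, b, nm in motif_spans]
        else:
            chrom_parts[chrom].append(reverse_complement(locus_str))
            chrom_cons[chrom].append(cons[::-1])
            ss = (g0 + total - t1, g0 + total - t2, g0 + total - t3, g0 + total - t4)
            spans = [(g0 + total - b, g0 + total - a, nm) for a, b, nm in motif_spans]
        chrom_len[chrom] = g0 + total
        ev = SpliceEvent(event_id=eid, chrom=chrom, strand=strand, ss=ss,
                         gene_id=f"g_{eid}", flank_exon_lens=(f1, f2))
        events.append(ev)
        for a, b, nm in spans:
            placement_rows.append((eid, nm, chrom, a, b))
        # PSI per condition from the transcript-orientation regions
        regions = EventRegions(
            acceptor_site=locus_str[t2 - ACCEPTOR_INTRONIC: t2 + 3],
            donor_site=locus_str[t3 - DONOR_EXONIC: t3 + 6],
            upstream_intron=locus_str[t2 - spec.upstream_reach: t2],
            cassette_exon=locus_str[t2:t3],
            downstream_intron=locus_str[t3: t3 + spec.downstream_reach],
            upstream_cons=cons[t2 - spec.upstream_reach: t2],
            exon_cons=cons[t2:t3],
            downstream_cons=cons[t3: t3 + spec.downstream_reach],
        )
        for c in conditions:
            psi = true_psi(regions, c, spec)
            truth_rows.append((eid, c, psi))
            if spec.noise_sd > 0:
                a_, b_ = (0.0 - psi) / spec.noise_sd, (1.0 - psi) / spec.noise_sd
                noisy = float(truncnorm.rvs(a_, b_, loc=psi, scale=spec.noise_sd,
                                            random_state=rng))
            else:
                noisy = psi
            quant_rows.append((eid, c, noisy))

    genome = {c: "".join(parts) for c, parts in chrom_parts.items() if parts}
    cons_dense = {c: np.concatenate(v) for c, v in chrom_cons.items() if v}
    conservation = DenseConservation(cons_dense)
    # pseudo-RBP expression: conditions x (motif RBPs + housekeeping)
    cols, data = [], []
    for m in spec.motifs:
        cols.append(f"RBP_{m.name}")
    n_house = 4
    cols += [f"RBP_HK{i}" for i in range(n_house)]
    for c in conditions:
        row = [5.0 * 2.0 ** m.weight(c) + rng.normal(0, 0.05) for m in spec.motifs]
        row += [5.0 + rng.normal(0, 0.05) for _ in range(n_house)]
        data.append(row)
    rbp = pd.DataFrame(data, index=list(conditions), columns=cols).clip(lower=0.0)

    ds = GrammarDataset(
        spec=spec,
        conditions=tuple(conditions),
        genome=genome,
        events=events,
        quantifications=pd.DataFrame(quant_rows, columns=["event_id", "condition", "psi"]),
        truth=pd.DataFrame(truth_rows, columns=["event_id", "condition", "true_psi"]),
        placements=pd.DataFrame(placement_rows,
                                columns=["event_id", "motif", "chrom", "start", "end"]),
        conservation=conservation,
        rbp_expression=rbp,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds


class DenseConservation(ConservationTrack):
    """Conservation stored as one dense array per chromosome."""

    def __init__(self, arrays: dict):
        super().__init__()
        self._arrays = arrays

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._arrays:
            return out
        arr = self._arrays[chrom]
        lo, hi = max(0, start), min(len(arr), end)
        if hi > lo:
            out[lo - start: hi - start] = arr[lo:hi]
        return out


DESIGN_REGION_LEN = 100


def design_region(event: SpliceEvent, genome, length: int = DESIGN_REGION_LEN
                  ) -> tuple[str, int, int]:
    """The transcript-orientation design region: the cassette exon plus
    intronic flanks, standardized to ``length`` nt.

    Returns (sequence, acceptor_offset, donor_offset); the acceptor
    boundary sits at the left-flank size, so both cassette splice sites
    (and their PWM footprints) lie inside the region.
    """
    from .data_model import fetch_padded

    L = event.cassette_len
    if L + 30 > length:
        raise ValueError(f"cassette exon of {L} nt too long for a {length} nt region")
    a = (length - L) // 2
    if a < ACCEPTOR_INTRONIC + 1:
        raise ValueError("left flank too short for the acceptor site footprint")
    b2, b3 = event.ss[1], event.ss[2]
    rflank = length - L - a
    if event.strand == "+":
        seq = fetch_padded(genome, event.chrom, b2 - a, b3 + rflank)
    else:
        seq = reverse_complement(fetch_padded(genome, event.chrom, b3 - rflank, b2 + a))
    return seq, a, a + L


class GrammarDesignOracle:
    """Scores candidate design regions with the grammar's noiseless rule.

    A candidate replaces the event's design region inside its fixed
    genomic context, so grammar signal just outside the region (e.g. the
    deep intronic part of the motif windows) stays constant.
    """

    def __init__(self, event: SpliceEvent, genome, spec: GrammarSpec,
                 conditions: tuple[str, ...], length: int = DESIGN_REGION_LEN):
        from .data_model import fetch_padded

        self.spec = spec
        self.conditions = tuple(conditions)
        self.exon_len = event.cassette_len
        self.length = length
        _, self.acc_off, self.don_off = design_region(event, genome, length)
        self.start_sequence, _, _ = design_region(event, genome, length)
        # transcript-orientation context: upstream/downstream reaches beyond
        # the region are fixed
        U = max(spec.upstream_reach, self.acc_off)
        D = max(spec.downstream_reach, length - self.don_off)
        b2, b3 = event.ss[1], event.ss[2]
        if event.strand == "+":
            sup = fetch_padded(genome, event.chrom, b2 - U, b3 + D)
        else:
            sup = reverse_complement(fetch_padded(genome, event.chrom, b3 - D, b2 + U))
        self._sup, self._U = sup, U

    def regions_for(self, seq: str) -> EventRegions:
        if len(seq) != self.length:
            raise ValueError(f"candidate length {len(seq)} != region length {self.length}")
        U, L = self._U, self.exon_len
        lead = U - self.acc_off
        sup = self._sup[:lead] + seq + self._sup[lead + self.length:]
        return EventRegions(
            acceptor_site=sup[U - ACCEPTOR_INTRONIC: U + 3],
            donor_site=sup[U + L - DONOR_EXONIC: U + L + 6],
            upstream_intron=sup[U - self.spec.upstream_reach: U],
            cassette_exon=sup[U: U + L],
            downstream_intron=sup[U + L: U + L + self.spec.downstream_reach],
        )

    def __call__(self, seq: str) -> dict:
        regions = self.regions_for(seq)
        return {c: true_psi(regions, c, self.spec) for c in self.conditions}


def interpolated_condition(ds: GrammarDataset, name: str, c0: str, c1: str,
                           alpha: float, spec: GrammarSpec) -> GrammarSpec:
    """A new condition whose motif weights interpolate two existing ones
    (used to probe generalisation to unseen conditions)."""
    motifs = [replace(m, weights={**m.weights,
                                  name: (1 - alpha) * m.weight(c0) + alpha * m.weight(c1)})
              for m in spec.motifs]
    return replace(spec, motifs=motifs)
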
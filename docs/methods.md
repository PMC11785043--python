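# Methods

This note documents the models, the synthetic data generator, the
numerical choices, and the limits of what the shipped experiments show.

## Data model and coordinates

Coordinates are 0-based half-open internally; GTF input (1-based
inclusive) is converted at the boundary. Every splice site is stored as
its exon/intron *boundary coordinate* — the genomic position of the
first base to the right of the junction — so a window of width W around
boundary b is `genome[b − W/2, b + W/2)` and the junction always sits at
window offset W/2. Minus-strand windows are reverse-complemented, which
preserves the centring convention in transcript orientation. The four
sites are kept in role order (upstream-exon donor, cassette acceptor,
cassette donor, downstream-exon acceptor); the invariant is genomically
increasing order on `+` and decreasing on `−`.

The train/test split holds out whole chromosomes and then discards test
exons whose cassette sequence is too similar to any training exon
(k-mer Jaccard over 11-mers, default threshold 0.8). The similarity rule
is configurable because paralog filtering has no single canonical
definition; Jaccard over mid-sized k-mers catches both exact paralogs
and near-duplicates while ignoring chance k-mer sharing.

## Tokenizer and masked pre-training

Sequences are tokenized as overlapping 6-mers (L − 5 tokens for L
bases); any k-mer containing N maps to UNK, and detokenization verifies
overlap consistency so a token sequence that cannot come from a real
sequence is rejected rather than silently merged. For masked-LM
training, seed tokens are drawn per token as Bernoulli(0.15) and a span
of 3 neighbouring tokens on each side is masked along with each seed:
overlapping 6-mers share bases, so masking the seed alone would leak it
through its neighbours. The loss is computed at the seeds only. The span
is configurable (fully hiding a 6-mer's bases needs span 5); 3 per side
— six neighbours in total — is the default. Masked positions are always
replaced by MASK; the classic 80/10/10 replacement is available behind a
flag but off by default, since the loss is restricted to seeds anyway.

The encoder is a pre-LN transformer with learned absolute positions.
The published-scale profile is 6 layers, 12 heads, width 768, 110k steps
at batch 40, lr 4e-4 with 10k linear warm-up steps; the `tiny` profile
(2 layers, width 64) trains in seconds on a CPU and is what every
shipped experiment uses. 3' and 5' windows are mixed in one corpus with
no site-type token — the centring convention itself distinguishes them.

## The four-tower inclusion model

Each splice site has its own transformer tower (weights separate by
default, shareable by flag, and initialisable from the pre-trained
encoder). Tower inputs are `[CLS, cond_c, cond_c', five length-bin
tokens] + k-mer tokens`; exon and intron lengths use 32 log-spaced bins
over [10, 5·10^5] nt, clamped at the edges. Per-base conservation enters
as a per-token scalar channel (mean over the token's bases) projected
onto the embedding; exonic positions are pre-filled with the exon mean
because exon-body conservation mostly reflects coding constraint and
only its level, not its profile, is informative for splicing.

The tower readout concatenates the CLS vector, the mean-pooled hidden
states, and the hidden states at the five token positions that tile the
splice-site footprint (offsets −21…+3 from the centre). Because the
windows are splice-site-centred by construction, those positions are
fixed and carry the donor/acceptor signal directly; adding them removed
most of the error on site-strength-driven events in development. The
four readouts plus an 8-dim dense feature block feed an MLP
(published-scale widths 3080 and 768; tiny 128 and 64) with three
sigmoid heads.

Supervision uses the three-part target per ordered condition pair
(c, c′), c′ ≠ c: `t_psi = Ψ_c`, `t_dpsi+ = |max(ε, ΔΨ)|`,
`t_dpsi− = |min(−ε, ΔΨ)|`, with ε drawn fresh per example per epoch from
U(0.001, 0.002). The minus head clamps at −ε so an unchanged event still
supplies ε to both direction heads; a clamp at +ε would give the minus
head a zero target at ΔΨ = 0 and reintroduce the vanishing-gradient
problem the ε exists to avoid. A consequence of the clamps is that
`t_dpsi+ − t_dpsi−` recovers ΔΨ only up to ±ε, which is the tolerance
the tests use. The loss is soft binary cross-entropy (each target in
[0,1] treated as a Bernoulli mean); the PSI head is weighted 3× relative
to the direction heads in the tiny profile, which substantially
stabilised regression quality without hurting the classification heads.
Training uses Adam with 10% linear warm-up then linear decay; when a
validation set is supplied the best-validation epoch's weights are
restored.

Prediction for a single condition uses the t_psi head with the query
condition paired against another known condition — the pair (c, c) is
never trained, so feeding it at prediction time is out of distribution
and measurably worse. ΔΨ̂ is the difference of the two direction heads,
clamped to [−1, 1]; by construction it carries an O(ε) bias and is only
approximately antisymmetric in (c, c′). The self-pair (c, c) is answered
definitionally as zero rather than by extrapolating heads that never saw
such a pair.

Conditions are represented either as learned tokens or by the bottleneck
code of an RBP expression autoencoder (symmetric MLP on standardized
log1p expression; bottleneck 16 tiny / 64 full). The autoencoder path
exists to embed conditions never seen in training from their expression
vector alone.

## Synthetic grammar

The generator plants cassette-exon loci (flanking exons 40–70 nt,
introns 90–160 nt, cassette exon 28–44 nt at desk scale) on 10
chromosomes, both strands. Splice sites are sampled from donor (9-mer,
GT core) and acceptor (23-mer, AG core) PWMs with a per-event quality
parameter that interpolates toward consensus, giving a continuous range
of site strengths. Regulatory motifs (6-mers with per-condition weights,
a region, and a positional window anchored at the cassette splice sites)
are planted with probability 0.4 per motif per event. True inclusion is

    Ψ(e, c) = σ( β0 + β_ss · (s3 + s5) + Σ_m w_{m,c} · count_m(e) )

with s3, s5 the min–max normalised PWM log-odds of the cassette sites,
β0 = −8.5 and β_ss = 4 chosen once so the PSI distribution is broad with
both tails populated and roughly 40% of events change by ≥ 0.15 between
the two default conditions. Observed quantifications add truncated
normal noise (sd 0.02). Conservation is 0.85–0.98 over exons and planted
motifs and 0.05–0.30 elsewhere; each motif has a pseudo-RBP whose
expression increases with its condition weight. A conservation-gated
variant plants decoy motif instances at background conservation and
counts only conserved instances, making the conservation channel
informative rather than decorative — this is the grammar used for the
conservation-ablation check.

What the generator does **not** emulate: realistic intron length
distributions (real introns reach hundreds of kilobases), branch points
and polypyrimidine-tract variation beyond the acceptor PWM, cooperative
or positional-sign-switching RBP effects, splicing noise that correlates
with coverage, and overlapping/nested events. Passing the recovery tests
therefore shows the architecture and training loop can extract a
local-sequence splicing rule of realistic shape from realistic data
volumes — not that the shipped tiny model approaches published-scale
accuracy on real tissue data.

## Perturbation analyses

Splice-site strengthening writes the PWM consensus over the site
footprint; weakening replaces the invariant GT/AG dinucleotide by its
lowest-scoring alternative under the PWM. Random substitutions pick one
of the three alternative bases per position; a motif-avoidance option
rejects draws that create a grammar motif near the edited span. The
"no change" cutoff is the nearest-rank 95th percentile of |ΔΨ̂| under
random same-length substitutions (100 events × 5 mutations per offset).
Sliding-window scans mutate 6-nt windows 5 times each and rank offsets
by |mean ΔΨ̂|; for localizing *condition-specific* elements the scanned
quantity is the predicted ΔΨ between the condition pair, because core
splice-site damage moves both conditions together and cancels in the
difference, while condition-specific motifs do not.

## Sequence VAE

Single-nucleotide tokens; non-autoregressive decoding (per-position
argmax) so decodes always have the task's fixed length. The tiny profile
uses a block-factorized latent: the 100-nt design region is split into
ten 10-nt blocks, each encoded to a 6-dim code by a shared map that sees
the block's own one-hot content plus contextual pooled hidden state, and
decoded through a shared block-local head plus a transformer decoder for
context. Training mixes in block-recombination augmentation (half the
batch items have random blocks swapped in from other corpus sequences),
which forces content through the local codes: identical content then
gets near-identical codes in any block, so transplanting one block's
code edits roughly one block's worth of sequence. This locality is what
makes an edit budget meaningful in latent space — with a global
entangled code, any useful latent move resamples the entire sequence.
The ELBO uses β = 10⁻³ annealed from zero over the first tenth of
training; the posterior log-variance head is initialised at −4 so
reparameterization noise does not drown the code early.

## Design optimizer

The objective for tissue-differential design is scalarized as
y = Ψ_c − max_{c′} Ψ_{c′}; success is judged by the task's explicit rule
(target > 0.5, others < 0.2, edit distance ≤ τ, floor ≥ 0.05), never by
the scalarization. The surrogate is a Matérn 5/2 ARD GP with
standardized outputs; the edit distance and the non-target PSI floor are
modelled by their own GPs (feasible ≤ threshold), with hyperparameters
re-optimised every fifth iteration and reused in between. Proposals are
Thompson samples over ~500 candidates: trust-region perturbations of the
incumbent (length halves after 5 failures, doubles after 3 successes,
restarts on collapse) plus an exploration fraction that transplants 1–3
anchor block codes from training-corpus latents — the surrogates learn
from those excursions where high-objective sequence modes live, and the
feasibility rule decides what actually gets evaluated. Latents that
decode to an already-scored sequence reuse the cached oracle values
without spending budget (the oracle is deterministic within a run), and
at most one duplicate latent per sequence enters the GP data. Returned
candidates are hard-filtered: nothing violating the edit budget or the
floor is ever success-flagged. The VAE is not retrained during
optimisation.

Baselines share the oracle-call accounting exactly: random mutation
substitutes one random 3/6/15/30-mer of the start per call; the GA uses
population 50, tournament k = 3, single-point crossover, per-base
mutation 0.01, and repairs offspring over the edit budget by reverting
random edits.

## Evaluation conventions

`a` (approximate accuracy) uses strict inequality |pred − truth| < 0.2.
dPSI classification labels events at ±0.15; AUPRC is step-wise
(`average_precision_score`, no interpolation) and AUROC the rank
statistic. Single-class directions are reported as missing with a
diagnostic rather than silently skipped. Design runs are summarised by
the success fraction and the top-20% candidates by objective value.

## Problem sizes and numerical notes

All shipped experiments use the desk-scale profile: 96-nt windows,
1-layer width-32 towers, 2000 events across 10 chromosomes with 2
conditions (two chromosomes held out for testing and one training
chromosome used for validation-based epoch selection), 500-step
pre-training runs, a 2500-step VAE, and 500-oracle-call design runs —
sizes chosen so the full pipeline, repeated over seeds, runs in minutes
per component on a single CPU core. Floating point is float32
throughout the NumPy engine (gradient checks run in float64 and agree
with finite differences to ~10⁻⁸ relative); Adam clips per-parameter
gradients at ±10; attention masking uses additive −10⁹ before softmax,
which underflows to exact zeros in float32 so padded positions cannot
leak. Degenerate (flat) PWMs score 0.5 by convention. Nearest-rank
percentile is the ⌈p·n⌉-th order statistic.

## Known limitations

The tiny models recover a synthetic rule; no claim is made about real
GTEx/ENCODE-scale accuracy. The VAE's block locality is an architectural
commitment — for design regions much longer than 100 nt, or for tasks
needing insertions/deletions, the fixed-length block layout would need
rethinking (edit distance is still computed properly, but decodes are
substitution-only relative to the block grid). The optimizer's anchor
exploration assumes the training corpus contains sequence features
relevant to the objective; on a task whose solution lies outside the
corpus manifold it degrades to trust-region search. The predicted ΔΨ̂
carries an O(ε) bias from the target clamps, and (c, c) self-pairs are
extrapolation, not trained behaviour.
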
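# splicecode

Tissue-specific splicing-code modelling and edit-budgeted RNA sequence
design for cassette exons.

## The problem

A cassette exon is included in the mature transcript at a rate Ψ ∈ [0,1]
("percent spliced in") that varies between tissues or cell conditions;
the change between two conditions c, c′ is ΔΨ = Ψ<sub>c</sub> −
Ψ<sub>c′</sub> ∈ [−1,1]. Inclusion is controlled by the strength of the
four splice sites flanking the event and by RNA-binding-protein (RBP)
motifs in the alternative exon and nearby introns. This package is for
researchers who want to (a) predict Ψ and ΔΨ from genomic sequence per
condition, (b) locate the regulatory elements responsible, and (c)
*design* minimally edited sequence variants that shift inclusion toward
a target profile — e.g. high inclusion in one tissue, low in the others
— under an edit budget.

## The models

**Four-tower inclusion model.** Each of the four splice sites (upstream
exon donor, cassette acceptor, cassette donor, downstream exon acceptor)
gets its own transformer tower over a 400-nt window centred on the
splice-site boundary, tokenized as overlapping 6-mers. Towers can be
initialised from a BERT-style encoder pre-trained on splice-site windows
with span masking (15% seed tokens, plus the surrounding tokens that
share bases with each seed; loss at the seeds only). Event features —
binned exon/intron lengths, condition identity, per-base conservation
(exonic positions replaced by the exon mean) — enter both as prefix
tokens and as a dense block. The four readouts plus features feed a
two-hidden-layer MLP with three sigmoid heads trained by soft binary
cross-entropy on the targets

    t_psi   = E[Ψ_{e,c}]
    t_dpsi+ = |max(ε, E[ΔΨ_{e,c,c′}])|
    t_dpsi- = |min(−ε, E[ΔΨ_{e,c,c′}])|,   ε ~ U(0.001, 0.002)

so unchanging events still supply a small non-zero signal to the
direction heads. Conditions can alternatively be embedded through an RBP
expression autoencoder, which lets the model generalise to conditions it
never trained on.

**Design loop.** Sequence design is cast as constrained black-box
optimisation: maximise (or redistribute) Ψ(S̃) subject to a Levenshtein
budget lev(S̃, S) ≤ τ and a PSI floor on non-target conditions. A
transformer VAE over fixed-length sequences provides a continuous latent
space; a Gaussian-process surrogate (Matérn 5/2, ARD) with a trust
region and an SCBO-style feasibility rule proposes latent candidates by
Thompson sampling, decodes them, and scores them with the inclusion
oracle. Random-mutation and genetic-algorithm baselines run under the
same oracle-call accounting.

**Synthetic grammar.** A fully specified generative rule — PWM-scored
splice sites plus condition-weighted regulatory motifs on the log-odds
scale of a logistic link — generates genomes, quantifications,
conservation tracks and RBP expression with exact ground truth, and
doubles as a noiseless oracle for perturbation and design experiments.

## Worked example

```python
import numpy as np
from splicecode import (default_spec, generate_dataset, Vocabulary,
                        InclusionConfig, InclusionModel, extract_windows,
                        split_train_test, pearson_r, approx_accuracy)
from splicecode.inclusion_model import build_examples, featurize, finetune, predict_batch

conds = ("liverlike", "cerebellumlike")
ds = generate_dataset(default_spec(conds), 2000, conds, seed=11)
split = split_train_test(ds.events, ds.genome, ["chr9", "chr10"])
windows = {e.event_id: extract_windows(e, ds.genome, ds.conservation, width=96)
           for e in ds.events}
vocab = Vocabulary(k=6, conditions=conds)
train = [e for e in ds.events if e.event_id in set(split.train_ids)]
test = [e for e in ds.events if e.event_id in set(split.test_ids)]

model = InclusionModel(InclusionConfig.tiny(), vocab, np.random.default_rng(0))
finetune(model, build_examples(train, windows, ds.quantifications, vocab),
         np.random.default_rng(0))

truth = ds.truth.set_index(["event_id", "condition"]).true_psi
feats = [featurize(e, windows[e.event_id], vocab, c, cp)
         for e in test for c, cp in (("liverlike", "cerebellumlike"),
                                     ("cerebellumlike", "liverlike"))]
t = np.array([truth[(e.event_id, c)] for e in test
              for c in ("liverlike", "cerebellumlike")])
p = predict_batch(model, feats)[:, 0]
print(f"held-out r = {pearson_r(p, t):.3f}, a(0.2) = {approx_accuracy(p, t):.3f}")
```

On this desk-scale dataset the run prints

```
held-out r = 0.912, a(0.2) = 0.891
```

`r` is the Pearson correlation between predicted and true inclusion on
events from held-out chromosomes, and `a(0.2)` is the fraction of
predictions within 0.2 of the truth; both are computed against the
grammar's noiseless Ψ, so they measure how much of the generative rule
the model recovered.

The same pipeline is scriptable from the shell:

```bash
splicecode simulate --n 2000 --seed 7 --out sim/
splicecode train --genome sim/genome.fa --events sim/events.tsv \
    --quant sim/quantifications.tsv --out model/
splicecode predict --model model/ --genome sim/genome.fa \
    --events sim/events.tsv --conditions liverlike,cerebellumlike --out pred.tsv
```

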
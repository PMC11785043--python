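"""The generative splicing grammar and its noiseless oracle."""

from dataclasses import replace

import numpy as np
import pytest

from splicecode import GrammarSpec, Motif, default_spec, generate_dataset, true_psi
from splicecode.data_model import extract_windows
from splicecode.synthetic_grammar import (DONOR_CORE, EventRegions,
                                          GrammarDesignOracle, _pwm, design_region,
                                          normalized_score, pwm_log_odds,
                                          regions_from_genome, regions_from_windows)

CONDS = ("liverlike", "cerebellumlike")


def test_deterministic_given_seed(grammar_spec):
    a = generate_dataset(grammar_spec, 30, CONDS, seed=5)
    b = generate_dataset(grammar_spec, 30, CONDS, seed=5)
    assert a.genome == b.genome
    assert a.quantifications.equals(b.quantifications)
    assert a.placements.equals(b.placements)
    c = generate_dataset(grammar_spec, 30, CONDS, seed=6)
    assert c.genome != a.genome


def test_zero_motifs_flat_pwms_degenerate(grammar_spec):
    flat = np.full((9, 4), 0.25)
    flat_a = np.full((23, 4), 0.25)
    spec = replace(grammar_spec, motifs=[], donor_pwm=flat, acceptor_pwm=flat_a,
                   noise_sd=0.0)
    ds = generate_dataset(spec, 20, CONDS, seed=1)
    vals = ds.truth.true_psi.to_numpy()
    expected = 1.0 / (1.0 + np.exp(-(spec.beta0 + spec.beta_ss * 1.0)))
    assert np.allclose(vals, expected)


def test_condition_specific_motif_raises_psi(grammar_spec):
    m = Motif("X", "TGCATG", {"cerebellumlike": 2.0, "liverlike": 0.0},
              "downstream_intron", (6, 40))
    spec = replace(grammar_spec, motifs=[m], p_motif=0.5, noise_sd=0.0)
    ds = generate_dataset(spec, 120, CONDS, seed=2)
    placed = set(ds.placements.event_id)
    piv = ds.truth.pivot(index="event_id", columns="condition", values="true_psi")
    with_m = piv.loc[sorted(placed & set(piv.index))]
    without = piv.loc[sorted(set(piv.index) - placed)]
    # every placed event gains log-odds 2.0 in cerebellum only
    d = with_m.cerebellumlike - with_m.liverlike
    assert (d > 0).all()
    # unplaced events differ only through rare accidental motif matches
    same = np.isclose(without.cerebellumlike, without.liverlike)
    assert same.mean() >= 0.9


def test_one_motif_instance_multiplies_odds_by_e_to_w(grammar_spec):
    spec = replace(grammar_spec,
                   motifs=[Motif("X", "GAAGAA", {"liverlike": 1.0}, "cassette_exon",
                                 (4, 22))])
    base = "A" * 48
    exon = "C" * 36
    reg0 = EventRegions("T" * 20 + "AG" + "C", "CAGGTAAGT", base, exon, "A" * 48)
    exon1 = exon[:6] + "GAAGAA" + exon[12:]
    reg1 = EventRegions(reg0.acceptor_site, reg0.donor_site, base, exon1, "A" * 48)
    p0 = true_psi(reg0, "liverlike", spec)
    p1 = true_psi(reg1, "liverlike", spec)
    odds = lambda p: p / (1 - p)
    assert odds(p1) / odds(p0) == pytest.approx(np.e, rel=1e-6)


def test_weakening_gt_strictly_reduces_psi(grammar_spec):
    reg = EventRegions("T" * 20 + "AGC"[:3], "CAGGTAAGT", "A" * 48, "C" * 36, "A" * 48)
    weak = EventRegions(reg.acceptor_site, "CAGCTAAGT", reg.upstream_intron,
                        reg.cassette_exon, reg.downstream_intron)
    for c in CONDS:
        assert true_psi(weak, c, grammar_spec) < true_psi(reg, c, grammar_spec)


def test_oracle_monotone_in_motif_count(grammar_spec):
    m = Motif("X", "TGCATG", {"liverlike": 1.5}, "downstream_intron", (6, 40))
    spec = replace(grammar_spec, motifs=[m])
    down0 = "A" * 48
    down1 = "A" * 8 + "TGCATG" + "A" * 34
    down2 = "A" * 8 + "TGCATG" + "A" * 4 + "TGCATG" + "A" * 24
    vals = []
    for down in (down0, down1, down2):
        reg = EventRegions("T" * 20 + "AGC", "CAGGTAAGT", "A" * 48, "C" * 36, down)
        vals.append(true_psi(reg, "liverlike", spec))
    assert vals[0] < vals[1] < vals[2]


def test_conservation_profile(small_dataset):
    ds = small_dataset
    placed = set(ds.placements.event_id)
    ev = next(e for e in ds.events if e.event_id not in placed)
    w = extract_windows(ev, ds.genome, ds.conservation, width=96)
    half = 48
    exon_len = min(ev.cassette_len, half)
    exon_cons = w.cons[1][half:half + exon_len]
    assert exon_cons.min() >= 0.8
    intron = w.cons[1][half - 40: half - 20]  # upstream intron background
    assert intron.mean() <= 0.35


def test_truth_consistent_through_genome_and_windows(small_dataset, grammar_spec):
    ds = small_dataset
    for ev in ds.events[:10]:
        rg = regions_from_genome(ev, ds.genome, grammar_spec, ds.conservation)
        w = extract_windows(ev, ds.genome, ds.conservation, width=96)
        rw = regions_from_windows(w, ev.cassette_len, grammar_spec)
        for c in CONDS:
            ref = ds.true_psi_of(ev.event_id, c)
            assert true_psi(rg, c, grammar_spec) == pytest.approx(ref, abs=1e-12)
            assert true_psi(rw, c, grammar_spec) == pytest.approx(ref, abs=1e-12)


def test_files_round_trip_through_loaders(tmp_path, small_dataset):
    from splicecode import load_events, open_genome

    paths = small_dataset.write(str(tmp_path))
    genome = open_genome(paths["genome"])
    res = load_events(paths["events"], paths["quant"], genome=genome)
    assert len(res.events) == len(small_dataset.events)
    assert not res.errors
    ev = res.events[0]
    ref = small_dataset.event(ev.event_id)
    assert ev.ss == ref.ss and ev.strand == ref.strand


def test_rbp_expression_tracks_motif_weights(small_dataset, grammar_spec):
    expr = small_dataset.rbp_expression
    for m in grammar_spec.motifs:
        col = f"RBP_{m.name}"
        for c in CONDS:
            for c2 in CONDS:
                if m.weight(c) > m.weight(c2):
                    assert expr.loc[c, col] > expr.loc[c2, col]


def test_design_region_contains_both_sites(small_dataset):
    ds = small_dataset
    for ev in ds.events[:8]:
        seq, acc, don = design_region(ev, ds.genome)
        assert len(seq) == 100
        assert don - acc == ev.cassette_len
        # acceptor AG just upstream of the boundary, donor GT at the boundary
        assert seq[acc - 2:acc] == "AG"
        assert seq[don:don + 2] == "GT"


def test_design_oracle_matches_truth_and_rejects_bad_length(small_dataset, grammar_spec):
    ds = small_dataset
    ev = ds.events[0]
    orc = GrammarDesignOracle(ev, ds.genome, grammar_spec, CONDS)
    vals = orc(orc.start_sequence)
    for c in CONDS:
        assert vals[c] == pytest.approx(ds.true_psi_of(ev.event_id, c), abs=1e-12)
    with pytest.raises(ValueError):
        orc("ACGT")


def test_motif_window_validation():
    with pytest.raises(ValueError, match="window"):
        GrammarSpec(motifs=[Motif("bad", "TGCATG", {"x": 1.0},
                                  "downstream_intron", (6, 500))])


def test_pwm_scores():
    pwm = _pwm("CAGGTAAGT", DONOR_CORE)
    assert normalized_score("CAGGTAAGT", pwm) == pytest.approx(1.0)
    assert pwm_log_odds("CAGGTAAGT", pwm) > pwm_log_odds("CAGCTAAGT", pwm)
    with pytest.raises(ValueError):
        pwm_log_odds("CAG", pwm)
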
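"""In-silico mutagenesis: mutation ops, null threshold, sliding scans."""

import numpy as np
import pytest

from splicecode import (MutationSpec, NullThreshold, call_effect, compute_null_threshold,
                        mutate, perturb_splice_site, sliding_window_scan, true_psi)
from splicecode.data_model import EventWindows, extract_windows
from splicecode.perturbation import nearest_rank_percentile, top_scan_offsets
from splicecode.synthetic_grammar import regions_from_windows

CONDS = ("liverlike", "cerebellumlike")


def _windows(seed=0, width=96):
    rng = np.random.default_rng(seed)
    seqs = tuple("".join(rng.choice(list("ACGT"), size=width)) for _ in range(4))
    return EventWindows(seqs, tuple(np.zeros(width) for _ in range(4)), width)


def _grammar_oracle(ds, spec, condition="liverlike"):
    def oracle(w, _cl=[None]):
        return true_psi(regions_from_windows(w, oracle.cassette_len, spec),
                        condition, spec)
    return oracle


class TestMutate:
    def test_exact_span_replaced(self):
        w = _windows()
        m = mutate(w, MutationSpec(0, 20, "CCA"))
        diff = [i for i, (a, b) in enumerate(zip(w.seqs[0], m.seqs[0])) if a != b]
        assert set(diff) <= {20, 21, 22}
        assert all(m.seqs[i] == w.seqs[i] for i in range(1, 4))

    def test_identity_replacement(self):
        w = _windows()
        m = mutate(w, MutationSpec(1, 10, w.seqs[1][10:13]))
        assert m.seqs[1] == w.seqs[1]

    def test_out_of_bounds_span(self):
        w = _windows()
        with pytest.raises(ValueError):
            mutate(w, MutationSpec(0, 95, "ACGT"))


class TestSpliceSitePerturbation:
    def test_weaken_breaks_gt(self, small_dataset, grammar_spec):
        ds = small_dataset
        ev = ds.events[0]
        w = extract_windows(ev, ds.genome, width=96)
        assert w.seqs[2][48:50] == "GT"
        weak = perturb_splice_site(w, "weaken", grammar_spec.donor_pwm, "donor")
        assert weak.seqs[2][48:50] != "GT"

    def test_strengthen_consensus_is_identity(self, grammar_spec):
        w = _windows()
        s1 = perturb_splice_site(w, "strengthen", grammar_spec.donor_pwm, "donor")
        s2 = perturb_splice_site(s1, "strengthen", grammar_spec.donor_pwm, "donor")
        assert s1.seqs[2] == s2.seqs[2]

    def test_direction_matches_grammar_oracle(self, small_dataset, grammar_spec):
        """Weakening decreases and strengthening does not decrease the
        grammar's true inclusion, event by event."""
        ds = small_dataset
        for ev in ds.events[:20]:
            w = extract_windows(ev, ds.genome, ds.conservation, width=96)
            def psi(win):
                return true_psi(regions_from_windows(win, ev.cassette_len,
                                                     grammar_spec),
                                "liverlike", grammar_spec)
            base = psi(w)
            weak = perturb_splice_site(w, "weaken", grammar_spec.donor_pwm, "donor")
            strong = perturb_splice_site(w, "strengthen", grammar_spec.donor_pwm,
                                         "donor")
            assert psi(weak) < base
            assert psi(strong) >= base

    def test_bad_pwm_length(self):
        with pytest.raises(ValueError):
            perturb_splice_site(_windows(), "strengthen", np.full((5, 4), 0.25),
                                "donor")
        with pytest.raises(ValueError):
            perturb_splice_site(_windows(), "sideways", np.full((9, 4), 0.25))


class TestNullThreshold:
    def test_nearest_rank_oracle(self):
        vals = [0.01 * i for i in range(1, 101)]
        assert nearest_rank_percentile(vals, 0.95) == pytest.approx(0.95)
        assert nearest_rank_percentile([3.0], 0.95) == 3.0

    def test_constant_oracle_gives_zero(self):
        ws = [_windows(i) for i in range(5)]
        null = compute_null_threshold(lambda w: 0.42, ws, [(0, 10)],
                                      n_events=5, n_mutations=2, seed=0)
        assert null.threshold == 0.0

    def test_reproducible_under_seed(self, small_dataset, grammar_spec):
        ds = small_dataset
        evs = ds.events[:10]
        ws = [extract_windows(e, ds.genome, width=96) for e in evs]
        lens = {w: e.cassette_len for w, e in zip(range(len(ws)), evs)}

        def oracle(win):
            # approximate: use the first event's exon length for region carving
            return true_psi(regions_from_windows(win, evs[0].cassette_len,
                                                 grammar_spec),
                            "liverlike", grammar_spec)

        a = compute_null_threshold(oracle, ws, [(1, 20), (2, 60)],
                                   n_events=5, n_mutations=3, seed=9)
        b = compute_null_threshold(oracle, ws, [(1, 20), (2, 60)],
                                   n_events=5, n_mutations=3, seed=9)
        assert a.threshold == b.threshold
        assert a.threshold >= 0

    def test_monotone_in_added_effects(self):
        vals = list(np.linspace(0, 0.5, 60))
        t1 = nearest_rank_percentile(vals, 0.95)
        t2 = nearest_rank_percentile(vals + [0.9, 0.95, 1.0], 0.95)
        assert t2 >= t1

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_null_threshold(lambda w: 0, [], [(0, 1)])


class TestCallEffect:
    def test_partition_rule(self):
        null = NullThreshold(threshold=0.019)
        assert call_effect(0.05, null) == "increase"
        assert call_effect(0.01, null) == "no_change"
        assert call_effect(-0.3, null) == "decrease"
        assert call_effect(-0.018, null) == "no_change"

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            NullThreshold(threshold=-0.1)


class TestSlidingScan:
    def test_zero_reps_error(self):
        with pytest.raises(ValueError):
            sliding_window_scan(lambda w: 0.5, _windows(), 0, reps=0)

    def test_identical_seed_identical_profile(self):
        oracle = lambda w: w.seqs[0].count("A") / 96
        a = sliding_window_scan(oracle, _windows(), 0, reps=3, seed=4)
        b = sliding_window_scan(oracle, _windows(), 0, reps=3, seed=4)
        assert a.equals(b)

    def test_grammar_scan_localizes_planted_motif(self, grammar_spec):
        """Scanning the grammar oracle itself peaks on a planted motif."""
        from dataclasses import replace
        from splicecode.synthetic_grammar import EventRegions

        spec = replace(grammar_spec, motifs=[m for m in grammar_spec.motifs
                                             if m.name == "NEUR_ENH"])
        rng = np.random.default_rng(5)
        width = 96
        half = width // 2
        exon_len = 36
        don = "".join(rng.choice(list("ACGT"), size=width))
        don = don[:half - 3] + "CAGGTAAGT" + don[half + 6:]
        motif_at = half + 12
        don = don[:motif_at] + "TGCATG" + don[motif_at + 6:]
        acc = "".join(rng.choice(list("ACGT"), size=width))
        acc = acc[:half - 20] + "TTTTTTTTTTCTTTTCCTAG" + acc[half:]
        w = EventWindows((acc, acc, don, don), tuple(np.zeros(width) for _ in range(4)),
                         width)

        def dpsi(win):
            # differential oracle: core-site effects cancel between the two
            # conditions, condition-specific motifs do not
            reg = regions_from_windows(win, exon_len, spec)
            return (true_psi(reg, "cerebellumlike", spec)
                    - true_psi(reg, "liverlike", spec))

        scan = sliding_window_scan(dpsi, w, 2, window_len=6, reps=5, seed=0)
        top = top_scan_offsets(scan, n=5)
        assert any(abs(int(o) - motif_at) < 6 for o in top.offset)
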
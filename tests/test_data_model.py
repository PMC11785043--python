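"""Event structures, loaders, window extraction, train/test split."""

import numpy as np
import pytest

from splicecode import (ConservationTrack, SpliceEvent, extract_windows, load_events,
                        split_train_test)
from splicecode.data_model import cassette_sequence, kmer_jaccard
from splicecode.tokenizer import reverse_complement


def _toy_genome(n=4000, seed=0):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=n)),
            "chr8": "".join(rng.choice(list("ACGT"), size=n))}


class TestSpliceEvent:
    def test_plus_strand_requires_increasing_sites(self):
        with pytest.raises(ValueError, match="ev1"):
            SpliceEvent("ev1", "chr1", "+", (100, 300, 200, 400))

    def test_minus_strand_requires_decreasing_sites(self):
        SpliceEvent("ev1", "chr1", "-", (400, 300, 200, 100))  # valid
        with pytest.raises(ValueError):
            SpliceEvent("ev1", "chr1", "-", (100, 200, 300, 400))

    def test_lengths(self):
        ev = SpliceEvent("e", "chr1", "+", (100, 200, 240, 340))
        assert ev.cassette_len == 40
        assert ev.intron_lens == (100, 100)


class TestLoaders:
    def _write(self, tmp_path, events_rows, quant_rows):
        ep = tmp_path / "events.tsv"
        qp = tmp_path / "quant.tsv"
        ep.write_text("event_id\tchrom\tstrand\tss1\tss2\tss3\tss4\n"
                      + "".join("\t".join(map(str, r)) + "\n" for r in events_rows))
        qp.write_text("event_id\tcondition\tpsi\n"
                      + "".join("\t".join(map(str, r)) + "\n" for r in quant_rows))
        return str(ep), str(qp)

    def test_toy_load_counts(self, tmp_path):
        ep, qp = self._write(
            tmp_path,
            [("e1", "chr1", "+", 100, 200, 240, 340),
             ("e2", "chr1", "+", 500, 600, 640, 740),
             ("e3", "chr1", "-", 1300, 1240, 1200, 1100)],
            [(e, c, 0.5) for e in ("e1", "e2", "e3") for c in ("liver", "brain")])
        res = load_events(ep, qp)
        assert len(res.events) == 3
        assert len(res.quantifications) == 6
        assert not res.errors

    def test_out_of_range_psi_rejected_with_diagnostic(self, tmp_path):
        ep, qp = self._write(
            tmp_path,
            [("e1", "chr1", "+", 100, 200, 240, 340)],
            [("e1", "liver", 1.3), ("e1", "brain", 0.4)])
        res = load_events(ep, qp)
        assert len(res.quantifications) == 1
        assert any("e1" in err and "1.3" in err for err in res.errors)
        assert any("line 2" in err for err in res.errors)

    def test_bad_geometry_raises_naming_event(self, tmp_path):
        ep, qp = self._write(
            tmp_path,
            [("bad_ev", "chr1", "+", 100, 240, 200, 340)],
            [("bad_ev", "liver", 0.5)])
        with pytest.raises(ValueError, match="bad_ev"):
            load_events(ep, qp)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_events(str(tmp_path / "nope.tsv"), str(tmp_path / "nope2.tsv"))

    def test_gtf_three_exon_transcripts(self, tmp_path):
        gtf = tmp_path / "toy.gtf"
        rows = []
        for i, start in enumerate((101, 1001, 2001)):
            tid, gid = f"tx{i}", f"g{i}"
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            rows.append(("chr1", "src", "transcript", start, start + 500, ".", "+", ".", attrs))
            for es, ee in ((start, start + 50), (start + 150, start + 190),
                           (start + 300, start + 360)):
                rows.append(("chr1", "src", "exon", es, ee, ".", "+", ".", attrs))
        gtf.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        qp = tmp_path / "q.tsv"
        qp.write_text("event_id\tcondition\tpsi\n"
                      + "".join(f"tx{i}\tliver\t0.5\n" for i in range(3)))
        res = load_events(str(gtf), str(qp))
        assert len(res.events) == 3
        ev = res.events[0]
        # GTF is 1-based inclusive: exon [101,151] -> donor boundary at 151
        assert ev.ss == (151, 250, 291, 400)
        assert ev.flank_exon_lens == (51, 61)


class TestExtractWindows:
    def test_center_boundary_coordinates(self):
        genome = _toy_genome()
        ev = SpliceEvent("e", "chr1", "+", (1000, 1200, 1240, 1400))
        w = extract_windows(ev, genome, width=400)
        assert w.seqs[0] == genome["chr1"][800:1200]
        assert w.seqs[0][200] == genome["chr1"][1000]

    def test_minus_strand_is_reverse_complement(self):
        genome = _toy_genome()
        plus = SpliceEvent("p", "chr1", "+", (1000, 1200, 1240, 1400))
        minus = SpliceEvent("m", "chr1", "-", (1400, 1240, 1200, 1000))
        wp = extract_windows(plus, genome, width=200)
        wm = extract_windows(minus, genome, width=200)
        # tower 0 of the minus event is centred on the same boundary as
        # tower 3 of the plus event, reverse-complemented
        assert wm.seqs[0] == reverse_complement(wp.seqs[3])

    def test_out_of_chromosome_padding(self):
        genome = _toy_genome()
        ev = SpliceEvent("e", "chr1", "+", (50, 300, 340, 500))
        w = extract_windows(ev, genome, width=400)
        assert w.seqs[0][:150] == "N" * 150
        assert (w.cons[0][:150] == 0).all()
        assert w.seqs[0][150:] == genome["chr1"][0:250]

    def test_odd_width_rejected(self):
        ev = SpliceEvent("e", "chr1", "+", (1000, 1200, 1240, 1400))
        with pytest.raises(ValueError):
            extract_windows(ev, _toy_genome(), width=401)

    def test_unknown_chromosome(self):
        ev = SpliceEvent("e", "chrX", "+", (1000, 1200, 1240, 1400))
        with pytest.raises(KeyError):
            extract_windows(ev, _toy_genome(), width=100)

    def test_conservation_track_values(self):
        genome = _toy_genome()
        track = ConservationTrack({"chr1": (np.arange(900, 1100),
                                            np.full(200, 0.7))})
        ev = SpliceEvent("e", "chr1", "+", (1000, 1200, 1240, 1400))
        w = extract_windows(ev, genome, track, width=400)
        assert (w.cons[0][100:300] == 0.7).all()
        assert (w.cons[0][:100] == 0.0).all()


class TestConservationIO:
    def test_fixed_step_wig(self, tmp_path):
        p = tmp_path / "c.wig"
        p.write_text("fixedStep chrom=chr1 start=11 step=1\n0.5\n0.6\n0.7\n")
        t = ConservationTrack.from_wig(str(p))
        # wig is 1-based: value 0.5 sits at 0-based position 10
        assert np.allclose(t.values("chr1", 10, 13), [0.5, 0.6, 0.7])
        assert t.values("chr1", 0, 2).tolist() == [0.0, 0.0]

    def test_tsv_track(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("chr1\t5\t0.9\nchr1\t7\t0.2\n")
        t = ConservationTrack.from_tsv(str(p))
        assert np.allclose(t.values("chr1", 5, 8), [0.9, 0.0, 0.2])


class TestSplit:
    def _events(self, genome):
        evs = []
        for i, chrom in enumerate(["chr1"] * 3 + ["chr8"] * 2):
            base = 500 + 700 * (i % 3)
            evs.append(SpliceEvent(f"e{i}", chrom, "+",
                                   (base, base + 100, base + 140, base + 240)))
        return evs

    def test_held_out_chromosome_split(self, small_dataset):
        ds = small_dataset
        split = split_train_test(ds.events, ds.genome, ["chr9", "chr10"])
        held = {"chr9", "chr10"}
        for e in ds.events:
            if e.event_id in set(split.test_ids):
                assert e.chrom in held
            if e.event_id in set(split.train_ids):
                assert e.chrom not in held
        assert not set(split.train_ids) & set(split.test_ids)

    def test_identical_exon_discarded(self):
        genome = _toy_genome()
        evs = self._events(genome)
        # copy chr1 cassette exon sequence onto the chr8 event's exon interval
        g = dict(genome)
        src = cassette_sequence(evs[0], g)
        lo, hi = evs[3].cassette_interval()
        g["chr8"] = g["chr8"][:lo] + src + g["chr8"][hi:]
        split = split_train_test(evs, g, ["chr8"], similarity_threshold=0.8)
        assert evs[3].event_id in split.discarded_test_ids
        assert evs[4].event_id in split.test_ids

    def test_order_invariance(self, small_dataset):
        ds = small_dataset
        a = split_train_test(ds.events, ds.genome, ["chr9"])
        b = split_train_test(list(reversed(ds.events)), ds.genome, ["chr9"])
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_empty_held_out_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            split_train_test(small_dataset.events, small_dataset.genome, [])

    def test_jaccard_extremes(self):
        assert kmer_jaccard("A" * 30, "A" * 30, k=11) == 1.0
        assert kmer_jaccard("A" * 30, "C" * 30, k=11) == 0.0
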
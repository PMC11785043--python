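"""Supervision targets, four-tower model contracts, RBP-AE.

Parameter-recovery quality on the grammar is measured in the acceptance
suite with a trained model; these tests cover the exact target algebra
and the model's structural contracts at initialisation.
"""

import numpy as np
import pytest

from splicecode import (RbpAutoencoder, SupervisionTarget, InclusionConfig, InclusionModel,
                        Vocabulary, featurize, finetune, target_transform, train_rbp_ae)
from splicecode.data_model import EventWindows, SpliceEvent
from splicecode.inclusion_model import TrainExample, length_bin
import pandas as pd

CONDS = ("liverlike", "cerebellumlike")
VOCAB = Vocabulary(k=6, conditions=CONDS)


def _event():
    return SpliceEvent("e", "chr1", "+", (1000, 1200, 1236, 1400),
                       flank_exon_lens=(60, 70))


def _windows(seed=0, width=64):
    rng = np.random.default_rng(seed)
    seqs = tuple("".join(rng.choice(list("ACGT"), size=width)) for _ in range(4))
    cons = tuple(rng.random(width) for _ in range(4))
    return EventWindows(seqs, cons, width)


def _tiny_model(**kw):
    cfg = InclusionConfig.tiny(**kw)
    cfg.encoder.max_tokens = 80
    return InclusionModel(cfg, VOCAB, np.random.default_rng(0)), cfg


class TestTargetTransform:
    def test_unchanged_event_forces_both_deltas_to_eps(self):
        t = target_transform(0.7, 0.7, np.random.default_rng(0))
        assert t.t_psi == 0.7
        assert t.t_dpsi_plus == t.t_dpsi_minus == t.eps
        assert 0.001 <= t.eps <= 0.002

    def test_inclusion_gain(self):
        t = target_transform(0.8, 0.5, np.random.default_rng(0))
        assert t.t_psi == 0.8
        assert t.t_dpsi_plus == pytest.approx(0.3)
        assert t.t_dpsi_minus == t.eps

    def test_inclusion_loss(self):
        t = target_transform(0.2, 0.6, np.random.default_rng(0))
        assert t.t_dpsi_plus == t.eps
        assert t.t_dpsi_minus == pytest.approx(0.4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            target_transform(1.2, 0.5, np.random.default_rng(0))

    def test_difference_recovers_dpsi_up_to_eps(self):
        """The head difference equals dPSI up to the epsilon the formulas
        inject (the clamp replaces one side by eps)."""
        rng = np.random.default_rng(1)
        for pc in np.linspace(0, 1, 21):
            for pp in np.linspace(0, 1, 21):
                t = target_transform(pc, pp, rng)
                d = pc - pp
                if abs(d) >= t.eps:
                    assert t.t_dpsi_plus - t.t_dpsi_minus == pytest.approx(
                        d, abs=t.eps + 1e-12)
                else:
                    assert abs(t.t_dpsi_plus - t.t_dpsi_minus) <= 2 * t.eps
                assert 0 <= t.t_dpsi_plus <= 1 and 0 <= t.t_dpsi_minus <= 1

    def test_seeded_eps_reproducible(self):
        a = target_transform(0.5, 0.5, np.random.default_rng(3)).eps
        b = target_transform(0.5, 0.5, np.random.default_rng(3)).eps
        assert a == b


def test_length_bins_clamp_to_edges():
    assert length_bin(1) == 0
    assert length_bin(10 ** 9) == 31
    assert 0 < length_bin(1000) < 31
    bins = [length_bin(x) for x in (10, 100, 1000, 10_000, 100_000)]
    assert bins == sorted(bins)


class TestForwardContracts:
    def test_outputs_in_unit_interval_and_deterministic(self):
        model, _ = _tiny_model()
        f = featurize(_event(), _windows(), VOCAB, *CONDS)
        out1 = model.forward([f])
        out2 = model.forward([f])
        assert out1.shape == (1, 3)
        assert ((out1 >= 0) & (out1 <= 1)).all()
        assert np.array_equal(out1, out2)

    def test_tower_swap_changes_output(self):
        model, _ = _tiny_model()
        w = _windows()
        swapped = EventWindows((w.seqs[3], w.seqs[1], w.seqs[2], w.seqs[0]),
                               w.cons, w.width)
        f1 = featurize(_event(), w, VOCAB, *CONDS)
        f2 = featurize(_event(), swapped, VOCAB, *CONDS)
        assert not np.allclose(model.forward([f1]), model.forward([f2]))

    def test_predict_dpsi_clamped_and_psi_in_range(self):
        model, _ = _tiny_model()
        ev, w = _event(), _windows()
        assert 0.0 <= model.predict_psi(ev, w, CONDS[0]) <= 1.0
        assert -1.0 <= model.predict_dpsi(ev, w, *CONDS) <= 1.0

    def test_unknown_condition_raises(self):
        model, _ = _tiny_model()
        with pytest.raises(KeyError):
            featurize(_event(), _windows(), VOCAB, "marslike", CONDS[0])
            model.forward([featurize(_event(), _windows(), VOCAB, "marslike",
                                     CONDS[0])])


class TestFinetune:
    def _examples(self, n=6):
        out = []
        for i in range(n):
            f = featurize(_event(), _windows(seed=i), VOCAB, *CONDS)
            out.append(TrainExample(f"e{i}", f, psi_c=0.2 + 0.1 * (i % 5),
                                    psi_cprime=0.5))
        return out

    def test_zero_epochs_leaves_model_at_initialization(self):
        model, cfg = _tiny_model(epochs=0)
        ref, _ = _tiny_model(epochs=0)
        finetune(model, self._examples(), np.random.default_rng(0))
        for a, b in zip(model.params(), ref.params()):
            assert np.array_equal(a.value, b.value)

    def test_empty_training_set_rejected(self):
        model, _ = _tiny_model()
        with pytest.raises(ValueError):
            finetune(model, [], np.random.default_rng(0))

    def test_loss_decreases_on_tiny_set(self):
        # constant lr: the warm-up/decay schedule is pointless over a
        # handful of steps and the fresh-eps targets add noise
        model, _ = _tiny_model(epochs=10, lr=3e-3, lr_decay=False)
        log = finetune(model, self._examples(16), np.random.default_rng(0))
        assert log.loss.iloc[-3:].mean() < log.loss.iloc[0]

    def test_checkpoint_round_trip(self, tmp_path):
        model, _ = _tiny_model()
        f = featurize(_event(), _windows(), VOCAB, *CONDS)
        before = model.forward([f]).copy()
        model.save(str(tmp_path / "m"))
        loaded = InclusionModel.load(str(tmp_path / "m"))
        assert np.allclose(loaded.forward([f]), before)


class TestRbpAutoencoder:
    def _matrix(self, n_cond=6, n_rbp=12, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(1, 10, size=(1, n_rbp))
        shift = np.repeat(rng.uniform(-2, 2, size=(n_cond, 1)), n_rbp, axis=1)
        X = np.abs(base + shift + rng.normal(0, 0.1, (n_cond, n_rbp)))
        return pd.DataFrame(X, index=[f"c{i}" for i in range(n_cond)],
                            columns=[f"r{j}" for j in range(n_rbp)])

    def test_identical_vectors_identical_embeddings(self):
        df = self._matrix()
        ae, _ = train_rbp_ae(df, latent_dim=4, steps=200)
        a = ae.embed(df.iloc[0])
        b = ae.embed(df.iloc[0].to_numpy())
        assert np.allclose(a, b)

    def test_reconstruction_loss_decreases(self):
        ae, losses = train_rbp_ae(self._matrix(), latent_dim=4, steps=400)
        assert losses[-1] < losses[0]

    def test_cluster_preservation(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(5, 6, size=12)
        b = rng.uniform(0.5, 1.0, size=12)
        rows = [a + rng.normal(0, 0.05, 12) for _ in range(4)] + \
               [b + rng.normal(0, 0.05, 12) for _ in range(4)]
        df = pd.DataFrame(np.abs(rows), columns=[f"r{j}" for j in range(12)],
                          index=[f"c{i}" for i in range(8)])
        ae, _ = train_rbp_ae(df, latent_dim=3, steps=800)
        Z = np.stack([ae.embed(df.iloc[i]) for i in range(8)])
        within = np.linalg.norm(Z[0] - Z[1])
        between = np.linalg.norm(Z[0] - Z[5])
        assert within < between

    def test_input_validation(self):
        df = self._matrix(n_cond=1)
        with pytest.raises(ValueError):
            train_rbp_ae(df, steps=10)
        ae, _ = train_rbp_ae(self._matrix(), steps=10)
        with pytest.raises(ValueError):
            ae.embed(np.ones(5))  # wrong RBP count
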
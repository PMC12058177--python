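"""Fine-tuning mechanics: augmentation, oversampling, freezing, ensembling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microbelm as m
from microbelm.corpus_io import TaxonVocabulary, TokenSequence
from microbelm.encoder_model import encoder_checksum, taxon_embedding_checksum
from microbelm.finetune import (
    FinetuneConfig,
    PhenotypeClassifier,
    _oversample_indices,
    make_classifier_model,
)

from conftest import tiny_sequences


def _seq_of(n):
    return TokenSequence(np.concatenate(([TaxonVocabulary.CLS],
                                         np.arange(3, 3 + n))))


class TestAugmentDelete:
    def test_ten_taxa_at_ten_percent_leaves_nine(self):
        out = m.augment_delete(_seq_of(10), 0.10, np.random.default_rng(0))
        assert len(out.taxa) == 9

    def test_rate_zero_identity(self):
        seq = _seq_of(7)
        out = m.augment_delete(seq, 0.0, np.random.default_rng(0))
        assert np.array_equal(out.token_indices, seq.token_indices)

    def test_cls_only_unchanged(self):
        seq = TokenSequence(np.array([TaxonVocabulary.CLS]))
        out = m.augment_delete(seq, 0.5, np.random.default_rng(0))
        assert np.array_equal(out.token_indices, seq.token_indices)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(1, 40), st.floats(0, 0.9), st.integers(0, 10_000))
    def test_survivor_order_and_count(self, n, rate, seed):
        seq = _seq_of(n)
        out = m.augment_delete(seq, rate, np.random.default_rng(seed))
        expected_deleted = int(np.floor(rate * n + 0.5))
        assert len(out.taxa) == n - expected_deleted
        assert out.token_indices[0] == TaxonVocabulary.CLS
        # survivors keep source order: subsequence check
        it = iter(seq.taxa.tolist())
        assert all(t in it for t in out.taxa.tolist())


class TestOversampling:
    def test_parity_each_epoch(self):
        labels = np.array([0] * 30 + [1] * 10)
        order = _oversample_indices(labels, np.random.default_rng(0))
        seen = labels[order]
        assert (seen == 0).sum() == (seen == 1).sum() == 30

    def test_balanced_input_untouched(self):
        labels = np.array([0, 1] * 10)
        order = _oversample_indices(labels, np.random.default_rng(0))
        assert sorted(order) == list(range(20))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            _oversample_indices(np.zeros(5, dtype=int), np.random.default_rng(0))


@pytest.fixture(scope="module")
def labeled_tiny(tiny_kit):
    """Tiny labeled corpus with a perfectly discriminative taxon."""
    rng = np.random.default_rng(1)
    vocab = tiny_kit["vocab"]
    seqs, labels = [], []
    marker = vocab.index("tx00")
    for i in range(48):
        label = i % 3 == 0  # ~1/3 positive: exercises oversampling
        others = rng.choice(np.arange(vocab.n_special + 1, vocab.size),
                            size=5, replace=False)
        taxa = np.sort(np.concatenate(([marker], others))) if label else np.sort(others)
        seqs.append(TokenSequence(np.concatenate(([TaxonVocabulary.CLS], taxa))))
        labels.append(int(label))
    return seqs, np.array(labels)


class TestFinetuneMechanics:
    def test_encoder_and_taxon_rows_frozen_heads_move(self, tiny_kit, labeled_tiny):
        encoder = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"],
                                tiny_kit["emb"], "token_binary", rng_seed=2)
        model = make_classifier_model(encoder, head_seed=3)
        enc_before = encoder_checksum(model)
        taxa_before = taxon_embedding_checksum(model)
        head_before = model.head.fc1.w.data.copy()
        proj_before = model.projection.w.data.copy()
        clf = PhenotypeClassifier(model, FinetuneConfig(epochs=2, batch_size=16))
        clf.fit(*labeled_tiny)
        assert encoder_checksum(model) == enc_before
        assert taxon_embedding_checksum(model) == taxa_before
        assert not np.array_equal(model.head.fc1.w.data, head_before)
        assert not np.array_equal(model.projection.w.data, proj_before)

    def test_mse_loss_bounded_and_decreasing(self, tiny_kit, labeled_tiny):
        encoder = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"],
                                tiny_kit["emb"], "token_binary", rng_seed=4)
        clf = m.finetune(encoder, *labeled_tiny,
                         FinetuneConfig(epochs=5, batch_size=16,
                                        learning_rate=0.05))
        losses = [h["train_loss"] for h in clf.history_]
        assert all(0 <= l <= 1 for l in losses)
        assert losses[4] < losses[0]
        per_class = clf.history_[0]["n_seen_per_class"]
        assert per_class[0] == per_class[1]

    def test_single_class_corpus_rejected(self, tiny_kit):
        encoder = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"],
                                tiny_kit["emb"], "token_binary")
        seqs = tiny_sequences(tiny_kit["vocab"], 6, np.random.default_rng(5))
        with pytest.raises(ValueError):
            m.finetune(encoder, seqs, np.ones(6, dtype=int), FinetuneConfig(epochs=1))

    def test_stopping_epoch_earliest_argmax(self, tiny_kit, labeled_tiny,
                                            monkeypatch):
        encoder = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"],
                                tiny_kit["emb"], "token_binary", rng_seed=6)
        seqs, labels = labeled_tiny
        # force a validation curve peaking (tied) at epochs 2 and 5
        curve = iter([0.6, 0.9, 0.7, 0.8, 0.9])
        monkeypatch.setattr("microbelm.evaluation.auroc",
                            lambda s, l: next(curve))
        epoch, _ = m.select_stopping_epoch(
            encoder, (seqs[:32], labels[:32]), (seqs[32:], labels[32:]),
            FinetuneConfig(epochs=5, batch_size=16))
        assert epoch == 2

    def test_degenerate_validation_rejected(self, tiny_kit, labeled_tiny):
        encoder = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"],
                                tiny_kit["emb"], "token_binary")
        seqs, labels = labeled_tiny
        with pytest.raises(ValueError):
            m.select_stopping_epoch(encoder, (seqs, labels),
                                    (seqs[:3], np.zeros(3, dtype=int)),
                                    FinetuneConfig(epochs=1))


class TestEnsemble:
    def test_k_members_and_k1_equals_single_member(self, tiny_kit):
        rng = np.random.default_rng(7)
        vocab = tiny_kit["vocab"]
        seqs = tiny_sequences(vocab, 20, rng)
        labels = np.array([0, 1] * 10)
        encoder = m.build_model(tiny_kit["cfg"], vocab, tiny_kit["emb"],
                                "token_binary", rng_seed=8)
        cfg = FinetuneConfig(epochs=1, batch_size=8)
        ens = m.train_ensemble(encoder, seqs, labels, k=3,
                               rng=np.random.default_rng(9), config=cfg)
        assert len(ens.members_) == 3
        one = m.train_ensemble(encoder, seqs, labels, k=1,
                               rng=np.random.default_rng(9), config=cfg)
        np.testing.assert_array_equal(one.predict_proba(seqs[:5]),
                                      one.members_[0].predict_proba(seqs[:5]))

    def test_mean_aggregation_of_forced_members(self, tiny_kit, monkeypatch):
        encoder = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"],
                                tiny_kit["emb"], "token_binary")
        ens = m.EnsembleClassifier(encoder, k=2)
        seqs = tiny_sequences(tiny_kit["vocab"], 4, np.random.default_rng(10))

        class Stub:
            def __init__(self, c):
                self.c = c

            def predict_proba(self, s):
                return np.full(len(s), self.c)

        ens.members_ = [Stub(0.2), Stub(0.8)]
        np.testing.assert_allclose(ens.predict_proba(seqs), 0.5)

    def test_each_member_trained_exactly_one_epoch(self, tiny_kit):
        vocab = tiny_kit["vocab"]
        seqs = tiny_sequences(vocab, 12, np.random.default_rng(11))
        labels = np.array([0, 1] * 6)
        encoder = m.build_model(tiny_kit["cfg"], vocab, tiny_kit["emb"],
                                "token_binary")
        ens = m.train_ensemble(encoder, seqs, labels, k=2,
                               rng=np.random.default_rng(12),
                               config=FinetuneConfig(epochs=7, batch_size=8))
        for member in ens.members_:
            assert len(member.history_) == 1

    def test_k_below_one_rejected(self, tiny_kit):
        encoder = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"],
                                tiny_kit["emb"], "token_binary")
        with pytest.raises(ValueError):
            m.EnsembleClassifier(encoder, k=0)
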
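"""ELECTRA mechanics: masking, replacement labeling, schedule arithmetic,
and learnability on tiny planted-structure fixtures."""

import numpy as np
import pytest

import microbelm as m
from microbelm.corpus_io import TaxonVocabulary, TokenSequence
from microbelm.electra import (
    PretrainSchedule,
    generate_replacements,
    mask_sample,
    masked_count,
    replace_batch,
    train_discriminator,
    train_generator,
)

from conftest import tiny_sequences


def _seq(n_taxa: int, vocab: TaxonVocabulary) -> TokenSequence:
    taxa = np.arange(vocab.n_special, vocab.n_special + n_taxa)
    return TokenSequence(np.concatenate(([TaxonVocabulary.CLS], taxa)))


class TestMasking:
    def test_15_percent_of_100(self):
        vocab = TaxonVocabulary([f"t{i}" for i in range(150)])
        masked, plan = mask_sample(_seq(100, vocab), 0.15, np.random.default_rng(0))
        assert len(plan) == 15
        assert np.all(masked[plan.positions] == TaxonVocabulary.MASK)
        assert masked[0] == TaxonVocabulary.CLS

    @pytest.mark.parametrize("n,expected", [(1, 1), (3, 1), (10, 2), (12, 2),
                                            (100, 15), (16, 2), (17, 3)])
    def test_round_half_up_with_floor_one(self, n, expected):
        assert masked_count(n, 0.15) == expected

    def test_equal_seeds_identical_plans(self):
        vocab = TaxonVocabulary([f"t{i}" for i in range(30)])
        seq = _seq(20, vocab)
        m1, p1 = mask_sample(seq, 0.15, np.random.default_rng(9))
        m2, p2 = mask_sample(seq, 0.15, np.random.default_rng(9))
        assert np.array_equal(m1, m2) and np.array_equal(p1.positions, p2.positions)

    def test_cls_only_unchanged(self):
        seq = TokenSequence(np.array([TaxonVocabulary.CLS]))
        masked, plan = mask_sample(seq, 0.15, np.random.default_rng(0))
        assert len(plan) == 0 and masked.tolist() == [TaxonVocabulary.CLS]

    def test_plan_records_originals(self):
        vocab = TaxonVocabulary([f"t{i}" for i in range(30)])
        seq = _seq(20, vocab)
        masked, plan = mask_sample(seq, 0.3, np.random.default_rng(1))
        assert np.array_equal(plan.original_tokens,
                              seq.token_indices[plan.positions])


class TestSchedule:
    def test_reference_schedule_consumes_8_checkpoints(self):
        sched = PretrainSchedule()  # 240/30, 120/15
        assert sched.n_checkpoints == 8
        assert sched.n_swaps == 8
        used = [sched.checkpoint_for_epoch(e) for e in range(120)]
        assert used == sorted(used)  # consumed in training order
        assert used[0] == 0 and used[-1] == 7
        assert used[14] == 0 and used[15] == 1  # epoch-30 ckpt feeds epochs 1-15

    def test_mismatched_intervals_rejected(self):
        with pytest.raises(ValueError):
            PretrainSchedule(generator_epochs=100, generator_checkpoint_every=30)

    def test_too_few_checkpoints_rejected(self, tiny_kit):
        model = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"], tiny_kit["emb"],
                              "token_binary")
        sched = PretrainSchedule(generator_epochs=4, generator_checkpoint_every=1,
                                 discriminator_epochs=4, generator_swap_every=1)
        with pytest.raises(ValueError, match="checkpoints"):
            train_discriminator(model, [_seq(3, tiny_kit["vocab"])],
                                [model.state_dict()] * 2, sched,
                                np.random.default_rng(0))


class TestReplacements:
    def test_empty_plan_identity(self, tiny_kit):
        gen = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"], tiny_kit["emb"],
                            "token_vocab")
        seq = TokenSequence(np.array([TaxonVocabulary.CLS]))
        masked, plan = mask_sample(seq, 0.15, np.random.default_rng(0))
        rep = generate_replacements(gen, masked, plan, np.random.default_rng(1))
        assert np.array_equal(rep.token_indices, seq.token_indices)
        assert not rep.modified.any()

    def test_deterministic_given_seed(self, tiny_kit):
        gen = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"], tiny_kit["emb"],
                            "token_vocab")
        seq = tiny_sequences(tiny_kit["vocab"], 1, np.random.default_rng(2),
                             max_len=10)[0]
        masked, plan = mask_sample(seq, 0.3, np.random.default_rng(3))
        a = generate_replacements(gen, masked, plan, np.random.default_rng(4))
        b = generate_replacements(gen, masked, plan, np.random.default_rng(4))
        assert np.array_equal(a.token_indices, b.token_indices)
        assert np.array_equal(a.modified, b.modified)

    def test_label_consistency_exhaustive(self, tiny_kit):
        """modified <=> emitted token differs from the original, over many
        random sequences."""
        gen = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"], tiny_kit["emb"],
                            "token_vocab")
        rng = np.random.default_rng(5)
        seqs = tiny_sequences(tiny_kit["vocab"], 200, rng)
        reps = replace_batch(gen, seqs, 0.3, rng)
        for seq, rep in zip(seqs, reps):
            assert len(rep.token_indices) == len(seq)
            changed = rep.token_indices != seq.token_indices
            assert np.array_equal(rep.modified, changed)
            assert not rep.modified[0]  # CLS untouched

    def test_uniform_generator_real_rate_matches_analytic(self, tiny_kit):
        """A generator forced to uniform output relabels a masked position
        "real" with probability 1/vocab."""
        gen = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"], tiny_kit["emb"],
                            "token_vocab")
        gen.head.fc2.w.data[:] = 0
        gen.head.fc2.b.data[:] = 0  # uniform logits over the vocabulary
        n_taxa = len(tiny_kit["vocab"])
        rng = np.random.default_rng(6)
        vocab = tiny_kit["vocab"]
        seq = _seq(8, vocab)
        real = total = 0
        masked, plan = mask_sample(seq, 0.5, np.random.default_rng(7))
        for _ in range(400):
            rep = generate_replacements(gen, masked, plan, rng)
            real += int((~rep.modified[plan.positions]).sum())
            total += len(plan)
        rate = real / total
        assert rate == pytest.approx(1 / n_taxa, abs=3 * np.sqrt(1 / n_taxa / total))

    def test_plan_mismatch_rejected(self, tiny_kit):
        gen = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"], tiny_kit["emb"],
                            "token_vocab")
        seq = _seq(5, tiny_kit["vocab"])
        _, plan = mask_sample(seq, 0.3, np.random.default_rng(8))
        with pytest.raises(ValueError):
            generate_replacements(gen, seq.token_indices, plan,
                                  np.random.default_rng(9))


@pytest.fixture(scope="module")
def planted_corpus(tiny_kit):
    # taxon tx01 always co-occurs with tx00; remaining taxa random
    rng = np.random.default_rng(10)
    vocab = tiny_kit["vocab"]
    seqs = []
    for _ in range(60):
        others = rng.choice(np.arange(vocab.n_special + 2, vocab.size),
                            size=4, replace=False)
        taxa = np.concatenate(([vocab.index("tx00"), vocab.index("tx01")],
                               others))
        seqs.append(TokenSequence(np.concatenate(([TaxonVocabulary.CLS],
                                                  np.sort(taxa)))))
    return seqs


class TestTrainingOnTinyFixture:
    """Learnability checks on a co-occurrence fixture small enough for CI."""

    def test_generator_loss_decreases_and_recovers_cooccurrence(
            self, tiny_kit, planted_corpus):
        gen = m.build_model(tiny_kit["cfg"], tiny_kit["vocab"], tiny_kit["emb"],
                            "token_vocab", rng_seed=0)
        sched = PretrainSchedule(generator_epochs=5, generator_checkpoint_every=1,
                                 discriminator_epochs=5, generator_swap_every=1,
                                 batch_size=16, learning_rate=3e-3)
        ckpts, log = train_generator(gen, planted_corpus, sched,
                                     np.random.default_rng(11))
        assert len(ckpts) == 5
        assert log[4]["train_loss"] <= log[0]["train_loss"]
        # masked-B top-1 recovery given A present should beat 1/vocab
        vocab = tiny_kit["vocab"]
        hits = 0
        for seq in planted_corpus[:30]:
            masked = seq.token_indices.copy()
            b_pos = int(np.nonzero(masked == vocab.index("tx01"))[0][0])
            masked[b_pos] = TaxonVocabulary.MASK
            probs = gen.token_predictions(TokenSequence(masked))
            hits += int(np.argmax(probs[b_pos]) == vocab.index("tx01"))
        assert hits / 30 > 3 / len(vocab)
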
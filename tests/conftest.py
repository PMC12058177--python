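"""Shared fixtures.

Cheap fixtures build a deliberately tiny encoder for mechanistic tests;
session-scoped heavy fixtures run the scaled pre-training / fine-tuning
pipeline once and are shared by every test that needs a trained model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import microbelm as m
from microbelm.corpus_io import EmbeddingMatrix, TaxonVocabulary
from microbelm.electra import (
    PretrainSchedule,
    evaluate_discriminator,
    evaluate_generator,
    train_discriminator,
    train_generator,
)
from microbelm.finetune import FinetuneConfig

# ---- scale used for the heavy pipeline fixtures ----------------------------
# Study world: 1000 samples (500 patients).  Pre-training uses 400 training
# and 200 held-out samples for 24 generator epochs (checkpoint every 3 ->
# 8 checkpoints) and 16 discriminator epochs (swap every 2), preserving
# the 8-checkpoint curriculum shape of the reference schedule at desk
# scale; lr 5e-4 with 200 warmup steps (post-norm blocks need the ramp).
# Fine-tuning runs 7 epochs at batch 16.
PRETRAIN_SCHEDULE = PretrainSchedule(
    generator_epochs=24, generator_checkpoint_every=3,
    discriminator_epochs=16, generator_swap_every=2, batch_size=32,
    learning_rate=5e-4, warmup_steps=200,
)
N_SAMPLES = 1000
N_PRETRAIN, N_HELD = 400, 200
FINETUNE_CFG = FinetuneConfig(epochs=7, batch_size=16, seed=0)


@pytest.fixture(scope="session")
def world() -> m.SyntheticWorld:
    return m.generate_world(m.SyntheticConfig(n_samples=N_SAMPLES, seed=0))


@pytest.fixture(scope="session")
def vocab(world) -> TaxonVocabulary:
    return world.vocabulary()


@pytest.fixture(scope="session")
def sequences(world, vocab):
    return m.tokenize_table(world.abundance, vocab)


@pytest.fixture(scope="session")
def shifted_world(world) -> m.SyntheticWorld:
    return m.generate_world(m.shifted_config(world.config))


# ---- tiny model kit for fast mechanistic tests -----------------------------

@pytest.fixture(scope="session")
def tiny_kit():
    rng = np.random.default_rng(7)
    taxa = [f"tx{i:02d}" for i in range(12)]
    emb = EmbeddingMatrix(pd.DataFrame(rng.standard_normal((12, 8)), index=taxa))
    vocab = TaxonVocabulary(taxa)
    cfg = m.ModelConfig(vocab_size=vocab.size, embed_dim=8, hidden_dim=16,
                        n_blocks=2, n_heads=2, ff_dim=32, max_positions=16,
                        head_hidden=16, dropout=0.1, seed=3)
    return {"vocab": vocab, "emb": emb, "cfg": cfg}


def tiny_sequences(vocab: TaxonVocabulary, n: int, rng: np.random.Generator,
                   max_len: int = 10):
    """Random small token sequences over the tiny vocabulary."""
    out = []
    for _ in range(n):
        k = int(rng.integers(1, max_len))
        taxa = rng.choice(np.arange(vocab.n_special, vocab.size), size=k,
                          replace=False)
        out.append(m.TokenSequence(np.concatenate(([TaxonVocabulary.CLS], taxa))))
    return out


# ---- heavy pipeline fixtures (shared across acceptance tests) --------------

@pytest.fixture(scope="session")
def pretrained(world, vocab, sequences):
    """Scaled ELECTRA pre-training on the default world.

    Returns the trained generator/discriminator plus held-out metrics at
    initialization and after training.
    """
    cfg = m.ModelConfig(vocab_size=vocab.size, seed=0)
    train = sequences[:N_PRETRAIN]
    held = sequences[N_PRETRAIN:N_PRETRAIN + N_HELD]
    generator = m.build_model(cfg, vocab, world.embeddings, "token_vocab", rng_seed=1)
    _, top1_init = evaluate_generator(generator, held, 0.15,
                                      np.random.default_rng(3), n_draws=5)
    checkpoints, gen_log = train_generator(
        generator, train, PRETRAIN_SCHEDULE, np.random.default_rng(2))
    _, top1 = evaluate_generator(generator, held, 0.15,
                                 np.random.default_rng(3), n_draws=5)

    discriminator = m.build_model(cfg, vocab, world.embeddings, "token_binary",
                                  rng_seed=4)
    gen_template = m.build_model(cfg, vocab, world.embeddings, "token_vocab",
                                 rng_seed=5)
    gen_template.load_state_dict(checkpoints[-1])
    balacc_init = evaluate_discriminator(discriminator, held, gen_template, 0.15,
                                         np.random.default_rng(6))
    disc_log = train_discriminator(discriminator, train, checkpoints,
                                   PRETRAIN_SCHEDULE, np.random.default_rng(7),
                                   generator_template=gen_template)
    gen_template.load_state_dict(checkpoints[-1])
    balacc = evaluate_discriminator(discriminator, held, gen_template, 0.15,
                                    np.random.default_rng(8))
    return {
        "config": cfg, "generator": generator, "checkpoints": checkpoints,
        "discriminator": discriminator, "generator_log": gen_log,
        "discriminator_log": disc_log, "held_out": held,
        "top1_init": top1_init, "top1": top1,
        "balacc_init": balacc_init, "balacc": balacc,
    }


@pytest.fixture(scope="session")
def protocol_results(pretrained, world, sequences):
    """Evaluation-protocol results (n_runs=3) on the study world, keeping
    each run's refit classifier for reuse by downstream tests."""
    runs, models = m.run_protocol(
        pretrained["discriminator"], sequences, world.label_array(),
        world.patient_array(), m.SplitSpec(seed=11), FINETUNE_CFG, n_runs=3,
        return_models=True)
    return {"runs": runs, "models": models}


@pytest.fixture(scope="session")
def protocol_runs(protocol_results):
    return protocol_results["runs"]


@pytest.fixture(scope="session")
def single_classifier(protocol_results, world, sequences):
    """Run 0's refit classifier and patient-blocked partition (shared by the
    ensemble, shift and attribution tests)."""
    first = protocol_results["models"][0]
    part = first["partition"]
    nontest = np.concatenate([part["train"], part["validation"]])
    return {"clf": first["classifier"], "part": part, "nontest": nontest}


@pytest.fixture(scope="session")
def attribution_classifier(pretrained, world, sequences, single_classifier):
    """A longer-trained (12-epoch) classifier for attribution analyses.

    Marker attribution needs a well-converged model: a half-converged head
    spreads ablation credit onto co-occurring block members.
    """
    from dataclasses import replace

    nontest = single_classifier["nontest"]
    labels = world.label_array()
    return m.finetune(pretrained["discriminator"],
                      [sequences[i] for i in nontest], labels[nontest],
                      replace(FINETUNE_CFG, epochs=12))


@pytest.fixture(scope="session")
def ensemble_classifier(pretrained, world, sequences, single_classifier):
    """k=10 single-epoch ensemble trained on the same non-test data."""
    nontest = single_classifier["nontest"]
    labels = world.label_array()
    ens = m.train_ensemble(pretrained["discriminator"],
                           [sequences[i] for i in nontest], labels[nontest],
                           k=10, rng=np.random.default_rng(21),
                           config=FINETUNE_CFG)
    return ens
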
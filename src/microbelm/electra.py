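"""ELECTRA-style self-supervised pre-training for microbiome token sequences.

Two models with identical encoder architecture are trained in sequence:

1. a *generator* learns to predict masked-out taxa (15% of the taxa in a
   sample are replaced by a MASK token) from the remaining community;
2. a *discriminator* learns to label each taxon of a generator-completed
   sample as "real" (original) or "modified" (generator-substituted).

The discriminator curriculum ramps up difficulty by swapping in
progressively stronger generator checkpoints: with the reference schedule
(generator 240 epochs, checkpoint every 30; discriminator 120 epochs, swap
every 15) the checkpoint saved at generator epoch 30 feeds discriminator
epochs 1-15, the epoch-60 checkpoint feeds 16-30, and so on.  The trained
discriminator's encoder becomes the universal sample encoder downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import bce_logits, cross_entropy_logits, no_grad, softmax, tape_arena
from .corpus_io import TaxonVocabulary, TokenSequence
from .encoder_model import EncoderModel
from .nn import Adam


@dataclass
class MaskingPlan:
    """Masked positions (sequence indices, CLS excluded) and their originals."""

    positions: np.ndarray
    original_tokens: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class PretrainSchedule:
    generator_epochs: int = 240
    generator_checkpoint_every: int = 30
    discriminator_epochs: int = 120
    generator_swap_every: int = 15
    mask_rate: float = 0.15
    batch_size: int = 32
    learning_rate: float = 1e-4
    warmup_steps: int = 0  # linear LR warmup; helps post-norm blocks at high LR
    balance_discriminator_classes: bool = True

    def __post_init__(self):
        if self.generator_epochs % self.generator_checkpoint_every:
            raise ValueError("generator_epochs must be a multiple of checkpoint interval")
        if self.discriminator_epochs % self.generator_swap_every:
            raise ValueError("discriminator_epochs must be a multiple of swap interval")

    @property
    def n_checkpoints(self) -> int:
        return self.generator_epochs // self.generator_checkpoint_every

    @property
    def n_swaps(self) -> int:
        return self.discriminator_epochs // self.generator_swap_every

    def checkpoint_for_epoch(self, disc_epoch: int) -> int:
        """0-based checkpoint index used during 0-based discriminator epoch."""
        return disc_epoch // self.generator_swap_every


@dataclass
class ReplacedSequence:
    """Generator-completed sequence with per-position real/modified labels."""

    token_indices: np.ndarray
    modified: np.ndarray  # bool per position; True = generator changed the token

    def __post_init__(self):
        if len(self.token_indices) != len(self.modified):
            raise ValueError("labels must align with tokens")


def masked_count(n_taxa: int, mask_rate: float) -> int:
    """Round-half-up with a floor of 1 (when any taxon is present)."""
    if n_taxa == 0:
        return 0
    return max(1, int(np.floor(mask_rate * n_taxa + 0.5)))


def mask_sample(tokens: TokenSequence, mask_rate: float,
                rng: np.random.Generator) -> tuple[np.ndarray, MaskingPlan]:
    """Replace a seeded random 15% (by default) of taxa with the MASK token."""
    if not 0 < mask_rate < 1:
        raise ValueError("mask_rate must be in (0, 1)")
    n_taxa = len(tokens) - 1
    k = masked_count(n_taxa, mask_rate)
    masked = tokens.token_indices.copy()
    if k == 0:
        return masked, MaskingPlan(np.empty(0, np.int64), np.empty(0, np.int64))
    pos = rng.choice(np.arange(1, n_taxa + 1), size=k, replace=False)
    pos.sort()
    originals = masked[pos].copy()
    masked[pos] = TaxonVocabulary.MASK
    return masked, MaskingPlan(pos, originals)


def _batches(n: int, batch_size: int, rng: np.random.Generator,
             lengths: np.ndarray | None = None, bucket: int = 8):
    """Shuffled batches; with ``lengths``, sequences are length-bucketed
    within shuffled windows (less padding waste), and batch order is
    re-shuffled so bucketing does not bias the SGD curriculum."""
    order = rng.permutation(n)
    if lengths is None:
        for i in range(0, n, batch_size):
            yield order[i : i + batch_size]
        return
    batches = []
    window = batch_size * bucket
    for i in range(0, n, window):
        chunk = order[i : i + window]
        chunk = chunk[np.argsort(lengths[chunk], kind="stable")]
        for j in range(0, len(chunk), batch_size):
            batches.append(chunk[j : j + batch_size])
    for k in rng.permutation(len(batches)):
        yield batches[k]


def _mask_batch(sequences: list[TokenSequence], mask_rate: float,
                rng: np.random.Generator) -> tuple[list[np.ndarray], list[MaskingPlan]]:
    masked, plans = [], []
    for seq in sequences:
        m, p = mask_sample(seq, mask_rate, rng)
        masked.append(m)
        plans.append(p)
    return masked, plans


def _pad(arrs: list[np.ndarray], max_positions: int) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(a) for a in arrs], dtype=np.int64)
    s = int(lengths.max())
    if s > max_positions:
        raise ValueError("sequence exceeds max_positions")
    idx = np.zeros((len(arrs), s), dtype=np.int64)
    for i, a in enumerate(arrs):
        idx[i, : len(a)] = a
    return idx, lengths


def generator_loss_batch(model: EncoderModel, sequences: list[TokenSequence],
                         mask_rate: float, rng: np.random.Generator,
                         training: bool = True):
    """Masked-token cross-entropy on one batch; returns (loss tensor, n_masked)."""
    masked, plans = _mask_batch(sequences, mask_rate, rng)
    idx, lengths = _pad(masked, model.cfg.max_positions)
    targets = np.zeros_like(idx)
    weights = np.zeros(idx.shape, dtype=model.embedding.weight.data.dtype)
    for i, plan in enumerate(plans):
        targets[i, plan.positions] = plan.original_tokens
        weights[i, plan.positions] = 1.0
    states = model.forward_states(idx, lengths, training=training)
    logits = model.head(states)
    return cross_entropy_logits(logits, targets, weights), int(weights.sum())


def train_generator(model: EncoderModel, corpus: list[TokenSequence],
                    schedule: PretrainSchedule, rng: np.random.Generator,
                    held_out: list[TokenSequence] | None = None,
                    ) -> tuple[list[dict[str, np.ndarray]], list[dict]]:
    """Train the generator; returns (checkpoints, per-epoch metrics log).

    Checkpoints are parameter snapshots taken every
    ``generator_checkpoint_every`` epochs, in training order.
    """
    if model.head_kind != "token_vocab":
        raise ValueError("generator requires a token_vocab head")
    if not corpus:
        raise ValueError("empty pre-training corpus")
    opt = Adam(model.trainable_parameters(), lr=schedule.learning_rate)
    lengths = np.array([len(s) for s in corpus])
    checkpoints: list[dict[str, np.ndarray]] = []
    log: list[dict] = []
    step = 0
    for epoch in range(schedule.generator_epochs):
        total, n_batches = 0.0, 0
        with tape_arena():
            for batch_idx in _batches(len(corpus), schedule.batch_size, rng, lengths):
                batch = [corpus[j] for j in batch_idx]
                step += 1
                if schedule.warmup_steps:
                    opt.lr = schedule.learning_rate * min(1.0, step / schedule.warmup_steps)
                opt.zero_grad()
                loss, _ = generator_loss_batch(model, batch, schedule.mask_rate, rng)
                loss.backward()
                opt.step()
                total += float(loss.data)
                n_batches += 1
        entry = {"epoch": epoch + 1, "train_loss": total / max(n_batches, 1)}
        if held_out is not None:
            entry["val_loss"], entry["val_top1"] = evaluate_generator(
                model, held_out, schedule.mask_rate,
                np.random.Generator(np.random.PCG64(12345)))
        log.append(entry)
        if (epoch + 1) % schedule.generator_checkpoint_every == 0:
            checkpoints.append(model.state_dict())
    return checkpoints, log


def evaluate_generator(model: EncoderModel, corpus: list[TokenSequence],
                       mask_rate: float, rng: np.random.Generator,
                       batch_size: int = 64, n_draws: int = 1) -> tuple[float, float]:
    """Held-out masked-token loss and top-1 recovery accuracy.

    ``n_draws`` > 1 repeats the evaluation with fresh mask draws and pools
    the masked positions — a lower-variance estimate on small held-out sets
    (one draw over 100 sparse samples probes only a few hundred positions).
    """
    total_loss, total_correct, total_masked, n_batches = 0.0, 0, 0, 0
    corpus = sorted(corpus, key=len) * n_draws
    with no_grad(), tape_arena():
        for start in range(0, len(corpus), batch_size):
            batch = corpus[start : start + batch_size]
            masked, plans = _mask_batch(batch, mask_rate, rng)
            idx, lengths = _pad(masked, model.cfg.max_positions)
            targets = np.zeros_like(idx)
            weights = np.zeros(idx.shape, dtype=model.embedding.weight.data.dtype)
            for i, plan in enumerate(plans):
                targets[i, plan.positions] = plan.original_tokens
                weights[i, plan.positions] = 1.0
            states = model.forward_states(idx, lengths, training=False)
            logits = model.head(states)
            loss = cross_entropy_logits(logits, targets, weights)
            pred = logits.data.argmax(axis=-1)
            mask = weights > 0
            total_correct += int((pred[mask] == targets[mask]).sum())
            total_masked += int(mask.sum())
            total_loss += float(loss.data)
            n_batches += 1
    return total_loss / max(n_batches, 1), total_correct / max(total_masked, 1)


def generate_replacements(generator: EncoderModel, masked_tokens: np.ndarray,
                          plan: MaskingPlan, rng: np.random.Generator) -> ReplacedSequence:
    """Fill masked positions by sampling from the generator distribution.

    A masked position is labeled "modified" iff the sampled taxon differs
    from the original; unmasked positions are always "real".
    """
    if (masked_tokens[plan.positions] != TaxonVocabulary.MASK).any():
        raise ValueError("plan does not match masked sequence")
    out = masked_tokens.copy()
    modified = np.zeros(len(out), dtype=bool)
    if len(plan) == 0:
        return ReplacedSequence(out, modified)
    with no_grad():
        idx, lengths = _pad([masked_tokens], generator.cfg.max_positions)
        states = generator.forward_states(idx, lengths, training=False)
        probs = softmax(generator.head(states), axis=-1).data[0]
    _fill_from_probs(out, modified, plan, probs, rng, generator.vocab)
    return ReplacedSequence(out, modified)


def _fill_from_probs(out, modified, plan, probs, rng, vocab: TaxonVocabulary) -> None:
    lo = vocab.n_special
    for pos, orig in zip(plan.positions, plan.original_tokens):
        p = probs[pos][lo:].astype(np.float64)  # sample over taxon tokens only
        p /= p.sum()
        draw = lo + rng.choice(len(p), p=p)
        out[pos] = draw
        modified[pos] = draw != orig


def replace_batch(generator: EncoderModel, sequences: list[TokenSequence],
                  mask_rate: float, rng: np.random.Generator
                  ) -> list[ReplacedSequence]:
    """Mask + generator-fill a batch (fresh randomization each call)."""
    masked, plans = _mask_batch(sequences, mask_rate, rng)
    idx, lengths = _pad(masked, generator.cfg.max_positions)
    with no_grad():
        states = generator.forward_states(idx, lengths, training=False)
        probs = softmax(generator.head(states), axis=-1).data
    out = []
    for i, plan in enumerate(plans):
        tokens = masked[i].copy()
        modified = np.zeros(len(tokens), dtype=bool)
        _fill_from_probs(tokens, modified, plan, probs[i], rng, generator.vocab)
        out.append(ReplacedSequence(tokens, modified))
    return out


def discriminator_loss_batch(model: EncoderModel, replaced: list[ReplacedSequence],
                             training: bool = True, balance_classes: bool = True):
    """Binary cross-entropy over all taxon positions (CLS and PAD excluded).

    Real positions greatly outnumber modified ones (~6:1 at a 15% mask
    rate); with ``balance_classes`` the two classes receive equal total
    weight within the batch, which prevents the degenerate always-"real"
    solution during short training runs.
    """
    idx, lengths = _pad([r.token_indices for r in replaced], model.cfg.max_positions)
    labels = np.zeros(idx.shape, dtype=model.embedding.weight.data.dtype)
    weights = np.zeros_like(labels)
    for i, r in enumerate(replaced):
        n = len(r.token_indices)
        weights[i, 1:n] = 1.0  # every taxon position; CLS at 0 excluded
        labels[i, 1:n] = r.modified[1:n]
    if balance_classes:
        n_mod = (weights * labels).sum()
        n_real = (weights * (1 - labels)).sum()
        if n_mod > 0 and n_real > 0:
            weights = weights * np.where(labels > 0, 0.5 / n_mod, 0.5 / n_real)
    states = model.forward_states(idx, lengths, training=training)
    logits = model.head(states)
    return bce_logits(logits.reshape(*idx.shape), labels, weights)


def train_discriminator(model: EncoderModel, corpus: list[TokenSequence],
                        generator_checkpoints: list[dict[str, np.ndarray]],
                        schedule: PretrainSchedule, rng: np.random.Generator,
                        generator_template: EncoderModel | None = None,
                        held_out: list[TokenSequence] | None = None,
                        ) -> list[dict]:
    """Train the discriminator with the checkpoint-swapping curriculum.

    ``generator_template`` is a token_vocab model whose parameters are
    overwritten by each checkpoint in turn (defaults to a fresh model with
    the discriminator's config).  Masking is re-randomized every epoch.
    Returns the per-epoch metrics log; the trained discriminator's encoder
    is the downstream universal encoder.
    """
    if model.head_kind != "token_binary":
        raise ValueError("discriminator requires a token_binary head")
    if len(generator_checkpoints) < schedule.n_swaps:
        raise ValueError(
            f"need {schedule.n_swaps} generator checkpoints, got {len(generator_checkpoints)}"
        )
    if generator_template is None:
        from .encoder_model import EncoderModel as _EM

        generator_template = _EM(model.cfg, model.vocab, _embeddings_of(model),
                                 "token_vocab")
    opt = Adam(model.trainable_parameters(), lr=schedule.learning_rate)
    lengths = np.array([len(s) for s in corpus])
    log: list[dict] = []
    current_ckpt = -1
    step = 0
    for epoch in range(schedule.discriminator_epochs):
        want = schedule.checkpoint_for_epoch(epoch)
        if want != current_ckpt:
            generator_template.load_state_dict(generator_checkpoints[want])
            current_ckpt = want
        total, n_batches = 0.0, 0
        with tape_arena():
            for batch_idx in _batches(len(corpus), schedule.batch_size, rng, lengths):
                batch = [corpus[j] for j in batch_idx]
                replaced = replace_batch(generator_template, batch,
                                         schedule.mask_rate, rng)
                step += 1
                if schedule.warmup_steps:
                    opt.lr = schedule.learning_rate * min(1.0, step / schedule.warmup_steps)
                opt.zero_grad()
                loss = discriminator_loss_batch(
                    model, replaced,
                    balance_classes=schedule.balance_discriminator_classes)
                loss.backward()
                opt.step()
                total += float(loss.data)
                n_batches += 1
        entry = {"epoch": epoch + 1, "checkpoint": want,
                 "train_loss": total / max(n_batches, 1)}
        if held_out is not None:
            entry["val_balanced_accuracy"] = evaluate_discriminator(
                model, held_out, generator_template, schedule.mask_rate,
                np.random.Generator(np.random.PCG64(54321)))
        log.append(entry)
    return log


def evaluate_discriminator(model: EncoderModel, corpus: list[TokenSequence],
                           generator: EncoderModel, mask_rate: float,
                           rng: np.random.Generator, batch_size: int = 64) -> float:
    """Balanced accuracy of real-vs-modified calls on generator-completed data."""
    tp = tn = pos = neg = 0
    corpus = sorted(corpus, key=len)
    with no_grad(), tape_arena():
        for start in range(0, len(corpus), batch_size):
            replaced = replace_batch(generator, corpus[start : start + batch_size],
                                     mask_rate, rng)
            idx, lengths = _pad([r.token_indices for r in replaced],
                                model.cfg.max_positions)
            states = model.forward_states(idx, lengths, training=False)
            logits = model.head(states).data[..., 0]
            for i, r in enumerate(replaced):
                n = len(r.token_indices)
                pred_mod = logits[i, 1:n] > 0
                truth = r.modified[1:n]
                tp += int((pred_mod & truth).sum())
                tn += int((~pred_mod & ~truth).sum())
                pos += int(truth.sum())
                neg += int((~truth).sum())
    tpr = tp / pos if pos else 0.0
    tnr = tn / neg if neg else 0.0
    return 0.5 * (tpr + tnr)


def _embeddings_of(model: EncoderModel):
    import pandas as pd

    from .corpus_io import EmbeddingMatrix

    rows = model.embedding.weight.data[TaxonVocabulary.n_special:]
    return EmbeddingMatrix(pd.DataFrame(np.asarray(rows, dtype=float),
                                        index=model.vocab.taxon_ids))
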
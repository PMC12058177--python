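"""Phenotype fine-tuning on a frozen pre-trained encoder.

A new two-layer CLS classification head is attached to the pre-trained
discriminator encoder.  During fine-tuning only the classification head,
the projection layer and the CLS embedding row are trained; encoder blocks,
positional embeddings and taxon embeddings stay frozen.  Training uses SGD
(lr 0.01, momentum 0.9) on a mean-squared-error loss between the predicted
probability and the {0,1} label, with two regularizers: random deletion of
10% of the input taxa (re-randomized per epoch, never at evaluation) and
minority-class oversampling to parity.

Also provides the k-member single-epoch ensemble used for cross-study
generalization: k heads with independent random initializations, each
fine-tuned for exactly one epoch, aggregated by mean probability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .autograd import Tensor, bce_logits, tape_arena
from .corpus_io import TaxonVocabulary, TokenSequence
from .encoder_model import EncoderModel
from .nn import SGD


@dataclass
class FinetuneConfig:
    learning_rate: float = 0.01
    momentum: float = 0.9
    loss: str = "mse"  # "mse" (default) or "bce" for ablation
    epochs: int = 50
    deletion_rate: float = 0.10
    oversample_minority: bool = True
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.deletion_rate < 1:
            raise ValueError("deletion_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("mse", "bce"):
            raise ValueError("loss must be 'mse' or 'bce'")


def augment_delete(tokens: TokenSequence, deletion_rate: float,
                   rng: np.random.Generator) -> TokenSequence:
    """Remove round(rate * n) uniformly chosen taxa; order preserved, CLS kept."""
    n = len(tokens) - 1
    k = int(np.floor(deletion_rate * n + 0.5))
    if n == 0 or k == 0:
        return tokens
    drop = rng.choice(n, size=k, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    kept = tokens.taxa[keep]
    return TokenSequence(np.concatenate(([TaxonVocabulary.CLS], kept)), tokens.sample_id)


def freeze_encoder(model: EncoderModel) -> None:
    """Freeze encoder blocks and positional embeddings (fine-tuning regime).

    Disabling requires_grad also skips their gradient computation entirely.
    The embedding matrix keeps its per-row freeze (taxon rows frozen, CLS
    trainable, per the pre-training regime).
    """
    for p in model.parameters():
        if p.name.startswith("block") or p.name == "positional":
            p.trainable = False
            p.requires_grad = False


def _oversample_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-epoch index multiset with the minority class resampled to parity."""
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("fine-tuning requires both classes present")
    if len(pos) == len(neg):
        return rng.permutation(len(labels))
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    extra = rng.choice(minority, size=len(majority) - len(minority), replace=True)
    out = np.concatenate([majority, minority, extra])
    return out[rng.permutation(len(out))]


class PhenotypeClassifier:
    """Frozen-encoder binary phenotype classifier (sklearn-style fit/predict)."""

    def __init__(self, model: EncoderModel, config: FinetuneConfig | None = None):
        if model.head_kind != "cls_binary":
            raise ValueError("phenotype classifier requires a cls_binary head")
        self.model = model
        self.config = config or FinetuneConfig()
        self.history_: list[dict] = []

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "config": self.config}

    def set_params(self, **params) -> "PhenotypeClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _loss_batch(self, sequences: list[TokenSequence], labels: np.ndarray) -> Tensor:
        idx, lengths = self.model.pad_batch(sequences)
        states = self.model.forward_states(idx, lengths, training=True)
        cls = states.select((slice(None), 0))
        logits = self.model.head(cls).reshape(len(sequences))
        y = labels.astype(self.model.embedding.weight.data.dtype)
        if self.config.loss == "bce":
            return bce_logits(logits, y)
        p = logits.sigmoid()
        return (p - Tensor(y)).pow(2.0).mean()

    def fit(self, sequences: list[TokenSequence], labels: np.ndarray,
            epochs: int | None = None,
            validation: tuple[list[TokenSequence], np.ndarray] | None = None,
            ) -> "PhenotypeClassifier":
        cfg = self.config
        labels = np.asarray(labels)
        epochs = cfg.epochs if epochs is None else epochs
        freeze_encoder(self.model)
        enc_before = _frozen_checksums(self.model)
        rng = np.random.Generator(np.random.PCG64(cfg.seed))
        self.model._dropout_rng = np.random.Generator(np.random.PCG64(cfg.seed + 7))
        opt = SGD(self.model.trainable_parameters(), lr=cfg.learning_rate,
                  momentum=cfg.momentum)
        lengths = np.array([len(s) for s in sequences])
        self.history_ = []
        for epoch in range(epochs):
            order = (_oversample_indices(labels, rng) if cfg.oversample_minority
                     else rng.permutation(len(labels)))
            order = _bucket_by_length(order, lengths, cfg.batch_size, rng)
            total, n_batches = 0.0, 0
            with tape_arena():
                for start in range(0, len(order), cfg.batch_size):
                    batch_idx = order[start : start + cfg.batch_size]
                    batch = [
                        augment_delete(sequences[j], cfg.deletion_rate, rng)
                        for j in batch_idx
                    ]
                    opt.zero_grad()
                    loss = self._loss_batch(batch, labels[batch_idx])
                    loss.backward()
                    opt.step()
                    total += float(loss.data)
                    n_batches += 1
            entry = {"epoch": epoch + 1, "train_loss": total / max(n_batches, 1),
                     "n_seen_per_class": _seen_per_class(order, labels)}
            if validation is not None:
                from .evaluation import auroc

                val_scores = self.predict_proba(validation[0])
                entry["val_auroc"] = auroc(val_scores, validation[1])
            self.history_.append(entry)
        assert _frozen_checksums(self.model) == enc_before, "frozen parameters moved"
        return self

    def predict_proba(self, sequences: list[TokenSequence],
                      batch_size: int = 64) -> np.ndarray:
        out = np.empty(len(sequences))
        srt = np.argsort([len(s) for s in sequences], kind="stable")
        with tape_arena():
            for start in range(0, len(srt), batch_size):
                take = srt[start : start + batch_size]
                out[take] = self.model.classify_batch([sequences[i] for i in take])
        return out

    def predict(self, sequences: list[TokenSequence]) -> np.ndarray:
        return (self.predict_proba(sequences) >= 0.5).astype(int)


def _bucket_by_length(order: np.ndarray, lengths: np.ndarray, batch_size: int,
                      rng: np.random.Generator, bucket: int = 8) -> np.ndarray:
    """Sort each shuffled window by sequence length, then shuffle the batch
    order; reduces padding waste without biasing the curriculum."""
    window = batch_size * bucket
    chunks = []
    for i in range(0, len(order), window):
        chunk = order[i : i + window]
        chunks.append(chunk[np.argsort(lengths[chunk], kind="stable")])
    seq = np.concatenate(chunks)
    batches = [seq[j : j + batch_size] for j in range(0, len(seq), batch_size)]
    return np.concatenate([batches[k] for k in rng.permutation(len(batches))])


def _seen_per_class(order: np.ndarray, labels: np.ndarray) -> dict[int, int]:
    seen = labels[order]
    return {0: int((seen == 0).sum()), 1: int((seen == 1).sum())}


def _frozen_checksums(model: EncoderModel) -> str:
    import hashlib

    h = hashlib.sha256()
    for p in sorted(model.parameters(), key=lambda q: q.name):
        if p.name.startswith("block") or p.name == "positional":
            h.update(np.ascontiguousarray(p.data).tobytes())
    rows = model.embedding.weight.data[TaxonVocabulary.n_special:]
    h.update(np.ascontiguousarray(rows).tobytes())
    return h.hexdigest()


def make_classifier_model(encoder: EncoderModel, head_seed: int,
                          fresh_projection: bool = False) -> EncoderModel:
    """New cls_binary model inheriting the pre-trained encoder.

    The head (and optionally the projection) is freshly initialized from
    ``head_seed``; embedding, positional and block parameters are copied
    from the pre-trained encoder.
    """
    from .electra import _embeddings_of

    model = EncoderModel(encoder.cfg, encoder.vocab, _embeddings_of(encoder),
                         "cls_binary", rng_seed=head_seed)
    state = encoder.state_dict()
    for p in model.parameters():
        if p.name.startswith("head_"):
            continue
        if fresh_projection and p.name.startswith("projection"):
            continue
        if p.name in state:
            p.data = state[p.name].astype(p.data.dtype).copy()
    return model


def finetune(encoder: EncoderModel, sequences: list[TokenSequence],
             labels: np.ndarray, config: FinetuneConfig,
             stopping_epoch: int | None = None,
             validation: tuple[list[TokenSequence], np.ndarray] | None = None,
             ) -> PhenotypeClassifier:
    """Fine-tune a fresh CLS head on the frozen pre-trained encoder."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("fine-tuning corpus must contain both classes")
    model = make_classifier_model(encoder, head_seed=config.seed + 1000)
    clf = PhenotypeClassifier(model, config)
    clf.fit(sequences, labels, epochs=stopping_epoch, validation=validation)
    return clf


def select_stopping_epoch(encoder: EncoderModel, train: tuple[list, np.ndarray],
                          val: tuple[list, np.ndarray],
                          config: FinetuneConfig) -> tuple[int, PhenotypeClassifier]:
    """Best validation-AUROC epoch in 1..config.epochs (earliest on ties)."""
    if len(np.unique(np.asarray(val[1]))) < 2:
        raise ValueError("validation set must contain both classes")
    clf = finetune(encoder, train[0], np.asarray(train[1]), config, validation=val)
    curve = np.array([h["val_auroc"] for h in clf.history_])
    return int(np.argmax(curve)) + 1, clf


class EnsembleClassifier:
    """k single-epoch heads over one shared frozen encoder; mean aggregation."""

    def __init__(self, encoder: EncoderModel, k: int = 10,
                 config: FinetuneConfig | None = None):
        if k < 1:
            raise ValueError("ensemble size k must be >= 1")
        self.encoder = encoder
        self.k = k
        self.config = config or FinetuneConfig()
        self.members_: list[PhenotypeClassifier] = []

    def get_params(self, deep: bool = True) -> dict:
        return {"encoder": self.encoder, "k": self.k, "config": self.config}

    def set_params(self, **params) -> "EnsembleClassifier":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, sequences: list[TokenSequence], labels: np.ndarray,
            rng: np.random.Generator | None = None) -> "EnsembleClassifier":
        labels = np.asarray(labels)
        rng = rng or np.random.Generator(np.random.PCG64(self.config.seed))
        self.members_ = []
        for member in range(self.k):
            seed = int(rng.integers(0, 2**31 - 1))
            # members differ in their randomly initialized classification
            # heads (and training order); the pre-trained projection is kept
            # as the starting point, as in single-classifier fine-tuning
            model = make_classifier_model(self.encoder, head_seed=seed,
                                          fresh_projection=False)
            cfg = replace(self.config, seed=seed)
            member_clf = PhenotypeClassifier(model, cfg)
            member_clf.fit(sequences, labels, epochs=1)
            self.members_.append(member_clf)
        return self

    def member_probas(self, sequences: list[TokenSequence]) -> np.ndarray:
        """(k, n) matrix of member probabilities."""
        if not self.members_:
            raise RuntimeError("ensemble not fitted")
        return np.stack([m.predict_proba(sequences) for m in self.members_])

    def predict_proba(self, sequences: list[TokenSequence]) -> np.ndarray:
        return self.member_probas(sequences).mean(axis=0)

    def predict(self, sequences: list[TokenSequence]) -> np.ndarray:
        return (self.predict_proba(sequences) >= 0.5).astype(int)


def train_ensemble(encoder: EncoderModel, sequences: list[TokenSequence],
                   labels: np.ndarray, k: int, rng: np.random.Generator,
                   config: FinetuneConfig | None = None) -> EnsembleClassifier:
    """k independently initialized heads, each fine-tuned exactly one epoch."""
    ens = EnsembleClassifier(encoder, k=k, config=config)
    return ens.fit(sequences, np.asarray(labels), rng=rng)
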
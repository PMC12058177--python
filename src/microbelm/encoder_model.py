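"""Transformer encoder for rank-tokenized microbiome samples.

Architecture: a frozen taxon embedding layer (vocabulary embeddings, e.g.
GloVe co-occurrence vectors, 100-d), a trainable linear projection into a
200-d hidden space, learned absolute positional embeddings over rank
positions, five post-norm encoder blocks, and a swappable two-layer head:

* ``token_vocab``  — per-token distribution over the vocabulary (generator),
* ``token_binary`` — per-token real-vs-modified probability (discriminator),
* ``cls_binary``   — sample-level phenotype probability read off the CLS state.

Taxon embedding rows stay frozen throughout; the CLS and MASK rows are
trainable.  PAD positions are excluded from attention keys and from every
loss.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor, dropout, no_grad, softmax
from .corpus_io import EmbeddingMatrix, TaxonVocabulary, TokenSequence

HEAD_KINDS = ("token_vocab", "token_binary", "cls_binary")


@dataclass
class ModelConfig:
    vocab_size: int  # taxa + special tokens
    embed_dim: int = 100
    hidden_dim: int = 200
    n_blocks: int = 5
    n_heads: int = 4
    ff_dim: int | None = None  # default 4 x hidden_dim
    max_positions: int = 513
    head_hidden: int = 200
    dropout: float = 0.1
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.ff_dim is None:
            self.ff_dim = 4 * self.hidden_dim
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def parameter_count(cfg: ModelConfig, head: str) -> int:
    """Closed-form parameter count for the configured architecture."""
    d, e, f = cfg.hidden_dim, cfg.embed_dim, cfg.ff_dim
    n = cfg.vocab_size * e  # embedding
    n += cfg.max_positions * d  # positional
    n += e * d + d  # projection
    per_block = (d * 3 * d + 3 * d) + (d * d + d) + 2 * (2 * d)  # qkv, out, 2 LN
    per_block += (d * f + f) + (f * d + d)  # feed-forward
    n += cfg.n_blocks * per_block
    out = cfg.vocab_size if head == "token_vocab" else 1
    n += d * cfg.head_hidden + cfg.head_hidden + cfg.head_hidden * out + out
    return n


class EncoderModel(nn.Module):
    """Embedding + projection + positional + encoder blocks + one head."""

    def __init__(self, cfg: ModelConfig, vocab: TaxonVocabulary,
                 vocab_embeddings: EmbeddingMatrix, head: str, rng_seed: int | None = None):
        if head not in HEAD_KINDS:
            raise ValueError(f"head must be one of {HEAD_KINDS}")
        if vocab.size != cfg.vocab_size:
            raise ValueError("config vocab_size does not match vocabulary")
        if vocab_embeddings.dim != cfg.embed_dim:
            raise ValueError(
                f"embedding dim {vocab_embeddings.dim} != config embed_dim {cfg.embed_dim}"
            )
        missing = vocab_embeddings.missing_taxa(vocab)
        if missing:
            raise ValueError(f"vocabulary embeddings missing taxa: {missing[:10]}")
        self.cfg = cfg
        self.vocab = vocab
        self.head_kind = head
        dtype = np.dtype(cfg.dtype)
        seed = cfg.seed if rng_seed is None else rng_seed
        rng = np.random.Generator(np.random.PCG64(seed))
        self._dropout_rng = np.random.Generator(np.random.PCG64(seed + 1))

        weight = np.zeros((cfg.vocab_size, cfg.embed_dim), dtype=dtype)
        # CLS and MASK rows: trainable seeded random draws; PAD stays zero.
        weight[TaxonVocabulary.CLS] = rng.standard_normal(cfg.embed_dim) * 0.1
        weight[TaxonVocabulary.MASK] = rng.standard_normal(cfg.embed_dim) * 0.1
        weight[TaxonVocabulary.n_special:] = vocab_embeddings.as_array(vocab.taxon_ids)
        frozen = np.ones(cfg.vocab_size, dtype=bool)
        frozen[[TaxonVocabulary.CLS, TaxonVocabulary.MASK]] = False
        self.embedding = nn.Embedding(weight, "embedding", frozen_rows=frozen)

        self.projection = nn.Linear(cfg.embed_dim, cfg.hidden_dim, rng, "projection", dtype)
        self.positional = nn.Parameter(
            (rng.standard_normal((cfg.max_positions, cfg.hidden_dim)) * 0.02).astype(dtype),
            "positional",
        )
        self.blocks = [
            nn.EncoderBlock(cfg.hidden_dim, cfg.n_heads, cfg.ff_dim, cfg.dropout,
                            rng, f"block{i}", dtype)
            for i in range(cfg.n_blocks)
        ]
        out_dim = cfg.vocab_size if head == "token_vocab" else 1
        self.head = nn.TwoLayerHead(cfg.hidden_dim, cfg.head_hidden, out_dim, rng,
                                    f"head_{head}", dtype)

    # -- batching -------------------------------------------------------
    def pad_batch(self, sequences: list[TokenSequence]) -> tuple[np.ndarray, np.ndarray]:
        """Right-pad with PAD=0; returns (indices (B,S), lengths (B,))."""
        lengths = np.array([len(s) for s in sequences], dtype=np.int64)
        s_max = int(lengths.max())
        if s_max > self.cfg.max_positions:
            raise ValueError(
                f"sequence length {s_max} exceeds max_positions {self.cfg.max_positions}"
            )
        idx = np.zeros((len(sequences), s_max), dtype=np.int64)
        for i, seq in enumerate(sequences):
            idx[i, : lengths[i]] = seq.token_indices
        return idx, lengths

    def forward_states(self, idx: np.ndarray, lengths: np.ndarray,
                       training: bool = False) -> Tensor:
        """Final-block hidden states, shape (B, S, hidden_dim)."""
        b, s = idx.shape
        dtype = np.dtype(self.cfg.dtype)
        x = self.embedding(idx)
        x = self.projection(x)
        x = x + self.positional.select((slice(0, s),))
        x = dropout(x, self.cfg.dropout, self._dropout_rng, training)
        key_pad = (np.arange(s)[None, :] >= lengths[:, None])
        attn_bias = np.where(key_pad, np.array(-1e9, dtype=dtype), np.array(0, dtype=dtype))
        attn_bias = attn_bias[:, None, None, :]
        for block in self.blocks:
            x = block(x, attn_bias, self._dropout_rng, training)
        return x

    def head_logits(self, states: Tensor) -> Tensor:
        return self.head(states)

    # -- core operations -------------------------------------------------
    def encode(self, tokens: TokenSequence) -> dict[str, np.ndarray]:
        """Deterministic inference encoding of a single sequence."""
        with no_grad():
            idx, lengths = self.pad_batch([tokens])
            states = self.forward_states(idx, lengths, training=False)
        token_states = states.data[0]
        return {"token_states": token_states, "cls_state": token_states[0]}

    def classify_batch(self, sequences: list[TokenSequence]) -> np.ndarray:
        """Phenotype probabilities for a batch (cls_binary head, inference)."""
        if self.head_kind != "cls_binary":
            raise ValueError("classify requires a cls_binary head")
        with no_grad():
            idx, lengths = self.pad_batch(sequences)
            states = self.forward_states(idx, lengths, training=False)
            cls = states.select((slice(None), 0))
            logits = self.head(cls)
        return 1.0 / (1.0 + np.exp(-logits.data[:, 0].astype(np.float64)))

    def classify_sample(self, tokens: TokenSequence) -> float:
        return float(self.classify_batch([tokens])[0])

    def token_predictions(self, tokens: TokenSequence) -> np.ndarray:
        """Per-token vocab distribution (generator) or binary probability
        (discriminator), inference mode."""
        if self.head_kind == "cls_binary":
            raise ValueError("token_predictions requires a token-level head")
        with no_grad():
            idx, lengths = self.pad_batch([tokens])
            states = self.forward_states(idx, lengths, training=False)
            logits = self.head(states)
            if self.head_kind == "token_vocab":
                return softmax(logits, axis=-1).data[0].astype(np.float64)
            return (1.0 / (1.0 + np.exp(-logits.data[0, :, 0]))).astype(np.float64)

    def clone_encoder_into(self, other: "EncoderModel") -> None:
        """Copy embedding/projection/positional/block parameters to ``other``."""
        state = self.state_dict()
        own_head = f"head_{self.head_kind}"
        for p in other.parameters():
            if p.name.startswith("head_"):
                continue
            p.data = state[p.name].copy()

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = self.state_dict()
        meta = {"config": asdict(self.cfg), "head": self.head_kind,
                "vocab_hash": self.vocab.content_hash(),
                "taxon_ids": self.vocab.taxon_ids}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path, vocab_embeddings: EmbeddingMatrix | None = None,
             head: str | None = None) -> "EncoderModel":
        with np.load(path if str(path).endswith(".npz") else f"{path}") as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        cfg = ModelConfig(**meta["config"])
        vocab = TaxonVocabulary(meta["taxon_ids"])
        if vocab.content_hash() != meta["vocab_hash"]:
            raise ValueError("vocabulary hash mismatch in checkpoint")
        if vocab_embeddings is None:
            import pandas as pd

            emb = arrays["embedding.weight"][TaxonVocabulary.n_special:]
            vocab_embeddings = EmbeddingMatrix(
                pd.DataFrame(np.asarray(emb, dtype=float), index=vocab.taxon_ids)
            )
        model = cls(cfg, vocab, vocab_embeddings, head or meta["head"])
        if head is None or head == meta["head"]:
            model.load_state_dict(arrays)
        else:  # head swap: load encoder weights only, keep fresh head
            for p in model.parameters():
                if not p.name.startswith("head_"):
                    p.data = arrays[p.name].astype(p.data.dtype).copy()
        return model


def build_model(cfg: ModelConfig, vocab: TaxonVocabulary,
                vocab_embeddings: EmbeddingMatrix, head: str,
                rng_seed: int | None = None) -> EncoderModel:
    """Construct an :class:`EncoderModel` (functional alias)."""
    return EncoderModel(cfg, vocab, vocab_embeddings, head, rng_seed)


def encoder_checksum(model: EncoderModel) -> str:
    """Checksum over encoder-only parameters (blocks + positional)."""
    names = [p.name for p in model.parameters()
             if p.name.startswith("block") or p.name == "positional"]
    return model.checksum(names)


def taxon_embedding_checksum(model: EncoderModel) -> str:
    import hashlib

    rows = model.embedding.weight.data[TaxonVocabulary.n_special:]
    return hashlib.sha256(np.ascontiguousarray(rows).tobytes()).hexdigest()
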
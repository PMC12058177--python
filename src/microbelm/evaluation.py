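"""Evaluation protocol: patient-blocked splitting, AUROC/AUPR, the
stopping-epoch selection protocol, and the abundance-weighted embedding
baseline.

The protocol (per run): block out 20% of patients (and all their samples)
for testing; split the remaining 80% into train/validation (default 75/25
by patient) to pick the best stopping epoch by validation AUROC; refit from
scratch on all non-test data for that many epochs; score the test set.
Runs are repeated with independent seeds and reported as mean (sd).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .corpus_io import EmbeddingMatrix, AbundanceTable, TokenSequence
from .encoder_model import EncoderModel
from .finetune import FinetuneConfig, finetune, select_stopping_epoch


@dataclass
class SplitSpec:
    test_fraction: float = 0.20
    validation_fraction: float = 0.25  # of the non-test portion
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1 or not 0 < self.validation_fraction < 1:
            raise ValueError("fractions must be in (0, 1)")


@dataclass
class MetricReport:
    auroc: float
    aupr: float
    n_pos: int
    n_neg: int
    seed: int


def patient_blocked_split(patient_ids: np.ndarray, spec: SplitSpec,
                          ) -> dict[str, np.ndarray]:
    """Sample-index partition {train, validation, test}; a patient's samples
    never straddle partitions."""
    patient_ids = np.asarray(patient_ids)
    patients = np.unique(patient_ids)
    if len(patients) < 3:
        raise ValueError("need at least 3 patients to form 3 partitions")
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    order = rng.permutation(patients)
    n_test = max(1, round(spec.test_fraction * len(patients)))
    n_val = max(1, round(spec.validation_fraction * (len(patients) - n_test)))
    test_p = set(order[:n_test])
    val_p = set(order[n_test : n_test + n_val])
    part = {
        "test": np.nonzero([p in test_p for p in patient_ids])[0],
        "validation": np.nonzero([p in val_p for p in patient_ids])[0],
    }
    assigned = test_p | val_p
    part["train"] = np.nonzero([p not in assigned for p in patient_ids])[0]
    return part


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPR undefined with a single class")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def metric_report(scores: np.ndarray, labels: np.ndarray, seed: int = 0) -> MetricReport:
    labels = np.asarray(labels)
    return MetricReport(auroc(scores, labels), aupr(scores, labels),
                        int((labels == 1).sum()), int((labels == 0).sum()), seed)


def run_protocol(encoder: EncoderModel, sequences: list[TokenSequence],
                 labels: np.ndarray, patient_ids: np.ndarray,
                 split: SplitSpec, config: FinetuneConfig,
                 n_runs: int = 5, return_models: bool = False):
    """Stopping-epoch selection protocol, repeated over seeded runs.

    Returns one row per run (auroc, aupr, stopping_epoch); mean/sd via
    ``summarize_runs``.  Test patients never influence stopping-epoch
    selection (disjoint patient sets by construction).  With
    ``return_models`` also returns the refit classifier and partition of
    each run.
    """
    labels = np.asarray(labels)
    rows = []
    models = []
    for run in range(n_runs):
        run_seed = split.seed + 1000 * run
        part = patient_blocked_split(patient_ids, replace(split, seed=run_seed))
        tr, va, te = part["train"], part["validation"], part["test"]
        assert not (set(patient_ids[te]) & set(patient_ids[tr]) | set(patient_ids[te]) & set(patient_ids[va]))
        cfg = replace(config, seed=run_seed)
        best_epoch, _ = select_stopping_epoch(
            encoder,
            ([sequences[i] for i in tr], labels[tr]),
            ([sequences[i] for i in va], labels[va]),
            cfg,
        )
        nontest = np.concatenate([tr, va])
        clf = finetune(encoder, [sequences[i] for i in nontest], labels[nontest],
                       replace(cfg, seed=run_seed + 17), stopping_epoch=best_epoch)
        scores = clf.predict_proba([sequences[i] for i in te])
        rows.append({"run": run, "seed": run_seed, "stopping_epoch": best_epoch,
                     "auroc": auroc(scores, labels[te]),
                     "aupr": aupr(scores, labels[te]),
                     "n_pos": int((labels[te] == 1).sum()),
                     "n_neg": int((labels[te] == 0).sum())})
        if return_models:
            models.append({"classifier": clf, "partition": part})
    df = pd.DataFrame(rows)
    return (df, models) if return_models else df


def summarize_runs(runs: pd.DataFrame) -> dict:
    return {
        "auroc_mean": float(runs["auroc"].mean()),
        "auroc_sd": float(runs["auroc"].std(ddof=1)) if len(runs) > 1 else 0.0,
        "aupr_mean": float(runs["aupr"].mean()),
        "aupr_sd": float(runs["aupr"].std(ddof=1)) if len(runs) > 1 else 0.0,
        "n_runs": int(len(runs)),
    }


def weighted_baseline(embeddings: EmbeddingMatrix, table: AbundanceTable,
                      ) -> pd.DataFrame:
    """Abundance-weighted average of each sample's vocabulary embeddings.

    Taxa without an embedding are dropped with renormalization over the
    covered taxa.  Samples with no covered taxon are rejected.
    """
    covered = [t for t in table.taxon_ids if t in embeddings.vectors.index]
    if not covered:
        raise ValueError("no sample taxa covered by the embedding matrix")
    sub = table.values[covered].to_numpy()
    weights_sum = sub.sum(axis=1)
    empty = weights_sum <= 0
    if empty.any():
        raise ValueError(
            f"sample {table.sample_ids[int(np.nonzero(empty)[0][0])]!r} has no "
            "taxa covered by the embedding matrix")
    emb = embeddings.as_array(covered)
    vectors = (sub @ emb) / weights_sum[:, None]
    return pd.DataFrame(vectors, index=table.values.index)


class WeightedEmbeddingClassifier:
    """The Weighted baseline: the same two-layer MLP head class applied to
    abundance-weighted vocabulary-embedding sample vectors."""

    def __init__(self, embeddings: EmbeddingMatrix, config: FinetuneConfig | None = None,
                 hidden: int = 200):
        self.embeddings = embeddings
        self.config = config or FinetuneConfig()
        self.hidden = hidden
        self._head = None

    def get_params(self, deep: bool = True) -> dict:
        return {"embeddings": self.embeddings, "config": self.config,
                "hidden": self.hidden}

    def set_params(self, **params) -> "WeightedEmbeddingClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, table: AbundanceTable, labels: np.ndarray,
            epochs: int | None = None) -> "WeightedEmbeddingClassifier":
        from .autograd import Tensor
        from .finetune import _oversample_indices
        from .nn import SGD, TwoLayerHead

        cfg = self.config
        x = weighted_baseline(self.embeddings, table).to_numpy().astype(np.float32)
        y = np.asarray(labels)
        rng = np.random.Generator(np.random.PCG64(cfg.seed))
        self._head = TwoLayerHead(x.shape[1], self.hidden, 1, rng, "weighted_head")
        opt = SGD(self._head.trainable_parameters(), lr=cfg.learning_rate,
                  momentum=cfg.momentum)
        for _ in range(cfg.epochs if epochs is None else epochs):
            order = (_oversample_indices(y, rng) if cfg.oversample_minority
                     else rng.permutation(len(y)))
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                opt.zero_grad()
                logits = self._head(Tensor(x[idx])).reshape(len(idx))
                target = y[idx].astype(np.float32)
                loss = (logits.sigmoid() - Tensor(target)).pow(2.0).mean()
                loss.backward()
                opt.step()
        return self

    def predict_proba(self, table: AbundanceTable) -> np.ndarray:
        from .autograd import Tensor, no_grad

        if self._head is None:
            raise RuntimeError("classifier not fitted")
        x = weighted_baseline(self.embeddings, table).to_numpy().astype(np.float32)
        with no_grad():
            logits = self._head(Tensor(x)).data[:, 0]
        return 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
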
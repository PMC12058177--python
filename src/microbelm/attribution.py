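"""Feature-ablation attribution and cross-dataset marker validation.

For a probability-valued classifier M and a dataset D, the attribution of
taxon m is the expected drop in predicted positive probability when m is
deleted from the samples that contain it:

    a(m) = (1 / |D_m|) * sum_{X in D_m} [ M(X) - M(X \\ m) ]

where D_m is the set of samples containing m and X \\ m is the sample with
m removed (survivors re-compacted into a valid rank sequence).  Positive
a(m) means the taxon pushes the model toward a positive call.

The validation pipeline mirrors a two-population marker study: restrict
each dataset to confident, correctly classified samples; drop rare taxa;
compute per-dataset attributions; require adequate support in both
datasets and a matching attribution sign; report the combined-sample mean
attribution ranked by magnitude within each sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .corpus_io import TaxonVocabulary, TokenSequence

logger = logging.getLogger(__name__)


class ProbabilityModel(Protocol):
    """Anything mapping token sequences to positive-class probabilities."""

    def predict_proba(self, sequences: list[TokenSequence]) -> np.ndarray: ...


@dataclass
class AttributionRecord:
    taxon_id: str
    a_value: float
    support: int
    dataset: str = ""

    def __post_init__(self):
        if self.support < 1:
            raise ValueError("support must be >= 1")
        if not -1.0 <= self.a_value <= 1.0:
            raise ValueError("attribution must lie in [-1, 1]")


@dataclass
class ValidationFilterSpec:
    confidence_quantile: float = 0.5
    min_prevalence: float = 0.05
    min_support_per_dataset: int = 5
    require_sign_match: bool = True

    def __post_init__(self):
        if not 0 < self.confidence_quantile <= 1:
            raise ValueError("confidence_quantile must be in (0, 1]")
        if not 0 <= self.min_prevalence <= 1:
            raise ValueError("min_prevalence must be in [0, 1]")


def ablate(tokens: TokenSequence, taxon_index: int) -> TokenSequence:
    """Remove one taxon; survivors keep their relative order (ranks re-compact)."""
    taxa = tokens.taxa
    keep = taxa != taxon_index
    if keep.all():
        raise ValueError(f"taxon index {taxon_index} not present in sequence")
    return TokenSequence(np.concatenate(([TaxonVocabulary.CLS], taxa[keep])),
                         tokens.sample_id)


def attribute_taxon(model: ProbabilityModel, dataset: Sequence[TokenSequence],
                    taxon_index: int, dataset_tag: str = "",
                    vocab: TaxonVocabulary | None = None) -> AttributionRecord:
    """a(m) for one taxon over the samples of ``dataset`` that contain it."""
    containing = [seq for seq in dataset if taxon_index in seq.taxa]
    if not containing:
        raise ValueError(f"taxon index {taxon_index} appears in no sample")
    originals = model.predict_proba(list(containing))
    ablated = model.predict_proba([ablate(seq, taxon_index) for seq in containing])
    a = float(np.mean(originals - ablated))
    name = vocab.taxon(taxon_index) if vocab is not None else str(taxon_index)
    return AttributionRecord(name, a, len(containing), dataset_tag)


def attribute_all(model: ProbabilityModel, dataset: Sequence[TokenSequence],
                  taxon_indices: Sequence[int] | None = None,
                  batch_size: int = 64) -> dict[int, tuple[float, int]]:
    """a(m) for many taxa at once: taxon index -> (a_value, support).

    Scores each sample once, then batches all single-taxon ablations of the
    sample through the model together.
    """
    wanted = None if taxon_indices is None else set(int(t) for t in taxon_indices)
    base = np.empty(len(dataset))
    for start in range(0, len(dataset), batch_size):
        base[start : start + batch_size] = model.predict_proba(
            list(dataset[start : start + batch_size]))
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i, seq in enumerate(dataset):
        targets = [int(t) for t in seq.taxa if wanted is None or int(t) in wanted]
        if not targets:
            continue
        ablated = [ablate(seq, t) for t in targets]
        probs = np.empty(len(ablated))
        for start in range(0, len(ablated), batch_size):
            probs[start : start + batch_size] = model.predict_proba(
                ablated[start : start + batch_size])
        for t, p in zip(targets, probs):
            sums[t] = sums.get(t, 0.0) + (base[i] - p)
            counts[t] = counts.get(t, 0) + 1
    return {t: (sums[t] / counts[t], counts[t]) for t in sums}


def filter_confident_correct(probs: np.ndarray, labels: np.ndarray,
                             quantile: float = 0.5) -> np.ndarray:
    """Indices of correct predictions in the top confidence quantile.

    Correctness is judged at threshold 0.5; confidence is the predicted
    probability of the predicted class, ranked pooled across classes.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    pred = (probs >= 0.5).astype(int)
    correct = np.nonzero(pred == labels)[0]
    if len(correct) == 0:
        logger.warning("no correctly classified samples; empty confident set")
        return correct
    confidence = np.where(pred[correct] == 1, probs[correct], 1.0 - probs[correct])
    k = int(np.ceil(quantile * len(correct)))
    order = np.argsort(-confidence, kind="stable")
    return np.sort(correct[order[:k]])


def _prevalence(datasets: Sequence[Sequence[TokenSequence]]) -> dict[int, float]:
    counts: dict[int, int] = {}
    n = 0
    for ds in datasets:
        n += len(ds)
        for seq in ds:
            for t in seq.taxa:
                counts[int(t)] = counts.get(int(t), 0) + 1
    return {t: c / n for t, c in counts.items()}


def validate_attributions(model: ProbabilityModel,
                          dataset_a: tuple[Sequence[TokenSequence], np.ndarray],
                          dataset_b: tuple[Sequence[TokenSequence], np.ndarray],
                          spec: ValidationFilterSpec,
                          vocab: TaxonVocabulary | None = None) -> pd.DataFrame:
    """Cross-dataset attribution validation pipeline.

    Returns a DataFrame (one row per validated taxon) with per-dataset and
    combined attributions, ranked by magnitude within each sign.  Attaches
    stage-by-stage survivor counts as ``df.attrs["stages"]``.
    """
    seqs_a, labels_a = list(dataset_a[0]), np.asarray(dataset_a[1])
    seqs_b, labels_b = list(dataset_b[0]), np.asarray(dataset_b[1])
    stages: dict[str, int] = {}

    # 1. confident-correct filtering per dataset
    keep_a = filter_confident_correct(model.predict_proba(seqs_a), labels_a,
                                      spec.confidence_quantile)
    keep_b = filter_confident_correct(model.predict_proba(seqs_b), labels_b,
                                      spec.confidence_quantile)
    conf_a = [seqs_a[i] for i in keep_a]
    conf_b = [seqs_b[i] for i in keep_b]
    stages["confident_correct_a"] = len(conf_a)
    stages["confident_correct_b"] = len(conf_b)

    # 2. prevalence over ALL samples of the combined datasets (pre-filtering)
    prevalence = _prevalence([seqs_a, seqs_b])
    stages["taxa_observed"] = len(prevalence)
    common = {t for t, p in prevalence.items() if p >= spec.min_prevalence}
    stages["taxa_min_prevalence"] = len(common)

    # 3. per-dataset attributions with support filter
    attr_a = attribute_all(model, conf_a, sorted(common))
    attr_b = attribute_all(model, conf_b, sorted(common))
    both = {
        t for t in common
        if attr_a.get(t, (0, 0))[1] >= spec.min_support_per_dataset
        and attr_b.get(t, (0, 0))[1] >= spec.min_support_per_dataset
    }
    stages["taxa_min_support"] = len(both)

    # 4. sign match between the two datasets
    if spec.require_sign_match:
        validated = {t for t in both
                     if np.sign(attr_a[t][0]) == np.sign(attr_b[t][0])
                     and attr_a[t][0] != 0.0}
    else:
        validated = both
    stages["taxa_sign_matched"] = len(validated)

    # 5. combined attribution over the pooled confident-correct samples
    combined = attribute_all(model, conf_a + conf_b, sorted(validated))
    rows = []
    for t in sorted(validated):
        a_comb, support = combined[t]
        rows.append({
            "taxon_id": vocab.taxon(t) if vocab is not None else str(t),
            "taxon_index": t,
            "a_combined": a_comb,
            "a_A": attr_a[t][0], "a_B": attr_b[t][0],
            "support_A": attr_a[t][1], "support_B": attr_b[t][1],
        })
    df = pd.DataFrame(rows, columns=["taxon_id", "taxon_index", "a_combined",
                                     "a_A", "a_B", "support_A", "support_B"])
    if len(df):
        # descending magnitude within each sign; ties by support then taxon id
        df["_sign"] = np.sign(df["a_combined"])
        df["_mag"] = df["a_combined"].abs()
        df = df.sort_values(["_sign", "_mag", "support_A", "taxon_id"],
                            ascending=[False, False, False, True])
        df = df.drop(columns=["_sign", "_mag"]).reset_index(drop=True)
    if not len(df):
        logger.warning("no taxa survived validation; stages: %s", stages)
    df.attrs["stages"] = stages
    return df
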
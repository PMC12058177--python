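"""Quantitative evaluation of taxon embedding spaces.

A taxon's *contextualized* embedding is its final-encoder-block state,
which varies with the surrounding community; averaging over every
occurrence gives one vector per taxon.  This module compares such spaces
(or raw vocabulary embeddings) against external structure:

* taxonomy — k-means phylum-purity curves over a range of k;
* metabolic pathways — Spearman correlation of every embedding dimension
  against every binary pathway-membership column, with a permutation test
  (default 1,000 permutations of taxon order) deciding which correlations
  beat the pooled null maximum (effective p < 0.001);
* two embedding spaces — Kolmogorov-Smirnov and Epps-Singleton tests plus
  Cliff's delta on their significant correlation magnitudes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .autograd import no_grad, tape_arena
from .corpus_io import TokenSequence
from .encoder_model import EncoderModel

logger = logging.getLogger(__name__)


def mean_contextual_embeddings(model: EncoderModel, corpus: list[TokenSequence],
                               top_n_taxa: int | None = None,
                               batch_size: int = 64) -> pd.DataFrame:
    """Mean final-block state per taxon over all its occurrences.

    Restricts to the ``top_n_taxa`` most frequent taxa (ties broken by
    ascending taxon index).  Returns a DataFrame indexed by taxon id with
    hidden-dim columns plus an ``n_occurrences`` column.
    """
    counts: dict[int, int] = {}
    for seq in corpus:
        for t in seq.taxa:
            counts[int(t)] = counts.get(int(t), 0) + 1
    if not counts:
        raise ValueError("corpus contains no taxa")
    ranked = sorted(counts, key=lambda t: (-counts[t], t))
    if top_n_taxa is not None:
        if top_n_taxa < 1:
            raise ValueError("top_n_taxa must be >= 1")
        ranked = ranked[:top_n_taxa]
    wanted = set(ranked)
    d = model.cfg.hidden_dim
    sums = {t: np.zeros(d) for t in ranked}
    with no_grad(), tape_arena():
        for start in range(0, len(corpus), batch_size):
            batch = corpus[start : start + batch_size]
            idx, lengths = model.pad_batch(batch)
            states = model.forward_states(idx, lengths, training=False).data
            for i, seq in enumerate(batch):
                toks = seq.token_indices
                for pos in range(1, len(toks)):
                    t = int(toks[pos])
                    if t in wanted:
                        sums[t] += states[i, pos]
    rows = np.stack([sums[t] / counts[t] for t in ranked])
    df = pd.DataFrame(rows, index=[model.vocab.taxon(t) for t in ranked],
                      columns=[f"h{j}" for j in range(d)])
    df["n_occurrences"] = [counts[t] for t in ranked]
    return df


def cluster_purity(assignments: np.ndarray, labels: np.ndarray) -> float:
    """Size-weighted purity: (1/N) * sum over clusters of the modal label count."""
    total = 0
    for c in np.unique(assignments):
        members = labels[assignments == c]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return total / len(labels)


def purity_curve(embeddings: np.ndarray, labels: np.ndarray,
                 k_values: list[int], n_restarts: int = 10,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """K-means label purity (e.g., phylum purity) as a function of k."""
    embeddings = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    if pd.isna(labels).any():
        bad = np.nonzero(pd.isna(labels))[0][:10]
        raise ValueError(f"unlabeled points at indices {bad.tolist()}")
    rng = rng or np.random.default_rng(0)
    rows = []
    for k in k_values:
        if k > len(embeddings):
            raise ValueError(f"k={k} exceeds number of points {len(embeddings)}")
        if k == len(embeddings):
            rows.append({"k": k, "purity": 1.0})
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++",
                    random_state=int(rng.integers(0, 2**31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assign = km.fit_predict(embeddings)
        rows.append({"k": k, "purity": cluster_purity(assign, labels)})
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    """Spearman matrix (dims x pathways) with optional significance mask."""

    correlations: np.ndarray
    constant_flags: np.ndarray  # True where a pathway column was constant
    mask: np.ndarray | None = None
    null_summary: dict = field(default_factory=dict)


def _rank_standardize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise average ranks, centered and scaled to unit norm.

    Returns (z, constant) where constant marks zero-variance columns
    (their z column is left at zero, so any product correlation is 0).
    """
    n, m = mat.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, np.asarray(mat, dtype=float))
    ranks -= ranks.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(ranks, axis=0)
    constant = norms == 0
    norms[constant] = 1.0
    return ranks / norms, constant


def pathway_correlations(embeddings: pd.DataFrame | np.ndarray,
                         pathways: pd.DataFrame) -> CorrelationResult:
    """Spearman r of every embedding dimension against every pathway column.

    Inputs are intersected on taxon id when both carry an index.  Constant
    pathway columns (rank correlation undefined) are recorded as r = 0 and
    flagged.
    """
    if isinstance(embeddings, pd.DataFrame):
        shared = embeddings.index.intersection(pathways.index)
        if len(shared) < 3:
            raise ValueError("need at least 3 shared taxa")
        emb = embeddings.loc[shared].to_numpy(dtype=float)
        pw = pathways.loc[shared].to_numpy(dtype=float)
    else:
        emb = np.asarray(embeddings, dtype=float)
        pw = pathways.to_numpy(dtype=float) if isinstance(pathways, pd.DataFrame) else np.asarray(pathways, dtype=float)
        if len(emb) < 3:
            raise ValueError("need at least 3 shared taxa")
    ze, const_e = _rank_standardize(emb)
    zp, const_p = _rank_standardize(pw)
    corr = ze.T @ zp
    corr[const_e, :] = 0.0
    corr[:, const_p] = 0.0
    if const_p.any():
        logger.warning("%d constant pathway columns; their r recorded as 0",
                       int(const_p.sum()))
    return CorrelationResult(correlations=corr, constant_flags=const_p)


def permutation_mask(embeddings: pd.DataFrame | np.ndarray, pathways: pd.DataFrame,
                     n_perm: int = 1000, rng: np.random.Generator | None = None,
                     per_cell: bool = False) -> CorrelationResult:
    """Permutation-test significance mask for the Spearman matrix.

    The null is built by permuting the taxon order of the embedding table
    ``n_perm`` times and recomputing the full correlation matrix.  Under
    the default pooled criterion a cell is significant iff its |r|
    strictly exceeds every correlation magnitude in the pooled null
    (effective p < 1/n_perm per the strictest reading); ``per_cell=True``
    compares each cell against its own null maximum instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng or np.random.default_rng(0)
    if isinstance(embeddings, pd.DataFrame):
        shared = embeddings.index.intersection(pathways.index)
        emb = embeddings.loc[shared].to_numpy(dtype=float)
        pw = pathways.loc[shared].to_numpy(dtype=float)
    else:
        emb = np.asarray(embeddings, dtype=float)
        pw = pathways.to_numpy(dtype=float) if isinstance(pathways, pd.DataFrame) else np.asarray(pathways, dtype=float)
    ze, _ = _rank_standardize(emb)
    zp, const_p = _rank_standardize(pw)
    observed = ze.T @ zp
    observed[:, const_p] = 0.0
    n = len(ze)
    pooled_max = 0.0
    cell_max = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        null = np.abs(ze[perm].T @ zp)
        pooled_max = max(pooled_max, float(null.max()))
        np.maximum(cell_max, null, out=cell_max)
    threshold = cell_max if per_cell else pooled_max
    mask = np.abs(observed) > threshold
    mask[:, const_p] = False
    return CorrelationResult(
        correlations=observed, constant_flags=const_p, mask=mask,
        null_summary={"pooled_max": pooled_max, "n_perm": n_perm,
                      "per_cell": per_cell},
    )


def cliffs_delta(a: np.ndarray, b: np.ndarray) -> float:
    """(#(a>b) - #(a<b)) / (n*m) over all cross-set pairs."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float(((a > b).sum() - (a < b).sum()) / (a.shape[0] * b.shape[1]))


def compare_magnitude_distributions(sig_a: np.ndarray, sig_b: np.ndarray) -> dict:
    """KS and Epps-Singleton p-values plus Cliff's delta of A vs B."""
    sig_a = np.asarray(sig_a, dtype=float)
    sig_b = np.asarray(sig_b, dtype=float)
    if len(sig_a) == 0 or len(sig_b) == 0:
        raise ValueError("both sets of significant correlations must be nonempty")
    out: dict = {
        "ks_p": float(stats.ks_2samp(sig_a, sig_b).pvalue),
        "cliffs_delta": cliffs_delta(sig_a, sig_b),
        "n_a": len(sig_a), "n_b": len(sig_b),
    }
    if min(len(sig_a), len(sig_b)) < 5:
        warnings.warn("fewer than 5 values in a set; Epps-Singleton omitted",
                      stacklevel=2)
        out["epps_singleton_p"] = None
    else:
        out["epps_singleton_p"] = float(
            stats.epps_singleton_2samp(sig_a, sig_b).pvalue)
    return out
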
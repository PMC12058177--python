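"""Tabular input/output and rank tokenization.

Microbiome samples arrive as relative-abundance vectors (samples x taxa).
To feed a transformer they are converted into "text-like" inputs: the taxa
present in a sample, sorted by decreasing abundance, truncated to the 512
most abundant, with a classification (CLS) token prepended.  Abundance
values are discarded after ranking; rank order is carried by absolute
positional embeddings downstream.

All tabular formats are plain TSV (tab-separated, UTF-8, mandatory header);
abundance tables may alternatively be BIOM-JSON (dense or sparse).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAX_TAXA_DEFAULT = 512
TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus")


class TaxonVocabulary:
    """Discrete token alphabet: PAD=0, CLS=1, MASK=2, then taxa.

    Taxon indices are contiguous starting at :attr:`n_special`; the
    identifier -> index -> identifier round trip is the identity.
    """

    PAD = 0
    CLS = 1
    MASK = 2
    n_special = 3
    special_names = ("<PAD>", "<CLS>", "<MASK>")

    def __init__(self, taxon_ids: list[str]):
        if len(set(taxon_ids)) != len(taxon_ids):
            raise ValueError("duplicate taxon ids in vocabulary")
        self.taxon_ids = list(taxon_ids)
        self.index_of = {t: i + self.n_special for i, t in enumerate(self.taxon_ids)}

    def __len__(self) -> int:
        return len(self.taxon_ids)

    @property
    def size(self) -> int:
        """Total token count including the three special tokens."""
        return len(self.taxon_ids) + self.n_special

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.index_of

    def index(self, taxon_id: str) -> int:
        return self.index_of[taxon_id]

    def taxon(self, index: int) -> str:
        if index < self.n_special:
            return self.special_names[index]
        return self.taxon_ids[index - self.n_special]

    def taxon_index_range(self) -> range:
        return range(self.n_special, self.size)

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256("\n".join(self.taxon_ids).encode()).hexdigest()


@dataclass
class TokenSequence:
    """CLS-prefixed, rank-ordered taxon index list for one sample."""

    token_indices: np.ndarray
    sample_id: str | None = None

    def __post_init__(self):
        self.token_indices = np.asarray(self.token_indices, dtype=np.int64)
        if len(self.token_indices) == 0 or self.token_indices[0] != TaxonVocabulary.CLS:
            raise ValueError("token sequence must start with CLS")
        taxa = self.token_indices[1:]
        if len(np.unique(taxa)) != len(taxa):
            raise ValueError("duplicate taxon indices in sequence")

    def __len__(self) -> int:
        return len(self.token_indices)

    @property
    def taxa(self) -> np.ndarray:
        return self.token_indices[1:]


@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances (rows sum to 1)."""

    values: pd.DataFrame  # index: sample ids, columns: taxon ids
    patient_ids: pd.Series | None = None
    rescaled_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.columns)

    def sample_vector(self, sample_id: str) -> pd.Series:
        return self.values.loc[sample_id]


def _normalize_rows(df: pd.DataFrame, tol: float = 1e-6) -> tuple[pd.DataFrame, list[str]]:
    sums = df.to_numpy().sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = df.index[zero][0]
        raise ValueError(f"all-zero sample row: {bad!r}")
    off = np.abs(sums - 1.0) > tol
    rescaled = [str(s) for s in df.index[off]]
    if not off.any():
        return df, rescaled
    # rescale only rows outside tolerance: loading is then idempotent and
    # write -> read -> write is a byte-level fixed point
    scale = np.where(off, sums, 1.0)
    out = df.div(scale, axis=0)
    return out, rescaled


def _validate_nonnegative(df: pd.DataFrame) -> None:
    arr = df.to_numpy()
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative abundance at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )


def load_abundance_table(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Load and row-normalize an abundance table (TSV or BIOM-JSON)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "biom":
        df = _read_biom_json(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'biom')")
    _validate_nonnegative(df)
    norm, rescaled = _normalize_rows(df)
    if rescaled:
        logger.info("normalized %d sample rows to sum 1", len(rescaled))
    return AbundanceTable(values=norm, rescaled_samples=rescaled)


def _read_biom_json(path: Path) -> pd.DataFrame:
    """BIOM-JSON: rows are observations (taxa), columns are samples."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:  # sparse triples [row, col, value]
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    return pd.DataFrame(mat.T, index=samples, columns=taxa)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="sample_id")


def rank_tokenize(
    sample: pd.Series | dict[str, float],
    vocab: TaxonVocabulary,
    max_taxa: int = MAX_TAXA_DEFAULT,
    sample_id: str | None = None,
) -> TokenSequence:
    """Order present taxa by decreasing abundance, truncate, prepend CLS.

    Ties in abundance are broken by ascending vocabulary index (a declared
    convention; deterministic across platforms).  Taxa absent from the
    vocabulary are dropped with a logged count.  At most ``max_taxa`` taxa
    are kept, so sequences have length <= 1 + max_taxa.
    """
    if max_taxa < 1:
        raise ValueError("max_taxa must be >= 1")
    idx: list[int] = []
    ab: list[float] = []
    n_unknown = 0
    for taxon, value in sample.items():
        if value <= 0:
            continue
        j = vocab.index_of.get(taxon)
        if j is None:
            n_unknown += 1
            continue
        idx.append(j)
        ab.append(float(value))
    if n_unknown:
        logger.debug("dropped %d taxa absent from vocabulary", n_unknown)
    if not idx:
        warnings.warn(f"sample {sample_id!r} has no taxa in vocabulary", stacklevel=2)
        return TokenSequence(np.array([TaxonVocabulary.CLS]), sample_id)
    order = np.lexsort((np.asarray(idx), -np.asarray(ab)))[:max_taxa]
    tokens = np.concatenate(([TaxonVocabulary.CLS], np.asarray(idx, dtype=np.int64)[order]))
    return TokenSequence(tokens, sample_id)


def tokenize_table(
    table: AbundanceTable, vocab: TaxonVocabulary, max_taxa: int = MAX_TAXA_DEFAULT
) -> list[TokenSequence]:
    arr = table.values.to_numpy()
    col_idx = np.array([vocab.index_of.get(t, -1) for t in table.taxon_ids], dtype=np.int64)
    out = []
    for i, sid in enumerate(table.sample_ids):
        present = np.nonzero(arr[i] > 0)[0]
        known = present[col_idx[present] >= 0]
        if known.size == 0:
            out.append(TokenSequence(np.array([TaxonVocabulary.CLS]), sid))
            continue
        ab = arr[i, known]
        vidx = col_idx[known]
        order = np.lexsort((vidx, -ab))[:max_taxa]
        tokens = np.concatenate(([TaxonVocabulary.CLS], vidx[order]))
        out.append(TokenSequence(tokens, sid))
    return out


@dataclass
class TaxonomyMap:
    """taxon_id -> (phylum, class, order, family, genus); None marks missing."""

    table: pd.DataFrame  # index taxon_id, columns TAXONOMY_RANKS, NaN = missing

    def lookup(self, taxon_id: str) -> tuple:
        row = self.table.loc[taxon_id]
        return tuple(None if pd.isna(v) else v for v in row)

    def rank_values(self, taxon_ids: list[str], rank: str = "phylum") -> pd.Series:
        return self.table.loc[taxon_ids, rank]

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)


def load_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["taxon_id", *TAXONOMY_RANKS]
    if list(df.columns) != expected:
        raise ValueError(f"taxonomy header must be {expected}, got {list(df.columns)}")
    dup = df["taxon_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate taxon_id: {df['taxon_id'][dup].iloc[0]!r}")
    df = df.set_index("taxon_id")
    df = df.where(df != "NA")  # NaN marks missing ranks
    return TaxonomyMap(df)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    out = tax.table.fillna("NA")
    out.to_csv(path, sep="\t", index_label="taxon_id")


@dataclass
class EmbeddingMatrix:
    """taxon_id -> fixed-dimension real vector."""

    vectors: pd.DataFrame  # index taxon_id, d numeric columns

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.vectors.index)

    def vector(self, taxon_id: str) -> np.ndarray:
        return self.vectors.loc[taxon_id].to_numpy()

    def missing_taxa(self, vocab: TaxonVocabulary) -> list[str]:
        return [t for t in vocab.taxon_ids if t not in self.vectors.index]

    def as_array(self, taxon_ids: list[str]) -> np.ndarray:
        return self.vectors.loc[taxon_ids].to_numpy()


def load_embedding_matrix(path: str | Path) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError("embedding matrix needs at least one dimension column")
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric embedding entry at taxon {row!r}, column {col!r}")
    arr = df.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite embedding entries")
    df.index = df.index.astype(str)
    return EmbeddingMatrix(pd.DataFrame(arr, index=df.index, columns=df.columns))


def write_embedding_matrix(emb: EmbeddingMatrix, path: str | Path) -> None:
    emb.vectors.to_csv(path, sep="\t", index_label="taxon_id", float_format="%.10g")


def load_labels(path: str | Path) -> pd.DataFrame:
    """Phenotype labels: columns sample_id, label (0/1), patient_id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    expected = {"sample_id", "label", "patient_id"}
    if not expected.issubset(df.columns):
        raise ValueError(f"labels file must have columns {sorted(expected)}")
    if not df["label"].isin([0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    return df.set_index("sample_id")


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def load_pathway_matrix(path: str | Path) -> pd.DataFrame:
    """Binary taxon x pathway membership matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.isin(arr, [0, 1]).all():
        raise ValueError("pathway matrix entries must be 0/1")
    df.index = df.index.astype(str)
    return df.astype(np.int8)


def write_pathway_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="taxon_id")
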
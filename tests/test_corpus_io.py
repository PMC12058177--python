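"""Tokenization and tabular I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import microbelm as m
from microbelm.corpus_io import (
    TaxonVocabulary,
    load_abundance_table,
    load_embedding_matrix,
    load_taxonomy,
    write_abundance_table,
    write_embedding_matrix,
    write_taxonomy,
)


@pytest.fixture()
def vocab5():
    return TaxonVocabulary(["A", "B", "C", "D", "E"])


def brute_force_rank(sample: dict, vocab: TaxonVocabulary, max_taxa: int):
    """Independent oracle: full stable sort on (-abundance, index)."""
    present = [(v, vocab.index(t)) for t, v in sample.items()
               if v > 0 and t in vocab]
    present.sort(key=lambda p: (-p[0], p[1]))
    return [TaxonVocabulary.CLS] + [i for _, i in present[:max_taxa]]


class TestRankTokenize:
    def test_sorted_input(self, vocab5):
        seq = m.rank_tokenize({"A": 0.5, "B": 0.3, "C": 0.2}, vocab5)
        assert seq.token_indices.tolist() == [
            TaxonVocabulary.CLS, vocab5.index("A"), vocab5.index("B"),
            vocab5.index("C")]

    def test_tie_broken_by_ascending_index(self, vocab5):
        seq = m.rank_tokenize({"B": 0.4, "A": 0.4, "C": 0.2}, vocab5)
        assert seq.token_indices.tolist() == brute_force_rank(
            {"B": 0.4, "A": 0.4, "C": 0.2}, vocab5, 512)
        assert seq.token_indices[1] == vocab5.index("A")

    def test_truncation_cap(self):
        taxa = [f"t{i:03d}" for i in range(600)]
        vocab = TaxonVocabulary(taxa)
        rng = np.random.default_rng(0)
        sample = {t: float(v) for t, v in zip(taxa, rng.random(600) + 0.01)}
        seq = m.rank_tokenize(sample, vocab, max_taxa=512)
        assert len(seq) == 513
        kept = {vocab.taxon(i) for i in seq.taxa}
        dropped_max = max(v for t, v in sample.items() if t not in kept)
        kept_min = min(sample[t] for t in kept)
        assert kept_min >= dropped_max

    def test_unknown_taxa_dropped_with_warning(self, vocab5):
        with pytest.warns(UserWarning):
            seq = m.rank_tokenize({"ZZZ": 1.0}, vocab5)
        assert seq.token_indices.tolist() == [TaxonVocabulary.CLS]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.dictionaries(st.sampled_from(["A", "B", "C", "D", "E"]),
                           st.floats(0, 1, allow_nan=False), min_size=1),
           st.integers(1, 6))
    def test_matches_brute_force(self, sample, max_taxa):
        vocab = TaxonVocabulary(["A", "B", "C", "D", "E"])
        if all(v <= 0 for v in sample.values()):
            return
        seq = m.rank_tokenize(sample, vocab, max_taxa=max_taxa)
        assert seq.token_indices.tolist() == brute_force_rank(sample, vocab, max_taxa)

    def test_removing_least_abundant_equals_dropping_last_token(self, vocab5):
        sample = {"A": 0.5, "B": 0.3, "C": 0.15, "D": 0.05}
        full = m.rank_tokenize(sample, vocab5)
        least = vocab5.taxon(int(full.token_indices[-1]))
        reduced = {t: v for t, v in sample.items() if t != least}
        again = m.rank_tokenize(reduced, vocab5)
        assert again.token_indices.tolist() == full.token_indices.tolist()[:-1]

    def test_deterministic(self, vocab5):
        sample = {"A": 0.25, "B": 0.25, "C": 0.5}
        a = m.rank_tokenize(sample, vocab5)
        b = m.rank_tokenize(sample, vocab5)
        assert np.array_equal(a.token_indices, b.token_indices)


class TestVocabulary:
    def test_round_trip_identity(self, vocab5):
        for t in ["A", "B", "E"]:
            assert vocab5.taxon(vocab5.index(t)) == t

    def test_special_indices_reserved(self, vocab5):
        assert {TaxonVocabulary.PAD, TaxonVocabulary.CLS, TaxonVocabulary.MASK} == {0, 1, 2}
        assert min(vocab5.index_of.values()) == TaxonVocabulary.n_special

    def test_duplicate_rejected(self):
        with pytest.raises(ValueError):
            TaxonVocabulary(["A", "A"])


class TestAbundanceTable:
    def test_normalization(self, tmp_path):
        path = tmp_path / "ab.tsv"
        path.write_text("sample_id\tA\tB\tC\ns1\t0.5\t0.3\t0.2\ns2\t2\t1\t1\n")
        table = load_abundance_table(path)
        np.testing.assert_allclose(table.values.loc["s2"].to_numpy(),
                                   [0.5, 0.25, 0.25])
        assert table.rescaled_samples == ["s2"]

    def test_negative_value_named(self, tmp_path):
        path = tmp_path / "ab.tsv"
        path.write_text("sample_id\tA\tB\ns1\t0.5\t-0.1\n")
        with pytest.raises(ValueError, match="s1.*B"):
            load_abundance_table(path)

    def test_all_zero_row_named(self, tmp_path):
        path = tmp_path / "ab.tsv"
        path.write_text("sample_id\tA\tB\ns1\t1\t1\nszero\t0\t0\n")
        with pytest.raises(ValueError, match="szero"):
            load_abundance_table(path)

    def test_round_trip(self, tmp_path, world):
        out = tmp_path / "round.tsv"
        write_abundance_table(world.abundance, out)
        again = load_abundance_table(out)
        np.testing.assert_allclose(again.values.to_numpy(),
                                   world.abundance.values.to_numpy(), atol=1e-9)
        assert again.taxon_ids == world.abundance.taxon_ids

    def test_biom_json_dense_and_sparse(self, tmp_path):
        import json

        taxa = ["A", "B"]
        samples = ["s1", "s2"]
        dense = {"rows": [{"id": t} for t in taxa],
                 "columns": [{"id": s} for s in samples],
                 "matrix_type": "dense", "data": [[1.0, 3.0], [1.0, 1.0]]}
        sparse = dict(dense, matrix_type="sparse",
                      data=[[0, 0, 1.0], [0, 1, 3.0], [1, 0, 1.0], [1, 1, 1.0]])
        for doc, name in ((dense, "d.biom"), (sparse, "s.biom")):
            p = tmp_path / name
            p.write_text(json.dumps(doc))
            table = load_abundance_table(p, format="biom")
            np.testing.assert_allclose(table.values.to_numpy(),
                                       [[0.5, 0.5], [0.75, 0.25]])


class TestTaxonomy:
    def test_na_is_missing(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("taxon_id\tphylum\tclass\torder\tfamily\tgenus\n"
                        "t1\tFirmicutes\tClostridia\tClostridiales\t"
                        "Lachnospiraceae\tNA\n")
        tax = load_taxonomy(path)
        assert tax.lookup("t1") == ("Firmicutes", "Clostridia", "Clostridiales",
                                    "Lachnospiraceae", None)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("taxon_id\tphylum\tclass\torder\tfamily\tgenus\n")
        assert len(load_taxonomy(path)) == 0

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("taxon_id\tphylum\tclass\torder\tfamily\tgenus\n"
                        "t1\tA\tB\tC\tD\tE\nt1\tA\tB\tC\tD\tE\n")
        with pytest.raises(ValueError, match="t1"):
            load_taxonomy(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text("id\tphylum\n" + "t1\tA\n")
        with pytest.raises(ValueError):
            load_taxonomy(path)

    def test_round_trip(self, tmp_path, world):
        out = tmp_path / "tax.tsv"
        write_taxonomy(world.taxonomy, out)
        again = load_taxonomy(out)
        for t in world.abundance.taxon_ids[:50]:
            assert again.lookup(t) == world.taxonomy.lookup(t)


class TestEmbeddingMatrix:
    def test_dimension(self, tmp_path):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((3, 100)),
                          index=["a", "b", "c"])
        out = tmp_path / "emb.tsv"
        df.to_csv(out, sep="\t", index_label="taxon_id")
        emb = load_embedding_matrix(out)
        assert emb.dim == 100

    def test_zero_vector_legal(self, tmp_path):
        out = tmp_path / "emb.tsv"
        out.write_text("taxon_id\te0\te1\nz\t0\t0\n")
        emb = load_embedding_matrix(out)
        np.testing.assert_array_equal(emb.vector("z"), [0.0, 0.0])

    def test_non_numeric_rejected_with_coordinates(self, tmp_path):
        out = tmp_path / "emb.tsv"
        out.write_text("taxon_id\te0\te1\na\t1.0\toops\n")
        with pytest.raises(ValueError, match="a.*e1"):
            load_embedding_matrix(out)

    def test_round_trip(self, tmp_path, world):
        out = tmp_path / "emb.tsv"
        write_embedding_matrix(world.embeddings, out)
        again = load_embedding_matrix(out)
        np.testing.assert_allclose(again.vectors.to_numpy(),
                                   world.embeddings.vectors.to_numpy(), atol=1e-9)
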
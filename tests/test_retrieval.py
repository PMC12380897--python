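"""Chunking arithmetic, embedding index and the two retrieval paths."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from smpc2idmp.idmp_model import field_by_id
from smpc2idmp.retrieval import (
    Chunk,
    HashedBowBackend,
    RetrievalConfig,
    VectorIndex,
    build_index,
    chunk_document,
    get_embedding_backend,
    rule_based_retrieve,
    semantic_retrieve,
)
from smpc2idmp.smpc_io import parse_smpc


def _doc(text: str):
    return parse_smpc(text, "t")


class TestChunking:
    def test_stride_arithmetic_900_chars(self):
        doc = _doc("a" * 900)
        chunks = chunk_document(doc, RetrievalConfig())
        assert [(c.start, c.end) for c in chunks] == [(0, 500), (300, 800), (600, 900)]

    def test_short_text_single_chunk(self):
        doc = _doc("short text")
        chunks = chunk_document(doc, RetrievalConfig())
        assert len(chunks) == 1 and chunks[0].text == "short text"

    @given(st.text(alphabet="abcd \n", min_size=1, max_size=3000))
    def test_overlap_reconstruction(self, text):
        """Concatenating each chunk's non-overlapping tail rebuilds the text."""
        doc = _doc(text)
        config = RetrievalConfig(chunk_size=50, overlap=20)
        chunks = chunk_document(doc, config)
        rebuilt = chunks[0].text
        for prev, cur in zip(chunks, chunks[1:]):
            rebuilt += cur.text[prev.end - cur.start :]
        assert rebuilt == text

    @given(st.text(alphabet="xy z", min_size=1, max_size=2000))
    def test_coverage_and_ordering_invariants(self, text):
        doc = _doc(text)
        config = RetrievalConfig(chunk_size=100, overlap=40)
        chunks = chunk_document(doc, config)
        assert all(len(c.text) <= config.chunk_size for c in chunks)
        assert all(c.end - c.start == len(c.text) for c in chunks)
        assert [c.start for c in chunks] == sorted(c.start for c in chunks)
        covered = set()
        for c in chunks:
            covered.update(range(c.start, c.end))
        assert covered == set(range(len(text)))

    def test_exact_overlap_between_consecutive_chunks(self):
        doc = _doc("b" * 1700)
        chunks = chunk_document(doc, RetrievalConfig())
        for prev, cur in zip(chunks[:-1], chunks[1:-1]):
            assert prev.end - cur.start == 200

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RetrievalConfig(chunk_size=100, overlap=100)
        with pytest.raises(ValueError):
            RetrievalConfig(k=0)

    def test_chunks_carry_owning_chapter(self, small_corpus):
        doc, _ = small_corpus[0]
        for chunk in chunk_document(doc, RetrievalConfig()):
            chapter = doc.chapter_at(chunk.start)
            assert chunk.chapter_id == chapter.chapter_id


class TestIndex:
    def test_index_shape_matches_backend_dim(self):
        backend = HashedBowBackend()
        chunks = [Chunk(i, t, 0, len(t), "0") for i, t in
                  enumerate(["alpha beta", "gamma delta", "epsilon"])]
        index = build_index(chunks, backend)
        assert index.vectors.shape == (3, backend.dim)

    def test_identical_texts_embed_identically(self):
        backend = HashedBowBackend()
        vecs = backend.embed(["the same words here", "the same words here"])
        assert np.array_equal(vecs[0], vecs[1])

    def test_rebuilt_index_gives_identical_rankings(self, small_corpus):
        doc, _ = small_corpus[0]
        config = RetrievalConfig()
        backend = get_embedding_backend("hashed-bow")
        chunks = chunk_document(doc, config)
        ctx1 = semantic_retrieve("shelf life", build_index(chunks, backend), config)
        ctx2 = semantic_retrieve("shelf life", build_index(chunks, backend), config)
        assert ctx1 == ctx2

    def test_empty_chunk_list_rejected(self):
        with pytest.raises(ValueError):
            build_index([], HashedBowBackend())


class _ToyBackend:
    """Fixed 2-D vectors keyed by text, for hand-checkable cosines."""

    name = "toy"
    dim = 2

    def __init__(self, mapping):
        self.mapping = mapping

    def embed(self, texts):
        return np.array([self.mapping[t] for t in texts], dtype=float)


class TestSemanticRetrieve:
    def test_self_similar_chunk_ranked_first(self, small_corpus):
        doc, _ = small_corpus[0]
        config = RetrievalConfig()
        chunks = chunk_document(doc, config)
        index = build_index(chunks, get_embedding_backend("hashed-bow"))
        target = chunks[5]
        ctx = semantic_retrieve(target.text, index, config)
        assert ctx.passages[0].provenance == str(target.chunk_id)
        assert ctx.passages[0].score == pytest.approx(
            max(p.score for p in ctx.passages)
        )

    def test_hand_computed_2d_cosines(self):
        mapping = {"q": (1, 1), "c0": (1, 0), "c1": (0, 1), "c2": (-1, 0)}
        backend = _ToyBackend(mapping)
        chunks = [Chunk(i, f"c{i}", 0, 2, "0") for i in range(3)]
        index = build_index(chunks, backend)
        from smpc2idmp import retrieval as r

        r.register_embedding_backend(backend)
        ctx = semantic_retrieve("q", index, RetrievalConfig(k=2))
        assert [p.provenance for p in ctx.passages] == ["0", "1"]
        assert ctx.passages[0].score == pytest.approx(1 / np.sqrt(2))
        assert ctx.passages[1].score == pytest.approx(1 / np.sqrt(2))

    def test_orthogonal_query_scores_zero_ordered_by_chunk_id(self):
        mapping = {"q": (0, 1), "c0": (1, 0), "c1": (-1, 0), "c2": (2, 0)}
        backend = _ToyBackend(mapping)
        from smpc2idmp import retrieval as r

        r.register_embedding_backend(backend)
        chunks = [Chunk(i, f"c{i}", 0, 2, "0") for i in range(3)]
        ctx = semantic_retrieve("q", build_index(chunks, backend), RetrievalConfig())
        assert [p.provenance for p in ctx.passages] == ["0", "1", "2"]
        assert all(p.score == 0.0 for p in ctx.passages)

    def test_result_invariant_to_chunk_insertion_order(self, small_corpus):
        doc, _ = small_corpus[0]
        config = RetrievalConfig(k=5)
        backend = get_embedding_backend("hashed-bow")
        chunks = chunk_document(doc, config)
        shuffled = list(reversed(chunks))
        ctx1 = semantic_retrieve("marketing authorisation", build_index(chunks, backend), config)
        ctx2 = semantic_retrieve("marketing authorisation", build_index(shuffled, backend), config)
        assert [p.provenance for p in ctx1.passages] == [
            p.provenance for p in ctx2.passages
        ]

    def test_cosine_equals_dot_of_normalized_vectors(self):
        rng = np.random.default_rng(0)
        from smpc2idmp.retrieval import _cosine_scores

        q = rng.normal(size=8)
        vectors = rng.normal(size=(5, 8))
        raw = _cosine_scores(q, vectors.copy())
        normed = (vectors / np.linalg.norm(vectors, axis=1, keepdims=True)) @ (
            q / np.linalg.norm(q)
        )
        assert np.allclose(raw, normed)

    def test_empty_index_returns_empty_context(self):
        index = VectorIndex([], np.zeros((0, 2)), "hashed-bow")
        ctx = semantic_retrieve("anything", index, RetrievalConfig())
        assert ctx.passages == ()


class TestRuleBasedRetrieve:
    @pytest.mark.parametrize(
        "field_id, expected_fragment_source",
        [
            ("product_name", "1"),
            ("atc_code", "5"),
            ("therapeutic_indications_information", "4"),
        ],
    )
    def test_mapped_chapter_is_returned(
        self, small_corpus, field_id, expected_fragment_source
    ):
        doc, gold = small_corpus[0]
        ctx = rule_based_retrieve(field_by_id(field_id), doc)
        assert ctx.mode == "rule_based"
        assert [p.provenance for p in ctx.passages][0] == expected_fragment_source
        assert all(p.score is None for p in ctx.passages)

    def test_atc_context_includes_subsection_5_1(self, small_corpus):
        doc, gold = small_corpus[0]
        ctx = rule_based_retrieve(field_by_id("atc_code"), doc)
        assert gold["medicinal_product"]["atc_code"] in ctx.text

    def test_absent_chapters_give_empty_context(self):
        doc = parse_smpc("1. FIRST\nonly chapter one\n", "x")
        ctx = rule_based_retrieve(field_by_id("shelf_life_value"), doc)
        assert ctx.passages == ()
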
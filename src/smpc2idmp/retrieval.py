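"""Field-relevant context retrieval: semantic (chunk + embed + cosine top-k)
and rule-based (field-to-chapter mapping).

The semantic path splits the document into 500-character chunks with a
200-character overlap, embeds them, and ranks chunks against the field's
question by cosine similarity, keeping the top k = 20.  The rule-based path
returns the full text of the SmPC chapters mapped to the field (product name
from chapter 1, ATC code from chapter 5, therapeutic indications from
chapter 4, and so on).

Embedding models are pluggable through a minimal contract (``name``, ``dim``,
``embed``).  The default offline backend is a deterministic hashed
bag-of-words: tokens are hashed into a fixed number of signed buckets with
sublinear term-frequency weighting.  It has no pretrained weights and no
notion of synonymy — it is a lexical-overlap embedding that keeps the whole
pipeline runnable and exactly reproducible offline; published transformer
encoders can be registered under their own names.
"""

from __future__ import annotations

import hashlib
import logging
import math
import re
from dataclasses import dataclass, field as dc_field
from typing import Protocol, Sequence

import numpy as np

from .idmp_model import FieldSpec
from .smpc_io import SmpcDocument, get_chapter

logger = logging.getLogger(__name__)

__all__ = [
    "Chunk",
    "RetrievalConfig",
    "EmbeddingBackend",
    "HashedBowBackend",
    "VectorIndex",
    "Passage",
    "RetrievedContext",
    "chunk_document",
    "build_index",
    "semantic_retrieve",
    "rule_based_retrieve",
    "get_embedding_backend",
    "register_embedding_backend",
]


@dataclass(frozen=True)
class Chunk:
    chunk_id: int
    text: str
    start: int
    end: int
    chapter_id: str


@dataclass(frozen=True)
class RetrievalConfig:
    """Chunking and ranking parameters (defaults: 500/200 characters, k=20)."""

    chunk_size: int = 500
    overlap: int = 200
    k: int = 20
    mode: str = "semantic"  # semantic | rule_based
    embedding_backend: str = "hashed-bow"
    snap_window: int = 0  # snap chunk bounds to whitespace within +/- this many chars

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.chunk_size):
            raise ValueError("require 0 <= overlap < chunk_size")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mode not in ("semantic", "rule_based"):
            raise ValueError(f"unknown retrieval mode {self.mode!r}")


class EmbeddingBackend(Protocol):
    name: str
    dim: int

    def embed(self, texts: Sequence[str]) -> np.ndarray: ...


_STOPWORDS = frozenset(
    "a an and are as at be by for from has have in is it its of on or that the "
    "this to was were will with what which how when where who each any".split()
)

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


class HashedBowBackend:
    """Deterministic hashed bag-of-words embedding (signed feature hashing).

    Each non-stopword token is md5-hashed (with a seed salt) to a bucket and a
    sign; bucket weights use sublinear term frequency (1 + log tf).  Identical
    text always embeds to the identical vector, independent of process state.
    """

    def __init__(self, dim: int = 256, seed: int = 0, name: str = "hashed-bow"):
        self.name = name
        self.dim = dim
        self.seed = seed

    def _bucket(self, token: str) -> tuple[int, float]:
        digest = hashlib.md5(f"{self.seed}:{token}".encode("utf-8")).digest()
        bucket = int.from_bytes(digest[:4], "big") % self.dim
        sign = 1.0 if digest[4] % 2 == 0 else -1.0
        return bucket, sign

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim), dtype=np.float64)
        for row, text in enumerate(texts):
            counts: dict[str, int] = {}
            for tok in _TOKEN_RE.findall(text.lower()):
                if tok not in _STOPWORDS:
                    counts[tok] = counts.get(tok, 0) + 1
            for tok, tf in counts.items():
                bucket, sign = self._bucket(tok)
                out[row, bucket] += sign * (1.0 + math.log(tf))
        return out


_EMBEDDING_REGISTRY: dict[str, EmbeddingBackend] = {}


def register_embedding_backend(backend: EmbeddingBackend) -> None:
    _EMBEDDING_REGISTRY[backend.name] = backend


def get_embedding_backend(name: str) -> EmbeddingBackend:
    if name not in _EMBEDDING_REGISTRY:
        raise KeyError(
            f"unknown embedding backend {name!r}; "
            f"registered: {sorted(_EMBEDDING_REGISTRY)}"
        )
    return _EMBEDDING_REGISTRY[name]


register_embedding_backend(HashedBowBackend())


# --- chunking --------------------------------------------------------------

def _snap(text: str, pos: int, window: int) -> int:
    """Move a boundary to the nearest whitespace within +/- window chars."""
    if window <= 0 or pos <= 0 or pos >= len(text):
        return pos
    best = pos
    best_dist = window + 1
    lo = max(0, pos - window)
    hi = min(len(text), pos + window + 1)
    for i in range(lo, hi):
        if text[i].isspace() and abs(i - pos) < best_dist:
            best, best_dist = i, abs(i - pos)
    return best


def chunk_document(doc: SmpcDocument, config: RetrievalConfig) -> list[Chunk]:
    """Sliding-window chunks with stride ``chunk_size - overlap``.

    Every character of the document appears in at least one chunk; consecutive
    chunks share exactly ``overlap`` characters except possibly the final
    pair (and except where ``snap_window`` adjusts bounds to whitespace).
    """
    text = doc.raw_text
    if not text:
        return []
    stride = config.chunk_size - config.overlap
    chunks: list[Chunk] = []
    nominal = 0
    while True:
        start = _snap(text, nominal, config.snap_window) if nominal else 0
        end = min(nominal + config.chunk_size, len(text))
        if end < len(text):
            end = _snap(text, end, config.snap_window)
        chapter = doc.chapter_at(start)
        chunks.append(
            Chunk(len(chunks), text[start:end], start, end,
                  chapter.chapter_id if chapter else "0")
        )
        if nominal + config.chunk_size >= len(text):
            break
        nominal += stride
    return chunks


# --- vector index ----------------------------------------------------------

@dataclass
class VectorIndex:
    """In-memory vector store: one embedding row per chunk."""

    chunks: list[Chunk]
    vectors: np.ndarray  # (n_chunks, dim)
    backend_name: str

    def __len__(self) -> int:
        return len(self.chunks)


def build_index(chunks: list[Chunk], backend: EmbeddingBackend) -> VectorIndex:
    if not chunks:
        raise ValueError("cannot build an index from an empty chunk list")
    try:
        vectors = np.asarray(backend.embed([c.text for c in chunks]), dtype=np.float64)
    except Exception as exc:  # noqa: BLE001 - annotate with chunk context
        raise RuntimeError(
            f"embedding backend {backend.name!r} failed on {len(chunks)} chunks"
        ) from exc
    if not np.all(np.isfinite(vectors)):
        raise RuntimeError(f"backend {backend.name!r} produced non-finite vectors")
    return VectorIndex(list(chunks), vectors, backend.name)


@dataclass(frozen=True)
class Passage:
    text: str
    score: float | None
    provenance: str  # chunk_id (semantic) or chapter_id (rule-based)


@dataclass(frozen=True)
class RetrievedContext:
    field_id: str
    mode: str
    passages: tuple[Passage, ...]

    @property
    def text(self) -> str:
        return "\n\n".join(p.text for p in self.passages)


def _cosine_scores(query_vec: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    qn = float(np.linalg.norm(query_vec))
    norms = np.linalg.norm(vectors, axis=1)
    denom = qn * norms
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = vectors @ query_vec / denom
    scores[~np.isfinite(scores)] = 0.0  # zero-norm vectors score 0
    return scores


def semantic_retrieve(
    query: str,
    index: VectorIndex,
    config: RetrievalConfig,
    field_id: str = "",
) -> RetrievedContext:
    """Top-k chunks by cosine similarity; ties broken by ascending chunk_id."""
    if len(index) == 0:
        logger.warning("semantic_retrieve on empty index")
        return RetrievedContext(field_id, "semantic", ())
    backend = get_embedding_backend(index.backend_name)
    query_vec = np.asarray(backend.embed([query]), dtype=np.float64)[0]
    scores = _cosine_scores(query_vec, index.vectors)
    order = sorted(range(len(index)), key=lambda i: (-scores[i], index.chunks[i].chunk_id))
    top = order[: config.k]
    passages = tuple(
        Passage(index.chunks[i].text, float(scores[i]), str(index.chunks[i].chunk_id))
        for i in top
    )
    return RetrievedContext(field_id, "semantic", passages)


def rule_based_retrieve(field: FieldSpec, doc: SmpcDocument) -> RetrievedContext:
    """Full text of the field's mapped chapters, in chapter_map order."""
    if not field.chapter_map:
        raise ValueError(f"field {field.field_id!r} has an empty chapter_map")
    passages = []
    for chapter_id in field.chapter_map:
        body = get_chapter(doc, chapter_id)
        if body:
            passages.append(Passage(body, None, chapter_id))
    if not passages:
        logger.warning(
            "no mapped chapter of %s present in %s", field.field_id, doc.doc_id
        )
    return RetrievedContext(field.field_id, "rule_based", tuple(passages))
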
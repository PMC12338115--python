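"""Two-stage context retrieval for retrieval-augmented scoring.

Stage one embeds the candidate documents (those mentioning both the
compound and the toxicity endpoint) and three templated retrieval
questions; each document's cumulative relevance is the sum of its cosine
similarities to the three query vectors, and the top ``k`` (default 20)
survive.  Stage two rescores those candidates with a pluggable
(query, document) pair scorer against a single specialized symptom query
and keeps the top five, each truncated to 100 words before entering the
prompt.

Real sentence encoders and cross-encoder rerankers plug in behind
:class:`Encoder` and a plain callable; the bundled
:class:`HashedBowEncoder` (hashed bag-of-words, L2-normalized) and
:func:`overlap_scorer` make the full path deterministic and dependency-free
for tests and synthetic studies.
"""

from __future__ import annotations

import logging
import re
import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from .pubtator import AnnotatedCorpus

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _load_queries() -> list[str]:
    text = (
        resources.files("toxlitscore")
        .joinpath("templates", "retrieval_queries.txt")
        .read_text("utf-8")
    )
    return [line for line in text.splitlines() if line.strip()]


def _load_rerank_query() -> str:
    return (
        resources.files("toxlitscore")
        .joinpath("templates", "rerank_query.txt")
        .read_text("utf-8")
        .strip()
    )


class Encoder(Protocol):
    """Text encoder contract: deterministic text -> fixed-dimension vector."""

    def encode(self, text: str) -> np.ndarray: ...


#: A cross-scorer maps (query, document text) to a relevance score.
CrossScorer = Callable[[str, str], float]


@dataclass(frozen=True)
class HashedBowEncoder:
    """Deterministic hashed bag-of-words encoder.

    Tokens are lowercased alphanumeric runs hashed by CRC32 into ``dim``
    buckets; the count vector is L2-normalized.  No vocabulary state, so
    identical text always maps to an identical vector regardless of what
    else was encoded.
    """

    dim: int = 256

    def encode(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim)
        for tok in _TOKEN_RE.findall(text.lower()):
            v[zlib.crc32(tok.encode("utf-8")) % self.dim] += 1.0
        n = np.linalg.norm(v)
        return v / n if n > 0 else v


def overlap_scorer(query: str, text: str) -> float:
    """Toy pair scorer: count of shared token types between query and text."""
    q = set(_TOKEN_RE.findall(query.lower()))
    t = set(_TOKEN_RE.findall(text.lower()))
    return float(len(q & t))


@dataclass
class RetrievedContext:
    """Result of the two-stage retrieval for one compound.

    ``candidates`` are the first-stage survivors with cumulative relevance
    scores, ``reranked`` the final top-5 with cross-scorer scores; both are
    sorted by descending score with document-ID ties broken ascending.
    ``texts`` aligns with ``reranked``, already truncated.
    """

    compound_id: str
    candidates: list[tuple[str, float]] = field(default_factory=list)
    reranked: list[tuple[str, float]] = field(default_factory=list)
    texts: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.reranked


def candidate_pool(
    corpus: AnnotatedCorpus, compound_id: str, tox_doc_set: set[str]
) -> set[str]:
    """Documents mentioning both the compound and the toxicity endpoint."""
    pool = corpus.docs_for(compound_id) & tox_doc_set
    if not pool:
        logger.warning(
            "no documents co-mention compound %s and the toxicity endpoint; "
            "context will be empty",
            compound_id,
        )
    return pool


def retrieve(
    encoder: Encoder,
    pool_texts: Mapping[str, str],
    compound_name: str,
    k: int = 20,
    queries: Sequence[str] | None = None,
) -> list[tuple[str, float]]:
    """First stage: cumulative query-document cosine ranking.

    Each of the three retrieval questions is instantiated with the
    compound name and encoded; a document's relevance is the *sum* of its
    cosines to the query vectors (the cumulative-score rule for documents
    hit by several queries).  Returns the top ``k`` as (doc_id, score),
    ties broken by ascending document ID, independent of input order.
    """
    if not pool_texts:
        return []
    if queries is None:
        queries = _load_queries()
    q_vecs = [encoder.encode(q.replace("[compound]", compound_name)) for q in queries]
    scored: list[tuple[str, float]] = []
    for doc_id in sorted(pool_texts):
        d = encoder.encode(pool_texts[doc_id])
        scored.append((doc_id, float(sum(np.dot(qv, d) for qv in q_vecs))))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]


def rerank(
    cross_scorer: CrossScorer,
    candidates: Sequence[tuple[str, float]],
    pool_texts: Mapping[str, str],
    compound_name: str,
    top: int = 5,
    query: str | None = None,
) -> list[tuple[str, float]]:
    """Second stage: pair-score candidates against the specialized query."""
    if not candidates:
        return []
    if query is None:
        query = _load_rerank_query()
    q = query.replace("[compound]", compound_name)
    rescored = [
        (doc_id, float(cross_scorer(q, pool_texts[doc_id])))
        for doc_id, _ in candidates
    ]
    rescored.sort(key=lambda t: (-t[1], t[0]))
    return rescored[:top]


def truncate_words(text: str, limit: int = 100) -> str:
    """First ``limit`` whitespace-delimited words, single-space rejoined."""
    return " ".join(text.split()[:limit])


def build_context(
    corpus: AnnotatedCorpus,
    compound_id: str,
    compound_name: str,
    tox_doc_set: set[str],
    encoder: Encoder | None = None,
    cross_scorer: CrossScorer = overlap_scorer,
    k: int = 20,
    top: int = 5,
    word_limit: int = 100,
) -> RetrievedContext:
    """Full two-stage pipeline for one compound.

    An empty candidate pool yields an empty context (scoring then proceeds
    in the no-context ablation mode).
    """
    if encoder is None:
        encoder = HashedBowEncoder()
    pool = candidate_pool(corpus, compound_id, tox_doc_set)
    if not pool:
        return RetrievedContext(compound_id=compound_id)
    pool_texts = {
        d: f"{corpus.documents[d][0]} {corpus.documents[d][1]}".strip()
        for d in pool
    }
    candidates = retrieve(encoder, pool_texts, compound_name, k=k)
    reranked = rerank(cross_scorer, candidates, pool_texts, compound_name, top=top)
    texts = [truncate_words(pool_texts[d], word_limit) for d, _ in reranked]
    return RetrievedContext(
        compound_id=compound_id,
        candidates=candidates,
        reranked=reranked,
        texts=texts,
    )
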
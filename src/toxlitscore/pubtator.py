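"""Reading and writing PubTator-dialect concept annotations and documents.

The concept-annotation format is the tab-separated, header-less dialect used
by the PubTator central bulk exports (``chemical2pubtatorcentral`` and
friends): one concept mention per line with five columns ::

    doc_id <TAB> concept_type <TAB> concept_id <TAB> mentions <TAB> resource

Concept IDs are MeSH-like accessions (``D002251``, ``C028473``).  The
``mentions`` column may hold several surface forms joined by ``|``; it is
kept verbatim.  Documents travel in a separate TSV with a header row
(``doc_id``, ``title``, ``abstract``).

Associations downstream are computed on concept IDs only; mention strings
matter solely for the term-list route of :func:`toxicity_documents`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Surface forms that tie a publication to hepatotoxicity when matched
#: (case-insensitively) against the mention column of a disease annotation.
DEFAULT_HEPATOTOX_TERMS = (
    "hepatotoxicity",
    "hepatotoxic",
    "liver toxicity",
    "hepatic toxicity",
)

CONCEPT_TYPES = ("chemical", "disease", "gene", "species", "other")


class PubTatorParseError(ValueError):
    """Raised when an annotation line does not have exactly five columns."""


@dataclass(frozen=True)
class DocumentAnnotation:
    """One concept mention in one document."""

    doc_id: str
    concept_type: str
    concept_id: str
    mention: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")


@dataclass
class AnnotatedCorpus:
    """Documents plus an inverted concept-ID -> document-ID index.

    ``documents`` maps a document ID to ``(title, abstract, full_text)``;
    ``index`` maps a concept ID to the deduplicated set of documents that
    mention it.  Mention strings are deliberately absent: associations are
    computed on normalized concept IDs only.
    """

    documents: dict[str, tuple[str, str, bool]] = field(default_factory=dict)
    index: dict[str, set[str]] = field(default_factory=dict)
    concept_names: dict[str, str] = field(default_factory=dict)
    concept_types: dict[str, str] = field(default_factory=dict)

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    def docs_for(self, concept_id: str) -> set[str]:
        """Document set for a concept; raises ``KeyError`` if unknown."""
        if concept_id not in self.index:
            raise KeyError(f"unknown concept: {concept_id!r}")
        return self.index[concept_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedCorpus):
            return NotImplemented
        return (
            self.documents == other.documents
            and self.index == other.index
            and self.concept_names == other.concept_names
            and self.concept_types == other.concept_types
        )


def _normalize_type(raw: str) -> str:
    low = raw.strip().lower()
    return low if low in CONCEPT_TYPES else "other"


def read_annotations(
    path: str | Path, concept_type: str | None = None
) -> list[DocumentAnnotation]:
    """Parse a 5-column PubTator TSV into annotations, order preserved.

    Lines whose concept-ID column is empty are skipped (a count is logged);
    a line with the wrong number of columns raises
    :class:`PubTatorParseError` naming the line number.  When
    ``concept_type`` is given, only annotations of that (normalized) type
    are returned.
    """
    path = Path(path)
    out: list[DocumentAnnotation] = []
    skipped = 0
    with path.open("r", encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise PubTatorParseError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, "
                    f"got {len(cols)}"
                )
            doc_id, ctype, concept_id, mention, source = cols
            if not concept_id.strip():
                skipped += 1
                continue
            ann = DocumentAnnotation(
                doc_id=doc_id.strip(),
                concept_type=_normalize_type(ctype),
                concept_id=concept_id.strip(),
                mention=mention,
                source=source,
            )
            if concept_type is None or ann.concept_type == _normalize_type(concept_type):
                out.append(ann)
    if skipped:
        logger.info("skipped %d annotation lines with missing concept_id", skipped)
    return out


def write_annotations(annotations: Iterable[DocumentAnnotation], path: str | Path) -> None:
    """Write annotations in the same 5-column TSV dialect."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for a in annotations:
            fh.write(
                f"{a.doc_id}\t{a.concept_type.capitalize()}\t{a.concept_id}"
                f"\t{a.mention}\t{a.source}\n"
            )


def read_documents(path: str | Path) -> dict[str, tuple[str, str, bool]]:
    """Read a documents TSV (header row: doc_id, title, abstract)."""
    docs: dict[str, tuple[str, str, bool]] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        header = fh.readline()
        if not header.rstrip("\r\n"):
            return docs
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise PubTatorParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(cols)}"
                )
            doc_id, title, abstract = cols
            docs[doc_id] = (title, abstract, False)
    return docs


def write_documents(
    documents: Mapping[str, tuple[str, str, bool]], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("doc_id\ttitle\tabstract\n")
        for doc_id in sorted(documents):
            title, abstract, _ = documents[doc_id]
            fh.write(f"{doc_id}\t{title}\t{abstract}\n")


def build_corpus(
    annotations: Iterable[DocumentAnnotation],
    documents: Mapping[str, tuple[str, str, bool]] | None = None,
) -> AnnotatedCorpus:
    """Assemble an :class:`AnnotatedCorpus` from annotations and documents.

    The inverted index is built on concept IDs only; duplicate
    (document, concept) pairs collapse to a single entry.  The preferred
    name of a concept is the first mention seen for it (first ``|``-part).
    Documents referenced by annotations but absent from ``documents`` get
    empty title/abstract placeholders so the index invariant holds.
    """
    corpus = AnnotatedCorpus()
    if documents:
        corpus.documents.update(documents)
    for ann in annotations:
        corpus.index.setdefault(ann.concept_id, set()).add(ann.doc_id)
        if ann.concept_id not in corpus.concept_names:
            corpus.concept_names[ann.concept_id] = ann.mention.split("|")[0]
            corpus.concept_types[ann.concept_id] = ann.concept_type
        if ann.doc_id not in corpus.documents:
            corpus.documents[ann.doc_id] = ("", "", False)
    return corpus


def filter_rare_concepts(corpus: AnnotatedCorpus, min_docs: int = 5) -> AnnotatedCorpus:
    """Drop concepts found in fewer than ``min_docs`` documents.

    The cut is strict — a concept in exactly ``min_docs`` documents is
    retained.  Documents themselves are untouched.  Idempotent.
    """
    if min_docs < 1:
        raise ValueError("min_docs must be >= 1")
    kept = {cid: docs for cid, docs in corpus.index.items() if len(docs) >= min_docs}
    return AnnotatedCorpus(
        documents=dict(corpus.documents),
        index={cid: set(docs) for cid, docs in kept.items()},
        concept_names={cid: corpus.concept_names[cid] for cid in kept if cid in corpus.concept_names},
        concept_types={cid: corpus.concept_types[cid] for cid in kept if cid in corpus.concept_types},
    )


def toxicity_documents(
    annotations: Iterable[DocumentAnnotation],
    terms: Sequence[str] = DEFAULT_HEPATOTOX_TERMS,
    concept_ids: Iterable[str] | None = None,
) -> set[str]:
    """Documents associated with the toxicity endpoint.

    Two routes, combinable: a surface-form route matching ``terms``
    case-insensitively against the mention column (how free-text corpora
    define the endpoint), and a concept-ID route for corpora where the
    endpoint is a planted or curated concept ID.
    """
    term_set = {t.lower() for t in terms} if terms else set()
    id_set = set(concept_ids) if concept_ids else set()
    hits: set[str] = set()
    for ann in annotations:
        if ann.concept_id in id_set:
            hits.add(ann.doc_id)
            continue
        if term_set:
            for part in ann.mention.split("|"):
                if part.strip().lower() in term_set:
                    hits.add(ann.doc_id)
                    break
    return hits
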
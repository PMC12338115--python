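"""Skip-gram word embeddings over entity-normalized sentences.

Compounds and the toxicity concept are single tokens (their concept IDs)
after preprocessing, so the embedding geometry directly encodes
compound-endpoint association: cosine similarity between a compound
vector and the toxicity vector is the association score.

The trainer implements skip-gram with negative sampling (SGNS): for each
(center, context) pair within a dynamically shrunk window, the center
vector is pulled toward the context's output vector and pushed away from
``negative_samples`` noise tokens drawn from the unigram distribution
raised to the 3/4 power.  Updates are applied in vectorized minibatches;
with a fixed seed and single-threaded execution training is exactly
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_ENTITY_TYPES = {"chemical", "drug", "disease", "gene"}


@dataclass(frozen=True)
class TrainingConfig:
    """SGNS hyperparameters.

    Defaults follow the standard biomedical-literature recipe (10 epochs,
    5 negatives, minimum count 5, learning rate 0.025, window 5,
    dimension 1000).  Test-scale corpora use dimensions of 32-64, which
    preserves all qualitative behavior at a fraction of the runtime.
    """

    epochs: int = 10
    negative_samples: int = 5
    min_word_count: int = 5
    learning_rate: float = 0.025
    window: int = 5
    dimension: int = 1000

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.window < 1 or self.negative_samples < 1:
            raise ValueError("window and negative_samples must be >= 1")


@dataclass
class EmbeddingSpace:
    """Vocabulary plus one real vector per token, optionally unit-norm."""

    vocabulary: dict[str, int]
    vectors: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError("vectors must be (n_tokens, dimension)")

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def vector(self, token: str) -> np.ndarray:
        if token not in self.vocabulary:
            raise KeyError(f"token not in vocabulary: {token!r}")
        return self.vectors[self.vocabulary[token]]

    def save(self, path: str | Path) -> None:
        """One token per line: token then whitespace-separated components."""
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"{len(self.vocabulary)} {self.vectors.shape[1]}\n")
            for token in sorted(self.vocabulary, key=self.vocabulary.get):
                comps = " ".join(f"{x:.8e}" for x in self.vector(token))
                fh.write(f"{token} {comps}\n")

    @classmethod
    def load(cls, path: str | Path, normalized: bool = True) -> "EmbeddingSpace":
        with Path(path).open("r", encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            vocab: dict[str, int] = {}
            vecs = np.empty((n, dim))
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                vocab[parts[0]] = i
                vecs[i] = [float(x) for x in parts[1:]]
        return cls(vocab, vecs, normalized=normalized)


def _clean_token(tok: str) -> str:
    return tok.strip(".,;:!?()[]{}\"'`")


def preprocess_sentences(
    sentences: Iterable[str | Sequence[str]],
    entity_map: Mapping[str, str],
    entity_types: Mapping[str, str] | None = None,
) -> list[list[str]]:
    """Lowercase, normalize entity mentions to concept-ID tokens, prune.

    ``entity_map`` maps surface mentions (possibly multi-word, e.g.
    "carbon tetrachloride") to concept IDs; replacement is
    longest-match-first so multi-word mentions win over their substrings.
    Noisy tokens — tokens without any alphanumeric character and
    single-character tokens — are dropped.  Sentences carrying fewer than
    two entities of type chemical/drug/disease/gene are removed, since a
    lone entity offers no relational signal.  Idempotent: concept-ID
    tokens pass through unchanged.
    """
    lower_map: dict[tuple[str, ...], str] = {}
    for mention, cid in entity_map.items():
        words = tuple(_clean_token(w) for w in mention.lower().split())
        if words:
            lower_map[words] = cid
    max_len = max((len(w) for w in lower_map), default=1)
    known_ids = set(lower_map.values())
    if entity_types is not None:
        known_ids |= set(entity_types)

    def is_entity(tok: str) -> bool:
        if entity_types is not None:
            return entity_types.get(tok, "").lower() in _ENTITY_TYPES
        return tok in known_ids

    out: list[list[str]] = []
    for sent in sentences:
        raw = sent.split() if isinstance(sent, str) else list(sent)
        toks = [_clean_token(t.lower()) if t not in known_ids else t for t in raw]
        toks = [t for t in toks if t]
        replaced: list[str] = []
        i = 0
        while i < len(toks):
            matched = False
            for span in range(min(max_len, len(toks) - i), 0, -1):
                window = tuple(toks[i : i + span])
                if window in lower_map:
                    replaced.append(lower_map[window])
                    i += span
                    matched = True
                    break
            if not matched:
                tok = toks[i]
                if len(tok) > 1 and any(c.isalnum() for c in tok):
                    replaced.append(tok)
                i += 1
        if sum(1 for t in replaced if is_entity(t)) >= 2:
            out.append(replaced)
    return out


def _build_vocab(
    sentences: Sequence[Sequence[str]], min_count: int
) -> tuple[dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    vocab = {t: i for i, t in enumerate(kept)}
    freq = np.array([counts[t] for t in kept], dtype=np.float64)
    return vocab, freq


def train_embeddings(
    sentences: Iterable[Sequence[str]],
    config: TrainingConfig = TrainingConfig(),
    seed: int = 0,
    workers: int = 1,
    batch_size: int = 1024,
) -> EmbeddingSpace:
    """Train SGNS embeddings; output vectors are L2-normalized.

    Tokens seen fewer than ``min_word_count`` times are excluded from the
    vocabulary.  The learning rate decays linearly over the run.  Only
    single-worker training is implemented; requesting more workers logs a
    warning and proceeds single-threaded, as reproducibility is a design
    requirement here.
    """
    if workers != 1:
        logger.warning(
            "multi-worker training is not reproducible; proceeding with 1 worker"
        )
    sents = [list(s) for s in sentences]
    vocab, freq = _build_vocab(sents, config.min_word_count)
    if not vocab:
        raise ValueError("empty vocabulary after min_word_count pruning")
    ids = [
        np.array([vocab[t] for t in s if t in vocab], dtype=np.int64) for s in sents
    ]
    ids = [s for s in ids if len(s) >= 2]

    rng = np.random.default_rng(seed)
    V, d = len(vocab), config.dimension
    W = (rng.random((V, d)) - 0.5) / d          # input (center) vectors
    C = np.zeros((V, d))                         # output (context) vectors
    noise = freq**0.75
    noise /= noise.sum()
    K = config.negative_samples
    lr0 = config.learning_rate

    # upper bound on pair count for the linear learning-rate schedule
    est_pairs = max(
        1, config.epochs * sum(len(s) * min(config.window, len(s) - 1) for s in ids)
    )
    seen = 0

    def flush(centers: list[int], contexts: list[int]) -> None:
        nonlocal seen
        if not centers:
            return
        c = np.asarray(centers, dtype=np.int64)
        o = np.asarray(contexts, dtype=np.int64)
        neg = rng.choice(V, size=(len(c), K), p=noise)
        lr = lr0 * max(1e-4, 1.0 - seen / est_pairs)
        wc = W[c]
        co = C[o]
        pos_s = _sigmoid(np.einsum("bd,bd->b", wc, co))
        neg_co = C[neg]
        neg_s = _sigmoid(np.einsum("bd,bkd->bk", wc, neg_co))
        d_wc = (1.0 - pos_s)[:, None] * co - np.einsum("bk,bkd->bd", neg_s, neg_co)
        d_co = (1.0 - pos_s)[:, None] * wc
        d_neg = -neg_s[..., None] * wc[:, None, :]
        np.add.at(W, c, lr * d_wc)
        np.add.at(C, o, lr * d_co)
        np.add.at(C, neg.reshape(-1), lr * d_neg.reshape(-1, d))
        seen += len(c)

    for _ in range(config.epochs):
        buf_c: list[int] = []
        buf_o: list[int] = []
        for sent in ids:
            n = len(sent)
            widths = rng.integers(1, config.window + 1, size=n)
            for i in range(n):
                b = int(widths[i])
                for j in range(max(0, i - b), min(n, i + b + 1)):
                    if j == i:
                        continue
                    buf_c.append(int(sent[i]))
                    buf_o.append(int(sent[j]))
                if len(buf_c) >= batch_size:
                    flush(buf_c, buf_o)
                    buf_c, buf_o = [], []
        flush(buf_c, buf_o)

    norms = np.linalg.norm(W, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return EmbeddingSpace(vocab, W / norms, normalized=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def cosine_similarity(space: EmbeddingSpace, token_a: str, token_b: str) -> float:
    """Cosine of the angle between two token vectors, in [-1, 1].

    Raises ``KeyError`` for out-of-vocabulary tokens — callers record a
    missing score rather than a zero, since absence of a vector is absence
    of evidence.
    """
    a = space.vector(token_a)
    b = space.vector(token_b)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cannot compute cosine with a zero vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


@dataclass
class ArithmeticReport:
    """Vector-arithmetic diagnostics for toxicity-type / organ pairs.

    ``pair_cosines`` holds, per (toxicity-type, organ) pair, the cosine
    between that difference vector and the general-toxicity vector;
    ``mean_cosine`` is the cosine between the *mean* difference vector and
    the general-toxicity vector.  If the space really encodes
    "organ + toxicity ~ organ-specific toxicity", these cosines approach 1.
    ``pca_coords`` gives 2-D projections of every involved token for
    plotting.
    """

    pair_cosines: dict[tuple[str, str], float]
    mean_difference: np.ndarray
    mean_cosine: float
    pca_coords: dict[str, tuple[float, float]]
    skipped: list[tuple[str, str]] = field(default_factory=list)


def toxicity_arithmetic_report(
    space: EmbeddingSpace,
    pairs: Sequence[tuple[str, str]],
    general_tox: str,
) -> ArithmeticReport:
    """Probe the additive structure of the embedding space.

    For each (toxicity-type, organ) pair the difference vector
    ``v(toxicity-type) - v(organ)`` is computed; pairs with missing tokens
    are listed as skipped.  The report compares the mean difference with
    the general-toxicity direction and projects all involved vectors onto
    their first two principal components.
    """
    from sklearn.decomposition import PCA

    g = space.vector(general_tox)
    diffs: list[np.ndarray] = []
    pair_cos: dict[tuple[str, str], float] = {}
    skipped: list[tuple[str, str]] = []
    tokens: list[str] = [general_tox]
    for tox_tok, organ_tok in pairs:
        if tox_tok not in space or organ_tok not in space:
            skipped.append((tox_tok, organ_tok))
            continue
        diff = space.vector(tox_tok) - space.vector(organ_tok)
        diffs.append(diff)
        pair_cos[(tox_tok, organ_tok)] = _cos(diff, g)
        tokens.extend([tox_tok, organ_tok])
    if not diffs:
        raise ValueError("no usable (toxicity, organ) pairs")
    mean_diff = np.mean(diffs, axis=0)
    mats = np.stack([space.vector(t) for t in dict.fromkeys(tokens)])
    n_comp = min(2, mats.shape[0], mats.shape[1])
    coords = PCA(n_components=n_comp).fit_transform(mats)
    if n_comp < 2:
        coords = np.hstack([coords, np.zeros((coords.shape[0], 2 - n_comp))])
    pca = {
        tok: (float(coords[i, 0]), float(coords[i, 1]))
        for i, tok in enumerate(dict.fromkeys(tokens))
    }
    return ArithmeticReport(
        pair_cosines=pair_cos,
        mean_difference=mean_diff,
        mean_cosine=_cos(mean_diff, g),
        pca_coords=pca,
        skipped=skipped,
    )


def _cos(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))
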
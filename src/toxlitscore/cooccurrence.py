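"""Compound-toxicity co-occurrence statistics from annotated literature.

For each compound the corpus yields a 2x2 contingency layout: among the
``n_tox`` publications tied to the toxicity endpoint, ``k`` mention the
compound; among the remaining ``n_other`` publications, ``b`` mention it.
Association strength is quantified two ways and then combined:

* an odds ratio formed as the ratio of mention proportions,
  ``(k / n_tox) / (b / n_other)``;
* an over-representation tail probability under the hypergeometric
  distribution — the probability of drawing at least ``k`` endpoint
  publications when sampling the compound's ``k + b`` publications from the
  whole corpus without replacement — reported as a negative log because the
  raw probability underflows for any strongly associated compound.

The composite score per compound is ``odds_ratio * neglog_p``, then
max-normalized across compounds to land in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .pubtator import AnnotatedCorpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 mention counts for one compound against the toxicity endpoint."""

    k: int        # compound docs within the toxicity set
    n_tox: int    # size of the toxicity set
    b: int        # compound docs outside the toxicity set
    n_other: int  # corpus docs outside the toxicity set

    def __post_init__(self) -> None:
        if min(self.k, self.n_tox, self.b, self.n_other) < 0:
            raise ValueError("counts must be non-negative")
        if self.k > self.n_tox:
            raise ValueError(f"k={self.k} exceeds n_tox={self.n_tox}")
        if self.b > self.n_other:
            raise ValueError(f"b={self.b} exceeds n_other={self.n_other}")

    @property
    def population(self) -> int:
        return self.n_tox + self.n_other

    @property
    def n_compound(self) -> int:
        return self.k + self.b


@dataclass
class AssociationScore:
    """Per-compound association statistics and composite score."""

    compound_id: str
    counts: ContingencyCounts
    odds_ratio: float
    neglog_p: float
    raw: float
    normalized: float = float("nan")


def count_contingency(
    corpus: AnnotatedCorpus, compound_id: str, tox_doc_set: set[str]
) -> ContingencyCounts:
    """Contingency counts for one compound via set arithmetic on the index."""
    compound_docs = corpus.docs_for(compound_id)
    k = len(compound_docs & tox_doc_set)
    return ContingencyCounts(
        k=k,
        n_tox=len(tox_doc_set),
        b=len(compound_docs) - k,
        n_other=corpus.n_documents - len(tox_doc_set),
    )


def odds_ratio(c: ContingencyCounts, zero_cell_shift: float = 0.5) -> float:
    """Ratio of mention proportions ``(k/n_tox) / (b/n_other)``.

    Degenerate cells: ``k == 0`` returns 0; ``b == 0`` with ``k > 0`` would
    be infinite, so a Haldane-style shift adds ``zero_cell_shift`` to both
    numerator counts (totals unchanged) and logs the adjustment.
    """
    if c.n_tox == 0 or c.n_other == 0:
        raise ValueError("n_tox and n_other must both be positive")
    if c.k == 0:
        return 0.0
    k, b = float(c.k), float(c.b)
    if c.b == 0:
        k += zero_cell_shift
        b += zero_cell_shift
        logger.info(
            "zero-cell adjustment (+%g to k and b) applied for counts %s",
            zero_cell_shift, c,
        )
    return (k / c.n_tox) / (b / c.n_other)


def hypergeom_neglog_sf(
    k: int, n_tox: int, n_draws: int, population: int, base: float = math.e
) -> float:
    """Negative log of the inclusive upper tail P(X >= k).

    X is hypergeometric: ``n_draws`` documents sampled without replacement
    from a population of ``population`` of which ``n_tox`` carry the
    endpoint.  The tail is accumulated entirely in log space from
    log-gamma-based log-pmf terms, so it stays finite far beyond the point
    where the plain probability underflows (tails around e^-5700 occur for
    real compounds).
    """
    if not 0 <= k <= min(n_draws, n_tox):
        raise ValueError(
            f"need 0 <= k <= min(n_draws, n_tox); got k={k}, "
            f"n_draws={n_draws}, n_tox={n_tox}"
        )
    if population < n_draws or population < n_tox:
        raise ValueError("population must be >= n_draws and >= n_tox")
    if base <= 1.0:
        raise ValueError("log base must exceed 1")
    if k == 0:
        return 0.0
    lo = max(k, n_draws - (population - n_tox))
    js = np.arange(lo, min(n_draws, n_tox) + 1, dtype=np.float64)
    log_pmf = (
        gammaln(n_tox + 1) - gammaln(js + 1) - gammaln(n_tox - js + 1)
        + gammaln(population - n_tox + 1)
        - gammaln(n_draws - js + 1)
        - gammaln(population - n_tox - n_draws + js + 1)
        + gammaln(n_draws + 1) + gammaln(population - n_draws + 1)
        - gammaln(population + 1)
    )
    log_sf = float(logsumexp(log_pmf))
    # rounding can push the summed tail infinitesimally above log(1)
    log_sf = min(log_sf, 0.0)
    return -log_sf / math.log(base)


def score_compound(
    corpus: AnnotatedCorpus,
    compound_id: str,
    tox_doc_set: set[str],
    base: float = math.e,
) -> AssociationScore:
    """Counts, odds ratio, log tail and raw composite for one compound."""
    c = count_contingency(corpus, compound_id, tox_doc_set)
    odds = odds_ratio(c)
    neglog = hypergeom_neglog_sf(
        c.k, c.n_tox, c.n_compound, c.population, base=base
    )
    return AssociationScore(
        compound_id=compound_id,
        counts=c,
        odds_ratio=odds,
        neglog_p=neglog,
        raw=odds * neglog,
    )


def composite_scores(assocs: list[AssociationScore]) -> list[AssociationScore]:
    """Fill the max-normalized composite score in place and return the list.

    ``normalized = raw / max(raw)``; every compound tied at the maximum gets
    exactly 1.  If all raw scores are zero the normalized scores are defined
    as 0 (with a warning) rather than dividing by zero.
    """
    if not assocs:
        raise ValueError("need at least one association")
    top = max(a.raw for a in assocs)
    if top == 0.0:
        logger.warning("all raw association scores are zero; normalized set to 0")
        for a in assocs:
            a.normalized = 0.0
        return assocs
    for a in assocs:
        a.normalized = 1.0 if a.raw == top else a.raw / top
    return assocs


def score_corpus(
    corpus: AnnotatedCorpus,
    tox_doc_set: set[str],
    compound_ids: list[str] | None = None,
    base: float = math.e,
) -> list[AssociationScore]:
    """Composite association scores for all (or given) chemical concepts."""
    if compound_ids is None:
        compound_ids = [
            cid for cid, t in corpus.concept_types.items() if t == "chemical"
        ]
        compound_ids.sort()
    assocs = [
        score_compound(corpus, cid, tox_doc_set, base=base)
        for cid in compound_ids
    ]
    return composite_scores(assocs)
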
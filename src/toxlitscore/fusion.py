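"""Score fusion and validation against an ordinal liver-injury ranking.

The final hepatotoxicity score per compound is a weighted mean of the
available method scores — literature mining, word embeddings, and the two
language-model sizes — with weights 2 : 1 : 2 : 2 (embeddings are
down-weighted as the weakest method).  Missing components are dropped
together with their weights, so a compound scored by three methods is
still fused over those three.

Validation treats the most severe ordinal class (class 8 on the 0-8
scale) as the positive label and the rest as negatives, and compares
methods by AUC with DeLong 95% confidence intervals, paired DeLong tests,
confusion-matrix rows at the balanced-accuracy-optimal threshold,
pairwise score correlations and top-k membership overlap.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Fusion weights; embeddings carry half the weight of the other methods.
DEFAULT_WEIGHTS: dict[str, float] = {"lm": 2.0, "w2v": 1.0, "llm8b": 2.0, "llm70b": 2.0}

#: Ordinal class treated as positive in "most severe vs rest" validation.
SEVERE_CLASS = 8


@dataclass
class CompoundRecord:
    """Per-compound method scores, confidence, fused score and label."""

    compound_id: str
    name: str = ""
    score_lm: float | None = None
    score_w2v: float | None = None
    score_llm8b: float | None = None
    score_llm70b: float | None = None
    confidence: float | None = None
    combined: float | None = None
    dili_class: int | None = None

    def component(self, key: str) -> float | None:
        return getattr(self, f"score_{key}")


def combined_score(
    record: CompoundRecord, weights: dict[str, float] | None = None
) -> float | None:
    """Weighted mean over the *present* component scores.

    Missing components are dropped and their weights leave the
    denominator.  With no components at all the combined score is missing
    (logged).  Scaling all weights by a constant leaves the result
    unchanged, and equal weights reduce it to the plain mean.
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    num = den = 0.0
    for key, w in weights.items():
        s = record.component(key)
        if s is not None:
            num += w * s
            den += w
    if den == 0.0:
        logger.warning("no component scores for %s; combined left missing",
                       record.compound_id)
        return None
    return num / den


def fuse_records(
    records: list[CompoundRecord], weights: dict[str, float] | None = None
) -> list[CompoundRecord]:
    """Fill ``combined`` on every record in place; returns the list."""
    for r in records:
        r.combined = combined_score(r, weights)
    return records


def confidence_filter(
    records: list[CompoundRecord], threshold: float = 0.9
) -> list[CompoundRecord]:
    """Keep records with confidence >= threshold (inclusive cut)."""
    return [r for r in records if r.confidence is not None and r.confidence >= threshold]


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


@dataclass
class RocResult:
    """Empirical ROC with DeLong 95% CI on the AUC."""

    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    tpr: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    thresholds: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


@dataclass
class ThresholdRow:
    """Confusion-matrix row at one decision threshold (score >= t positive)."""

    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    bacc: float


def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            f"labels must contain both classes 0 and 1; got classes {classes}"
        )


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (per-positive, per-negative).

    The midrank formulation: the AUC equals the Mann-Whitney statistic
    with tied score pairs counted one half.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n                   # per positive
    v01 = 1.0 - (tz[m:] - ty) / m             # per negative
    return float(auc), v10, v01


def roc_auc(scores, labels) -> RocResult:
    """Empirical ROC, trapezoidal AUC and DeLong 95% CI.

    The AUC is the Mann-Whitney estimate (tied pairs count one half); the
    CI comes from the DeLong variance with a normal approximation, clipped
    to [0, 1].  Requires both classes present.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    half = stats.norm.ppf(0.975) * math.sqrt(var)
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocResult(
        auc=auc,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
    )


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong test for paired AUC difference.

    Both score vectors must be aligned on the same label vector.  The
    variance of the AUC difference comes from the covariance of the
    structural components; a zero variance (e.g. identical classifiers)
    reports p = 1 with a degenerate-case warning.  Symmetric in its
    arguments.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned")
    _check_binary(labels)
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    var = 0.0
    if m > 1:
        s10 = np.cov(np.stack([v10_a, v10_b]))
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.stack([v01_a, v01_b]))
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        logger.warning("degenerate DeLong variance (identical AUC components); p = 1")
        return 1.0
    z = (auc_a - auc_b) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def threshold_metrics(
    scores, labels, criterion: str = "bacc"
) -> ThresholdRow:
    """Confusion-matrix row at the criterion-optimal threshold.

    Sweeps every distinct score as a candidate threshold (predicting
    positive when score >= threshold); the default criterion is balanced
    accuracy, with ties resolved toward the *lower* threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best: ThresholdRow | None = None
    for t in np.unique(scores):
        row = _row_at(scores, labels, float(t))
        key = getattr(row, criterion)
        if best is None or key > getattr(best, criterion) + 1e-12:
            best = row
        elif abs(key - getattr(best, criterion)) <= 1e-12 and t < best.threshold:
            best = row
    assert best is not None
    return best


def _row_at(scores: np.ndarray, labels: np.ndarray, t: float) -> ThresholdRow:
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return ThresholdRow(
        threshold=t,
        tp=tp, tn=tn, fp=fp, fn=fn,
        ppv=tp / (tp + fp) if tp + fp else 0.0,
        npv=tn / (tn + fn) if tn + fn else 0.0,
        sensitivity=sens,
        specificity=spec,
        bacc=(sens + spec) / 2.0,
    )


# ---------------------------------------------------------------------------
# Method comparison


@dataclass
class MethodComparison:
    """Pairwise correlations and top-k membership overlap between methods."""

    pearson: dict[tuple[str, str], tuple[float, float]]
    spearman: dict[tuple[str, str], tuple[float, float]]
    top_k: int
    top_sets: dict[str, set[str]]
    venn: dict[frozenset[str], int]


def method_comparison(
    method_scores: dict[str, dict[str, float]], k: int = 100
) -> MethodComparison:
    """Compare methods scored over a shared compound universe.

    ``method_scores`` maps method name -> {compound_id -> score}.
    Correlations are computed on the compounds scored by both methods of a
    pair; the Venn counts cover every non-empty method subset, counting
    compounds that are in the top-k of exactly that subset.
    """
    if len(method_scores) < 2:
        raise ValueError("need at least two methods to compare")
    names = sorted(method_scores)
    pearson: dict[tuple[str, str], tuple[float, float]] = {}
    spearman: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in itertools.combinations(names, 2):
        shared = sorted(set(method_scores[a]) & set(method_scores[b]))
        xa = np.array([method_scores[a][c] for c in shared])
        xb = np.array([method_scores[b][c] for c in shared])
        pr = stats.pearsonr(xa, xb)
        sr = stats.spearmanr(xa, xb)
        pearson[(a, b)] = (float(pr.statistic), float(pr.pvalue))
        spearman[(a, b)] = (float(sr.statistic), float(sr.pvalue))
    top_sets = {
        name: set(
            sorted(method_scores[name], key=lambda c: (-method_scores[name][c], c))[:k]
        )
        for name in names
    }
    venn: dict[frozenset[str], int] = {}
    universe = set().union(*top_sets.values())
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            exactly = set(universe)
            for n in combo:
                exactly &= top_sets[n]
            for n in names:
                if n not in combo:
                    exactly -= top_sets[n]
            venn[frozenset(combo)] = len(exactly)
    return MethodComparison(
        pearson=pearson, spearman=spearman, top_k=k, top_sets=top_sets, venn=venn
    )


def indecision_report(scores, tol: float = 1e-9) -> float:
    """Fraction of scores sitting exactly at the indecisive midpoint 0.5."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        return 0.0
    return float(np.mean(np.abs(scores - 0.5) <= tol))
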
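"""Weighted fusion, ROC/AUC, DeLong comparison, threshold rows, overlap."""

import numpy as np
import pytest
from scipy import stats

from toxlitscore import (
    CompoundRecord,
    combined_score,
    confidence_filter,
    delong_test,
    indecision_report,
    method_comparison,
    roc_auc,
    threshold_metrics,
)


def pair_count_auc(scores, labels):
    """Oracle: concordant pairs plus half the ties over all pos-neg pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(1.0 for p in pos for n in neg if p == n)
    return (conc + 0.5 * ties) / (len(pos) * len(neg))


class TestCombinedScore:
    def test_four_component_weighted_mean(self):
        r = CompoundRecord("x", score_lm=0.77, score_w2v=0.49,
                           score_llm8b=0.94, score_llm70b=0.99)
        assert combined_score(r) == pytest.approx(5.89 / 7)
        assert round(combined_score(r), 2) == 0.84

    def test_missing_component_dropped_with_weight(self):
        r = CompoundRecord("x", score_lm=0.45, score_llm8b=0.96, score_llm70b=1.00)
        assert combined_score(r) == pytest.approx(4.82 / 6)
        assert round(combined_score(r), 2) == 0.80

    def test_constant_components_give_constant(self):
        r = CompoundRecord("x", score_lm=0.6, score_w2v=0.6,
                           score_llm8b=0.6, score_llm70b=0.6)
        assert combined_score(r) == pytest.approx(0.6)

    def test_no_components_is_missing(self):
        assert combined_score(CompoundRecord("x")) is None

    def test_weight_scaling_invariance(self):
        r = CompoundRecord("x", score_lm=0.3, score_w2v=0.9, score_llm8b=0.1,
                           score_llm70b=0.7)
        w1 = {"lm": 2, "w2v": 1, "llm8b": 2, "llm70b": 2}
        w5 = {k: 5 * v for k, v in w1.items()}
        assert combined_score(r, w1) == pytest.approx(combined_score(r, w5))

    def test_equal_weights_reduce_to_mean(self):
        r = CompoundRecord("x", score_lm=0.2, score_w2v=0.4, score_llm8b=0.6,
                           score_llm70b=0.8)
        w = {"lm": 1, "w2v": 1, "llm8b": 1, "llm70b": 1}
        assert combined_score(r, w) == pytest.approx(0.5)


class TestConfidenceFilter:
    def _records(self, confs):
        return [CompoundRecord(str(i), confidence=c) for i, c in enumerate(confs)]

    def test_threshold_inclusive(self):
        kept = confidence_filter(self._records([0.9, 0.8999, 0.95]))
        assert [r.compound_id for r in kept] == ["0", "2"]

    def test_zero_threshold_is_identity(self):
        recs = self._records([0.1, 0.5, 0.9])
        assert confidence_filter(recs, threshold=0.0) == recs


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0
        assert r.ci_high <= 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(0.5, abs=0.05)
        assert r.ci_low <= 0.5 <= r.ci_high

    def test_six_point_toy_matches_pair_counting(self):
        scores = [0.9, 0.7, 0.7, 0.4, 0.3, 0.1]
        labels = [1, 1, 0, 1, 0, 0]
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_matches_pair_counting_on_random_small_instances(self):
        """Midrank AUC equals the O(n^2) pair-count oracle for n <= 50."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestDelong:
    Y = [1, 1, 1, 1, 0, 0, 0, 0]
    A = [0.68, 0.14, 0.20, 0.01, 0.79, 0.66, 0.71, 0.78]
    B = [0.46, 0.57, 0.14, 0.11, 0.67, 0.47, 0.57, 0.76]

    def test_identical_classifiers_give_one(self):
        assert delong_test(self.A, self.A, self.Y) == 1.0

    def test_symmetric(self):
        assert delong_test(self.A, self.B, self.Y) == pytest.approx(
            delong_test(self.B, self.A, self.Y), abs=1e-12
        )

    def test_toy_instance_matches_bootstrap_oracle(self):
        """Asymptotic p within 0.02 of a 1e5-replicate stratified bootstrap."""
        sa, sb = np.asarray(self.A), np.asarray(self.B)
        y = np.asarray(self.Y)
        pos = np.where(y == 1)[0]
        neg = np.where(y == 0)[0]

        def auc(s, p, n):
            diff = s[p][:, None] - s[n][None, :]
            return np.mean(diff > 0) + 0.5 * np.mean(diff == 0)

        rng = np.random.default_rng(0)
        n_rep = 100_000
        bp = rng.choice(pos, (n_rep, len(pos)))
        bn = rng.choice(neg, (n_rep, len(neg)))
        diffs = np.array(
            [auc(sa, bp[r], bn[r]) - auc(sb, bp[r], bn[r]) for r in range(n_rep)]
        )
        d0 = auc(sa, pos, neg) - auc(sb, pos, neg)
        p_boot = 2 * stats.norm.sf(abs(d0) / diffs.std(ddof=1))
        assert delong_test(sa, sb, y) == pytest.approx(p_boot, abs=0.02)

    def test_separator_beats_noise_at_scale(self):
        """A perfect separator is significantly better than random scores."""
        rng = np.random.default_rng(5)
        n = 400
        labels = np.repeat([1, 0], n // 2)
        perfect = labels + 0.01 * rng.random(n)
        noise = rng.random(n)
        assert delong_test(perfect, noise, labels) < 0.01


class TestThresholdMetrics:
    def test_perfect_separator_hits_unit_bacc(self):
        row = threshold_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert row.sensitivity == row.specificity == row.bacc == 1.0
        assert (row.tp, row.tn, row.fp, row.fn) == (2, 2, 0, 0)

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(3)
        scores = rng.choice(np.linspace(0, 1, 9), size=40)
        labels = rng.integers(0, 2, 40)

        def sweep_best():
            best = None
            for t in sorted(set(scores)):
                pred = scores >= t
                tp = int(np.sum(pred & (labels == 1)))
                tn = int(np.sum(~pred & (labels == 0)))
                fp = int(np.sum(pred & (labels == 0)))
                fn = int(np.sum(~pred & (labels == 1)))
                sens = tp / (tp + fn) if tp + fn else 0.0
                spec = tn / (tn + fp) if tn + fp else 0.0
                bacc = (sens + spec) / 2
                if best is None or bacc > best[0] + 1e-12:
                    best = (bacc, t)
            return best

        bacc, t = sweep_best()
        row = threshold_metrics(scores, labels)
        assert row.bacc == pytest.approx(bacc, abs=1e-12)
        assert row.threshold == pytest.approx(t)

    def test_degenerate_single_score(self):
        row = threshold_metrics([0.4, 0.4, 0.4], [1, 0, 1])
        assert row.threshold == 0.4
        assert row.fn == 0 and row.tn == 0  # everything predicted positive

    def test_bacc_is_mean_of_sens_spec(self):
        row = threshold_metrics([0.9, 0.6, 0.5, 0.2], [1, 0, 1, 0])
        assert row.bacc == pytest.approx((row.sensitivity + row.specificity) / 2)


class TestMethodComparison:
    def test_identical_scores_full_agreement(self):
        scores = {f"c{i}": i / 30 for i in range(30)}
        cmp_ = method_comparison({"m1": scores, "m2": dict(scores)}, k=10)
        assert cmp_.pearson[("m1", "m2")][0] == pytest.approx(1.0)
        assert cmp_.venn[frozenset({"m1", "m2"})] == 10

    def test_anticorrelated_ranks(self):
        n = 20
        s1 = {f"c{i}": i / n for i in range(n)}
        s2 = {f"c{i}": (n - i) / n for i in range(n)}
        cmp_ = method_comparison({"m1": s1, "m2": s2}, k=5)
        assert cmp_.spearman[("m1", "m2")][0] == pytest.approx(-1.0)
        assert cmp_.venn[frozenset({"m1", "m2"})] == 0

    def test_independent_scores_overlap_near_expectation(self):
        """Random top-k sets intersect in about k^2/n compounds on average."""
        rng = np.random.default_rng(9)
        n, k, reps = 500, 50, 30
        overlaps = []
        for _ in range(reps):
            s1 = {f"c{i}": rng.random() for i in range(n)}
            s2 = {f"c{i}": rng.random() for i in range(n)}
            cmp_ = method_comparison({"m1": s1, "m2": s2}, k=k)
            overlaps.append(len(cmp_.top_sets["m1"] & cmp_.top_sets["m2"]))
        expected = k * k / n
        se = np.sqrt(expected / reps) * 3
        assert abs(np.mean(overlaps) - expected) < max(3 * se, 1.5)

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            method_comparison({"m1": {"a": 1.0}})


class TestIndecision:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([0.5, 0.5, 0.5], 1.0),
            ([0.1, 0.9, 0.3], 0.0),
            ([0.5, 0.5, 0.5, 0.1, 0.9, 0.2, 0.3, 0.4], 0.375),
        ],
    )
    def test_fractions(self, scores, expected):
        assert indecision_report(scores) == pytest.approx(expected)
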
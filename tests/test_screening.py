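import math

import numpy as np
import pytest

from pdkeys.screening import (
    DeLongComparison,
    auc_mann_whitney,
    auc_with_exact_ci,
    delong_auc_variance,
    delong_test,
    roc_curve,
    screen_feature,
    youden_cutoff,
)


def pair_counting_auc(scores, labels):
    """Oracle: exhaustive concordant-pair counting with ties at 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    cases, ctrls = scores[labels], scores[~labels]
    total = 0.0
    for c in cases:
        for d in ctrls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(ctrls))


def random_instance(rng, max_n=30):
    n1 = int(rng.integers(1, max_n // 2))
    n0 = int(rng.integers(1, max_n // 2))
    scores = np.round(rng.normal(0, 1, n1 + n0), 1)  # rounding forces ties
    labels = np.array([True] * n1 + [False] * n0)
    return scores, labels


class TestRocAuc:
    def test_perfect_separation_has_perfect_point(self):
        roc = roc_curve([1, 2, 3, 4], [False, False, True, True])
        j = roc.sensitivity + roc.specificity
        assert np.any(np.isclose(j, 2.0))

    def test_interleaved_auc(self):
        # controls {1,3}, cases {2,4}: 3 of 4 pairs concordant
        auc = auc_mann_whitney([1, 2, 3, 4], [False, True, False, True])
        assert auc == pytest.approx(0.75)

    def test_all_tied_scores_auc_half(self):
        assert auc_mann_whitney([5, 5, 5, 5], [True, True, False, False]) == pytest.approx(0.5)

    def test_pair_counting_oracle(self, rng):
        for _ in range(300):
            scores, labels = random_instance(rng)
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_trapezoid_equals_mann_whitney(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng)
            roc = roc_curve(scores, labels)
            # threshold-descending order walks the staircase left to right
            fpr = (1.0 - roc.specificity)[::-1]
            trap = float(np.trapezoid(roc.sensitivity[::-1], fpr))
            assert trap == pytest.approx(auc_mann_whitney(scores, labels), abs=1e-12)

    def test_negation_complement(self, rng):
        scores, labels = random_instance(rng)
        a = auc_mann_whitney(scores, labels)
        b = auc_mann_whitney(-scores, labels)
        assert a + b == pytest.approx(1.0, abs=1e-15)

    def test_monotone_transform_invariance(self, rng):
        scores, labels = random_instance(rng)
        a = auc_mann_whitney(scores, labels)
        b = auc_mann_whitney(np.exp(2.0 * scores), labels)
        assert a == pytest.approx(b, abs=1e-15)

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(25):
            scores, labels = random_instance(rng)
            if labels.all() or not labels.any():
                continue
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], [True, True])

    def test_missing_scores_excluded(self):
        auc = auc_mann_whitney([1, 2, np.nan, 4], [False, True, True, True])
        assert auc == pytest.approx(auc_mann_whitney([1, 2, 4], [False, True, True]))


class TestExactBinomialCI:
    def test_perfect_separation_lower_bound_closed_form(self):
        scores = np.arange(10.0)
        labels = np.array([False] * 5 + [True] * 5)
        auc, (lo, hi) = auc_with_exact_ci(scores, labels)
        assert auc == 1.0
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-10)

    def test_beta_quantile_oracle(self):
        from scipy.stats import beta

        auc, (lo, hi) = auc_with_exact_ci([1, 2, 3, 4], [False, True, False, True])
        assert auc == pytest.approx(0.75)
        x, n = round(0.75 * 4), 4
        assert lo == pytest.approx(beta.ppf(0.025, x, n - x + 1))
        assert hi == pytest.approx(beta.ppf(0.975, x + 1, n - x))
        assert lo <= auc <= hi

    def test_ci_ordering_invariant(self, rng):
        for _ in range(20):
            n1, n0 = int(rng.integers(3, 15)), int(rng.integers(3, 15))
            scores = rng.normal(size=n1 + n0)
            labels = np.array([True] * n1 + [False] * n0)
            auc, (lo, hi) = auc_with_exact_ci(scores, labels)
            assert 0.0 <= lo <= auc + 0.5 / (n1 + n0) and auc - 0.5 / (n1 + n0) <= hi <= 1.0


def reference_delong(sa, sb, y):
    """Independent placement-value implementation (explicit loops)."""
    sa, sb, y = np.asarray(sa, float), np.asarray(sb, float), np.asarray(y, bool)

    def placements(s):
        cases, ctrls = s[y], s[~y]
        m, n = len(cases), len(ctrls)
        v10 = np.array([
            sum(1.0 if c > d else 0.5 if c == d else 0.0 for d in ctrls) / n
            for c in cases
        ])
        v01 = np.array([
            sum(1.0 if c > d else 0.5 if c == d else 0.0 for c in cases) / m
            for d in ctrls
        ])
        return v10, v01, v10.mean()

    v10a, v01a, aa = placements(sa)
    v10b, v01b, ab = placements(sb)
    m, n = len(v10a), len(v01a)

    def cov(u, v):
        return ((u - u.mean()) * (v - v.mean())).sum() / (len(u) - 1)

    var = (
        cov(v10a, v10a) / m + cov(v10b, v10b) / m - 2 * cov(v10a, v10b) / m
        + cov(v01a, v01a) / n + cov(v01b, v01b) / n - 2 * cov(v01a, v01b) / n
    )
    z = (aa - ab) / math.sqrt(var)
    from scipy.stats import norm

    return z, 2 * norm.sf(abs(z))


class TestDeLong:
    def test_identical_scores_p_one(self):
        s = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [False, False, False, True, True, True]
        cmp_ = delong_test(s, s, y)
        assert cmp_.z == 0.0 and cmp_.p_value == 1.0

    def test_hand_built_fixture_matches_reference(self):
        sa = [0.1, 0.3, 0.2, 0.8, 0.6, 0.7, 0.9, 0.4, 0.5, 0.65]
        sb = [0.2, 0.1, 0.4, 0.5, 0.3, 0.9, 0.6, 0.35, 0.8, 0.7]
        y = [False] * 5 + [True] * 5
        cmp_ = delong_test(sa, sb, y)
        z_ref, p_ref = reference_delong(sa, sb, y)
        assert cmp_.z == pytest.approx(z_ref, abs=1e-10)
        assert cmp_.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_random_instances_match_reference(self, rng):
        for _ in range(20):
            n1, n0 = int(rng.integers(4, 12)), int(rng.integers(4, 12))
            y = np.array([True] * n1 + [False] * n0)
            sa = rng.normal(size=n1 + n0)
            sb = 0.5 * sa + rng.normal(size=n1 + n0)
            cmp_ = delong_test(sa, sb, y)
            z_ref, p_ref = reference_delong(sa, sb, y)
            assert cmp_.z == pytest.approx(z_ref, abs=1e-10)
            assert cmp_.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_single_auc_variance_self_consistency(self, rng):
        y = np.array([True] * 10 + [False] * 12)
        s = rng.normal(size=22)
        var = delong_auc_variance(s, y)
        # must equal the diagonal term of the paired computation against itself
        cases, ctrls = s[y], s[~y]
        cmp_mat = (cases[:, None] > ctrls[None, :]) + 0.5 * (cases[:, None] == ctrls[None, :])
        v10, v01 = cmp_mat.mean(axis=1), cmp_mat.mean(axis=0)
        expected = np.var(v10, ddof=1) / 10 + np.var(v01, ddof=1) / 12
        assert var == pytest.approx(expected, abs=1e-14)

    def test_pairwise_missing_dropped(self):
        sa = [1, 2, 3, 4, np.nan, 6]
        sb = [2, 1, 4, 3, 5, 6]
        y = [False, False, False, True, True, True]
        cmp_ = delong_test(sa, sb, y)
        assert cmp_.n_paired == 5

    def test_degenerate_unequal_aucs_zero_variance_raises(self):
        sa = [1, 1, 1, 2, 2, 2]  # perfect separation, no variance in placements
        sb = [2, 2, 2, 1, 1, 1]
        y = [False, False, False, True, True, True]
        with pytest.raises(ValueError, match="degenerate"):
            delong_test(sa, sb, y)


class TestYouden:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 10, 11], [False, False, True, True])
        cutoff, sens, spec = youden_cutoff(roc)
        assert sens == 1.0 and spec == 1.0
        assert 2 < cutoff < 10

    def test_tie_break_prefers_sensitivity(self):
        # controls {1,3}, cases {2,4}: J = 0.5 at cutoffs 1.5 and 3.5
        roc = roc_curve([1, 2, 3, 4], [False, True, False, True])
        cutoff, sens, spec = youden_cutoff(roc)
        assert cutoff == pytest.approx(1.5)
        assert sens == pytest.approx(1.0)
        assert spec == pytest.approx(0.5)

    def test_all_tied_scores_j_zero(self):
        roc = roc_curve([5, 5, 5, 5], [True, False, True, False])
        j = roc.sensitivity + roc.specificity - 1
        assert np.allclose(j.max(), 0.0)

    def test_exhaustive_scan_oracle(self, rng):
        for _ in range(300):
            n1, n0 = int(rng.integers(1, 15)), int(rng.integers(1, 15))
            scores = np.round(rng.normal(size=n1 + n0), 1)
            labels = np.array([True] * n1 + [False] * n0)
            roc = roc_curve(scores, labels)
            _, sens, spec = youden_cutoff(roc)
            j_best = sens + spec - 1
            # exhaustive scan over every threshold between/beyond scores
            grid = np.concatenate([[-np.inf], np.sort(np.unique(scores)) - 1e-9, [np.inf]])
            cases, ctrls = scores[labels], scores[~labels]
            j_scan = max(
                (cases > t).mean() + (ctrls <= t).mean() - 1 for t in grid
            )
            assert j_best == pytest.approx(j_scan, abs=1e-12)


class TestScreenFeature:
    def test_full_result_structure(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(1.2, 1, 20)])
        labels = np.array([False] * 30 + [True] * 20)
        res = screen_feature(scores, labels, "il_sd")
        assert res.orientation == "cases_higher"
        assert res.auc_ci95[0] <= res.auc <= res.auc_ci95[1]
        assert 0 <= res.sensitivity_at_cutoff <= 100
        assert res.n_cases == 20 and res.n_controls == 30

    def test_auto_orient_flips_reversed_feature(self, rng):
        # feature that is LOWER in cases, declared cases_higher
        scores = np.concatenate([rng.normal(1.5, 1, 25), rng.normal(0, 1, 25)])
        labels = np.array([False] * 25 + [True] * 25)
        res = screen_feature(scores, labels, orientation="cases_higher")
        assert res.orientation == "cases_lower"
        assert res.auc > 0.5
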
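"""Diagnostic statistics: ROC/AUC against brute-force Mann-Whitney,
Youden search against exhaustive enumeration, DeLong properties,
Bland-Altman and OLS against closed forms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import infarctmap as im


def brute_force_auc(scores, labels):
    """Concordant-pair count with ties worth one half, over all
    positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(rng, n_max=30, ties=True):
    n = int(rng.integers(4, n_max + 1))
    while True:
        labels = rng.random(n) < 0.5
        if labels.any() and not labels.all():
            break
    if ties:
        scores = rng.integers(0, 6, n).astype(float)
    else:
        scores = rng.normal(size=n)
    return scores, labels


class TestRocCurve:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 10, 11, 12], float)
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        assert im.roc_curve(scores, labels).auc == 1.0

    def test_uninformative_scores_near_half(self, rng):
        n = 10_000
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.4
        assert im.roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_mann_whitney_oracle(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng)
            auc = im.roc_curve(scores, labels).auc
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_dichotomous_auc_is_mean_of_sens_and_spec(self, rng):
        scores, labels = random_instance(rng, ties=True)
        binary = (scores > 2).astype(float)
        if not (0 < binary.sum() < binary.size):
            binary[0], binary[-1] = 1.0, 0.0
        auc = im.roc_curve(binary, labels).auc
        perf = im.performance_at_cutoff(binary, labels, 0.5)
        assert auc == pytest.approx(
            (perf.sensitivity + perf.specificity) / 200.0, abs=1e-12
        )

    def test_points_reproduced_by_performance_at_cutoff(self, rng):
        scores, labels = random_instance(rng)
        curve = im.roc_curve(scores, labels)
        n_pos = labels.sum()
        n_neg = labels.size - n_pos
        for fpr, tpr, cutoff in curve.roc_points:
            perf = im.performance_at_cutoff(scores, labels, cutoff)
            tp, fp, tn, fn = perf.counts
            assert tp / n_pos == pytest.approx(tpr)
            assert fp / n_neg == pytest.approx(fpr)

    @given(
        seed=st.integers(0, 200),
        a=st.floats(0.1, 5.0),
        b=st.floats(-10.0, 10.0),
    )
    def test_auc_invariant_under_monotone_transform(self, seed, a, b):
        rng = np.random.default_rng(seed)
        scores, labels = random_instance(rng, ties=False)
        auc0 = im.roc_curve(scores, labels).auc
        auc1 = im.roc_curve(a * scores + b, labels).auc
        auc2 = im.roc_curve(np.exp(scores), labels).auc
        assert auc1 == pytest.approx(auc0, abs=1e-12)
        assert auc2 == pytest.approx(auc0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            im.roc_curve([1.0, 2.0], [True, True])

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores, labels = random_instance(rng)
            assert im.roc_curve(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestPerformanceAtCutoff:
    def test_segment_counts_continuous_test(self):
        # 146 segments, 41 reference-positive; 35 test-positive of which
        # 4 are false positives -> sensitivity 31/41, specificity 101/105
        scores = np.concatenate([np.ones(31), np.zeros(10), np.ones(4), np.zeros(101)])
        labels = np.concatenate([np.ones(41, bool), np.zeros(105, bool)])
        perf = im.performance_at_cutoff(scores, labels, 0.5)
        assert perf.sensitivity == pytest.approx(100 * 31 / 41)
        assert perf.sensitivity == pytest.approx(75.6, abs=0.05)
        assert perf.specificity == pytest.approx(100 * 101 / 105)
        assert perf.counts == (31, 4, 101, 10)

    def test_segment_counts_dichotomous_test(self):
        # 46 test-positive segments, 9 false -> sensitivity 37/41
        scores = np.concatenate([np.ones(37), np.zeros(4), np.ones(9), np.zeros(96)])
        labels = np.concatenate([np.ones(41, bool), np.zeros(105, bool)])
        perf = im.performance_at_cutoff(scores, labels, 0.5)
        assert perf.sensitivity == pytest.approx(100 * 37 / 41)
        assert perf.sensitivity == pytest.approx(90.2, abs=0.05)
        assert perf.specificity == pytest.approx(100 * 96 / 105)

    def test_perfect_prediction_gives_j_one(self):
        perf = im.performance_at_cutoff(
            [0.0, 0.0, 1.0, 1.0], [False, False, True, True], 0.5
        )
        assert perf.youden_j == pytest.approx(1.0)

    def test_counts_sum_to_n(self, rng):
        scores, labels = random_instance(rng)
        perf = im.performance_at_cutoff(scores, labels, float(np.median(scores)))
        assert sum(perf.counts) == labels.size
        assert perf.youden_j == pytest.approx(
            perf.sensitivity / 100 + perf.specificity / 100 - 1
        )


class TestYoudenOptimalCutoff:
    def test_matches_exhaustive_search(self, rng):
        for _ in range(30):
            scores, labels = random_instance(rng, n_max=50)
            cutoff, perf = im.youden_optimal_cutoff(scores, labels)
            u = np.unique(scores)
            mids = (u[:-1] + u[1:]) / 2
            best_j = max(
                im.performance_at_cutoff(scores, labels, c).youden_j for c in mids
            )
            assert perf.youden_j == pytest.approx(best_j, abs=1e-12)

    def test_perfectly_separated_gives_j_one_in_gap(self):
        scores = np.array([1.0, 2.0, 8.0, 9.0])
        labels = np.array([False, False, True, True])
        cutoff, perf = im.youden_optimal_cutoff(scores, labels)
        assert perf.youden_j == pytest.approx(1.0)
        assert 2.0 < cutoff < 8.0

    def test_tie_broken_toward_smallest_cutoff(self):
        # both midpoints achieve J = 0.5; the smaller must be returned
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        labels = np.array([False, True, False, True])
        cutoff, perf = im.youden_optimal_cutoff(scores, labels)
        assert cutoff == pytest.approx(0.5)

    def test_cutoff_between_class_means_for_separated_tissue(self, rng):
        hits = 0
        for _ in range(100):
            remote = rng.normal(995, 48, 105)
            infarct = rng.normal(1347, 89, 41)
            scores = np.concatenate([infarct, remote])
            labels = np.concatenate([np.ones(41, bool), np.zeros(105, bool)])
            cutoff, _ = im.youden_optimal_cutoff(scores, labels)
            hits += 995.0 < cutoff < 1347.0
        assert hits >= 99


class TestDelong:
    def test_identical_scores_give_zero_z(self, rng):
        scores, labels = random_instance(rng)
        res = im.delong_compare(scores, scores, labels)
        assert res.z == 0.0
        assert res.p == 1.0

    def test_antisymmetry(self, rng):
        for _ in range(10):
            scores, labels = random_instance(rng, ties=False)
            other = np.asarray(scores)[::-1].copy()
            ab = im.delong_compare(scores, other, labels)
            ba = im.delong_compare(other, scores, labels)
            assert ab.z == pytest.approx(-ba.z, abs=1e-12)
            assert ab.auc_a == ba.auc_b

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            im.delong_compare([1.0, 2.0, 3.0], [1.0, 2.0], [True, False, True])

    def test_auc_se_close_to_bootstrap(self, rng):
        n = 150
        labels = np.concatenate([np.ones(50, bool), np.zeros(100, bool)])
        scores = np.where(labels, rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n))
        se = im.roc_curve(scores, labels).auc_se
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            lab_b = labels[idx]
            if lab_b.all() or not lab_b.any():
                continue
            boot.append(im.roc_curve(scores[idx], lab_b).auc)
        assert se == pytest.approx(np.std(boot, ddof=1), rel=0.15)


class TestBlandAltman:
    def test_identity_and_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        same = im.bland_altman(x, x)
        assert same.bias == 0.0 and same.sd_diff == 0.0
        assert same.loa_low == same.loa_high == 0.0
        shifted = im.bland_altman(x, x + 2.0)
        assert shifted.bias == pytest.approx(2.0)
        assert shifted.sd_diff == 0.0

    def test_matches_direct_formula(self, rng):
        x = rng.normal(20, 5, 40)
        y = x + rng.normal(-1, 2, 40)
        res = im.bland_altman(x, y)
        d = y - x
        assert res.bias == pytest.approx(d.mean(), rel=1e-12)
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), rel=1e-10)
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), rel=1e-10)

    def test_antisymmetric_bias(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert im.bland_altman(x, y).bias == pytest.approx(
            -im.bland_altman(y, x).bias, abs=1e-12
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            im.bland_altman([1.0], [2.0])


class TestLinearRegression:
    def test_identity_line(self):
        x = np.arange(10.0)
        res = im.linear_regression(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(10, 3, 50)
        y = 2.5 * x - 4 + rng.normal(0, 1, 50)
        res = im.linear_regression(x, y)
        design = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(design.T @ design, design.T @ y)
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)

    def test_independent_data_has_small_r2(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        assert im.linear_regression(x, y).r_squared < 0.01

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            im.linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
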
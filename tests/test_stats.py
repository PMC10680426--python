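"""Statistical engine: IRLS logistic fits, AUC/DeLong, bootstrap, Wilcoxon."""

import itertools

import numpy as np
import pytest
import scipy.stats
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from rectdvh.errors import ModelError
from rectdvh.stats import (
    EXPLORATORY_ALPHA,
    PRIMARY_ALPHA,
    auc,
    bonferroni_threshold,
    bootstrap_performance,
    combine_632,
    compare_definitions,
    delong_paired,
    delong_variance_single,
    dichotomize,
    estimate_632,
    fit_logistic,
    significance_policy,
    wilcoxon_signed_rank,
)
from rectdvh.stats import _delong_components  # white-box check against the O(n^2) oracle


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels):
    """Exhaustive Mann-Whitney pair counting."""
    cases = [s for s, l in zip(scores, labels) if l == 1]
    controls = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


def delong_components_naive(scores, labels):
    """O(n^2) structural components: V10_i = mean_j psi(x_i, y_j), V01_j likewise."""
    cases = np.asarray([s for s, l in zip(scores, labels) if l == 1], float)
    controls = np.asarray([s for s, l in zip(scores, labels) if l == 0], float)
    psi = (cases[:, None] > controls[None, :]) + 0.5 * (cases[:, None] == controls[None, :])
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def wilcoxon_enumeration(diffs):
    """Exact two-sided p over all 2^n sign assignments (midranks on |d|)."""
    d = np.asarray([x for x in diffs if x != 0], float)
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=len(d))]
    ws = np.asarray(ws)
    n = len(ws)
    p_le = np.sum(ws <= w_obs + 1e-12) / n
    p_ge = np.sum(ws >= w_obs - 1e-12) / n
    return min(1.0, 2.0 * min(p_le, p_ge))


def youden_scan(probs, labels):
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    best_t, best_j = None, None
    for t in sorted(set(probs)):
        pred = np.asarray(probs) >= t
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        j = tp * n0 - fp * n1  # exact integer-scaled Youden J
        if best_j is None or j > best_j:  # strict: keeps the lowest threshold among ties
            best_j, best_t = j, t
    return best_t


# ---------------------------------------------------------------------------
# logistic fit
# ---------------------------------------------------------------------------

class TestFitLogistic:
    def test_intercept_only_reduction(self):
        rng = np.random.default_rng(0)
        y = (rng.random(200) < 0.3).astype(float)
        X = np.ones((200, 3)) * 2.5  # all covariates zero-variance
        fit = fit_logistic(X, y)
        p = y.mean()
        assert fit.coefficients[1:] == pytest.approx(np.zeros(3))
        assert fit.coefficients[0] == pytest.approx(np.log(p / (1 - p)), abs=1e-6)
        assert fit.dropped_columns == (0, 1, 2)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 4))
        lp = -0.5 + X @ np.array([0.8, -0.4, 0.0, 1.2])
        y = (rng.random(400) < expit(lp)).astype(float)
        fit = fit_logistic(X, y)
        oracle = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients, oracle.params, rtol=1e-6)
        np.testing.assert_allclose(fit.covariance, oracle.cov_params(), rtol=1e-5)
        assert fit.loglik == pytest.approx(oracle.llf, rel=1e-8)
        assert fit.converged

    def test_loglik_dominates_intercept_only(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(size=(100, 2))
            y = (r.random(100) < 0.4).astype(float)
            full = fit_logistic(X, y)
            null = fit_logistic(np.zeros((100, 1)) + 1.0, y)  # zero-variance → intercept only
            assert full.loglik >= null.loglik - 1e-8

    def test_one_class_rejected(self):
        with pytest.raises(ModelError):
            fit_logistic(np.random.default_rng(0).normal(size=(50, 2)), np.zeros(50))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ModelError):
            fit_logistic(np.eye(5), np.array([0, 1, 0, 1, 0.0]))

    def test_separation_flagged(self):
        x = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = (x[:, 0] > 0).astype(float)  # perfectly separable
        fit = fit_logistic(x, y)
        assert not fit.converged

    def test_probabilities_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2)) * 10
        y = (rng.random(60) < 0.5).astype(float)
        fit = fit_logistic(X, y)
        assert np.all(fit.fitted_prob > 0) and np.all(fit.fitted_prob < 1)

    def test_wald_recovery_single_large_cohort(self):
        """Known coefficients land inside ±4 SE at n = 5000."""
        from rectdvh.cohort import sample_covariates

        rng = np.random.default_rng(9)
        X = sample_covariates(5000, rng=rng)
        beta = np.array([-2.2, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0, 8.0])
        y = (rng.random(5000) < expit(beta[0] + X @ beta[1:])).astype(float)
        fit = fit_logistic(X, y)
        se = np.sqrt(np.diag(fit.covariance))
        assert np.all(np.abs(fit.coefficients - beta) < 4 * se)


# ---------------------------------------------------------------------------
# AUC and DeLong
# ---------------------------------------------------------------------------

class TestAuc:
    def test_perfect_and_degenerate(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    def test_worked_example_against_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert auc(scores, labels) == pytest.approx(auc_pair_counting(scores, labels))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**30 - 1))
    def test_equals_pair_counting_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = rng.integers(0, 8, n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            return
        assert auc(scores, labels) == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_flip_symmetry(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        assert auc(scores, labels) == pytest.approx(1.0 - auc(-scores, labels))

    def test_one_class_rejected(self):
        with pytest.raises(ModelError):
            auc([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        a1, a2, z, p = delong_paired(s, s, y)
        assert a1 == a2
        assert p == 1.0

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**30 - 1))
    def test_components_match_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            return
        order = np.concatenate([np.nonzero(labels == 1)[0], np.nonzero(labels == 0)[0]])
        a, v10, v01 = _delong_components(scores, labels)
        o10, o01, oa = delong_components_naive(scores, labels)
        np.testing.assert_allclose(v10, o10, atol=1e-12)
        np.testing.assert_allclose(v01, o01, atol=1e-12)
        assert a == pytest.approx(oa, abs=1e-12)

    def test_variance_close_to_hanley_continuous(self):
        """No-tie continuous case: DeLong variance ≈ the Hanley-McNeil closed form."""
        rng = np.random.default_rng(6)
        n1, n0 = 500, 1500
        scores = np.concatenate([rng.normal(0.5, 1, n1), rng.normal(0, 1, n0)])
        labels = np.concatenate([np.ones(n1), np.zeros(n0)])
        a = auc(scores, labels)
        q1 = a / (2 - a)
        q2 = 2 * a**2 / (1 + a)
        hanley = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
        assert delong_variance_single(scores, labels) == pytest.approx(hanley, rel=0.10)

    def test_detects_genuine_difference(self):
        rng = np.random.default_rng(7)
        n = 600
        signal = rng.normal(size=n)
        y = (rng.random(n) < expit(2 * signal)).astype(int)
        good = signal
        bad = rng.normal(size=n)  # uninformative
        _, _, _, p = delong_paired(good, bad, y)
        assert p < 1e-6


# ---------------------------------------------------------------------------
# thresholds, bootstrap, .632
# ---------------------------------------------------------------------------

class TestDichotomize:
    def test_matches_exhaustive_scan(self):
        probs = np.array([0.1, 0.2, 0.35, 0.35, 0.7, 0.9])
        labels = np.array([0, 0, 1, 0, 1, 1])
        assert dichotomize(probs, labels) == youden_scan(probs, labels)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**30 - 1))
    def test_matches_scan_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        probs = np.round(rng.random(n), 2)
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            return
        assert dichotomize(probs, labels) == youden_scan(probs, labels)

    def test_perfect_separation(self):
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        t = dichotomize(probs, labels)
        pred = probs >= t
        assert (pred == labels.astype(bool)).all()

    def test_all_equal_probabilities(self):
        probs = np.full(6, 0.4)
        labels = np.array([0, 1, 0, 1, 0, 1])
        t = dichotomize(probs, labels)
        assert (probs >= t).all()  # sens 1, spec 0 under the tie-break rule

    def test_fixed_rule(self):
        assert dichotomize([0.2, 0.8], [0, 1], rule="fixed05") == 0.5


def _toy_model_data(n=300, seed=0, beta=1.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = (rng.random(n) < expit(-0.8 + beta * X[:, 0])).astype(float)
    return X, y


class TestBootstrap:
    def test_seed_reproducibility(self):
        X, y = _toy_model_data()
        a = bootstrap_performance(X, y, B=50, rng=123)
        b = bootstrap_performance(X, y, B=50, rng=123)
        assert a.auc_ci == b.auc_ci
        assert a.sens632 == b.sens632

    def test_zero_resamples_flagged(self):
        X, y = _toy_model_data()
        perf = bootstrap_performance(X, y, B=0, rng=0)
        assert perf.auc_ci is None
        assert perf.n_bootstrap == 0

    def test_metrics_in_unit_interval_and_ci_brackets_point(self):
        X, y = _toy_model_data(n=400, seed=3)
        perf = bootstrap_performance(X, y, B=100, rng=5)
        for v in (perf.sens632, perf.spec632, perf.ppv632, perf.npv632):
            assert 0.0 <= v <= 1.0
        lo, hi = perf.auc_ci
        assert lo <= perf.auc <= hi
        assert perf.ci_contains_point

    def test_ci_width_shrinks_with_n(self):
        widths = {}
        for n in (200, 2000):
            X, y = _toy_model_data(n=n, seed=11, beta=0.8)
            perf = bootstrap_performance(X, y, B=200, rng=17)
            widths[n] = perf.auc_ci[1] - perf.auc_ci[0]
        assert widths[2000] < widths[200]

    def test_632_fixed_point_with_perfect_scorer(self):
        # a stub "fit" that reproduces the outcome exactly: apparent = OOB = 1
        class Stub:
            converged = True

            def __init__(self, X, y):
                self.fitted_prob = y.astype(float)
                self.coefficients = None

            def predict_prob(self, X):
                return X[:, 0]  # first covariate IS the outcome below

        X, y = _toy_model_data(n=200, seed=8)
        X = np.column_stack([y, X])
        perf = bootstrap_performance(X, y, B=40, rng=2, fit_fn=lambda a, b: Stub(a, b))
        assert perf.sens632 == pytest.approx(1.0)
        assert perf.spec632 == pytest.approx(1.0)

    def test_combine_632_arithmetic(self):
        assert combine_632(0.1, 0.2) == pytest.approx(0.1632)

    def test_estimate_632_keys(self):
        X, y = _toy_model_data()
        est = estimate_632(X, y, B=30, seed=1)
        assert set(est) == {"sens632", "spec632", "ppv632", "npv632"}


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_identical_pairs(self):
        a = np.arange(10.0)
        assert wilcoxon_signed_rank(a, a) == 1.0

    def test_all_positive_n5_exact(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.zeros(5)
        p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(wilcoxon_enumeration(a - b))
        assert p == pytest.approx(2 / 32)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**30 - 1))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        d = rng.integers(-4, 5, n).astype(float)  # ties and zeros
        if np.all(d == 0):
            return
        p = wilcoxon_signed_rank(d, np.zeros(n))
        assert p == pytest.approx(wilcoxon_enumeration(d), abs=1e-12)

    def test_exact_path_matches_scipy_no_ties(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        ours = wilcoxon_signed_rank(a, b)
        ref = scipy.stats.wilcoxon(a, b, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_approx_path_matches_scipy(self):
        rng = np.random.default_rng(13)
        a = np.round(rng.normal(size=80), 1)
        b = np.round(rng.normal(size=80), 1)
        ours = wilcoxon_signed_rank(a, b)
        ref = scipy.stats.wilcoxon(
            a, b, alternative="two-sided", method="approx", correction=True,
            zero_method="wilcox",
        ).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0.3, 1, 30)
        b = rng.normal(0, 1, 30)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(wilcoxon_signed_rank(b, a))


# ---------------------------------------------------------------------------
# significance policy
# ---------------------------------------------------------------------------

class TestSignificancePolicy:
    def test_bonferroni_printed_threshold(self):
        assert bonferroni_threshold(0.05, 32) == 0.0015
        assert PRIMARY_ALPHA == 0.0015
        assert EXPLORATORY_ALPHA == 0.0001

    def test_primary_flags(self):
        flags = significance_policy([0.002, 0.0005, 0.0015], "primary_model_comparisons")
        assert flags.tolist() == [False, True, False]

    def test_exploratory_flags(self):
        flags = significance_policy([0.0002, 0.00005], "exploratory_dose_levels")
        assert flags.tolist() == [False, True]

    def test_unknown_family_rejected(self):
        with pytest.raises(ModelError):
            significance_policy([0.01], "secondary")


def test_compare_definitions_near_null_rarely_significant():
    """Two noisy derivatives of one dosimetric signal should not differ at .0015."""
    rng = np.random.default_rng(99)
    n_sig = 0
    for rep in range(10):
        n = 400
        signal = rng.normal(size=(n, 3))
        y = (rng.random(n) < expit(-0.5 + signal[:, 0])).astype(float)
        X_a = signal + 0.3 * rng.normal(size=(n, 3))
        X_b = signal + 0.3 * rng.normal(size=(n, 3))
        mc = compare_definitions(X_a, X_b, y, "a", "b", B=0, rng=rep)
        n_sig += mc.significant_primary
    assert n_sig <= 1
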
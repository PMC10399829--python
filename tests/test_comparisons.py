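import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from commodular.comparisons import (compare_ordinations, eigen_profile, fisher_combine,
                                    fisher_z_compare, fisher_z_test, pooled_t_test,
                                    shapiro_wilk, variance_ratio_test)

# Shapiro-Wilk reference values computed with R 4.3.3 stats::shapiro.test on the
# vectors regenerated below (same generator calls, seed 42)
R_SHAPIRO = [(0.9342998674, 0.1867564893), (0.8885625202, 0.06378741721),
             (0.9209446672, 0.02837982285), (0.9113557402, 0.2220509704),
             (0.9240511782, 0.06340831316)]


def _reference_vectors():
    rng = np.random.default_rng(42)
    return [rng.normal(0, 1, 20).round(4), rng.exponential(1, 15).round(4),
            rng.uniform(-2, 2, 30).round(4), np.round(rng.normal(5, 2, 12), 4),
            rng.gamma(2, 1, 25).round(4)]


class TestShapiroWilk:
    def test_near_perfect_normality(self):
        q = stats.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        W, _ = shapiro_wilk(q)
        assert W > 0.99

    def test_skewed_samples_rejected(self):
        rejected = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=50)
            _, p = shapiro_wilk(x)
            rejected += p < 0.01
        assert rejected >= 90

    def test_agreement_with_r_reference(self):
        for x, (W_ref, p_ref) in zip(_reference_vectors(), R_SHAPIRO):
            W, p = shapiro_wilk(x)
            assert W == pytest.approx(W_ref, abs=1e-4)
            assert p == pytest.approx(p_ref, rel=1e-2)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.full(10, 3.0))


class TestPooledT:
    def test_published_lv1_row(self):
        t, p = pooled_t_test(-0.274, 1.008, 36, 0.010, 0.331, 36)
        assert t == pytest.approx(1.473, abs=5e-4)

    def test_published_lv2_row(self):
        t, _ = pooled_t_test(-0.156, 0.583, 36, 0.074, 0.394, 36)
        assert t == pytest.approx(1.394, abs=0.01)

    def test_equal_means_null(self):
        t, p = pooled_t_test(1.0, 2.0, 10, 1.0, 3.0, 10)
        assert t == 0.0 and p == 1.0

    def test_df_modes_differ_only_in_pvalue(self):
        t1, p1 = pooled_t_test(0.0, 1.0, 36, 0.5, 1.0, 36, df_mode="per-sample")
        t2, p2 = pooled_t_test(0.0, 1.0, 36, 0.5, 1.0, 36, df_mode="standard")
        assert t1 == t2 and p1 > p2  # fewer df, heavier tails


class TestVarianceRatio:
    def test_published_rows(self):
        F, p = variance_ratio_test(0.583, 36, 0.394, 36)
        assert F == pytest.approx(1.480, abs=5e-4)
        assert p == pytest.approx(0.2513, abs=5e-4)
        F, _ = variance_ratio_test(1.008, 36, 0.331, 36)
        assert F == pytest.approx(3.049, abs=0.01)

    def test_identity_and_swap_invariance(self):
        F, p = variance_ratio_test(2.0, 15, 2.0, 15)
        assert F == 1.0 and p == pytest.approx(1.0)
        _, p1 = variance_ratio_test(3.1, 20, 1.2, 25)
        _, p2 = variance_ratio_test(1.2, 25, 3.1, 20)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            variance_ratio_test(1.0, 10, 0.0, 10)


class TestFisherCombine:
    def test_published_combinations(self):
        chi2, df, p = fisher_combine([0.1496, 0.0014, 0.1721, 0.2513])
        assert df == 8
        assert chi2 == pytest.approx(23.23, abs=0.05)
        assert p == pytest.approx(0.0031, abs=5e-4)
        chi2, df, p = fisher_combine([0.3059, 0.1605, 0.2123, 0.2334])
        assert chi2 == pytest.approx(12.04, abs=0.01)
        assert p == pytest.approx(0.1496, abs=1e-3)

    def test_uninformative_input(self):
        chi2, df, p = fisher_combine([1.0, 1.0, 1.0])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fisher_combine([0.5, 0.0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8),
           st.integers(min_value=0, max_value=6))
    def test_permutation_invariant_and_monotone(self, ps, idx):
        chi2, df, p = fisher_combine(ps)
        chi2_perm, _, _ = fisher_combine(list(reversed(ps)))
        assert chi2 == pytest.approx(chi2_perm, rel=1e-12)
        smaller = list(ps)
        smaller[idx % len(ps)] = smaller[idx % len(ps)] / 2
        chi2_smaller, _, _ = fisher_combine(smaller)
        assert chi2_smaller >= chi2


class TestFisherZ:
    def test_null_and_closed_form(self):
        z, p = fisher_z_test(0.0, 30)
        assert z == 0.0 and p == 1.0
        z, _ = fisher_z_test(0.5, 28)
        assert z == pytest.approx(math.atanh(0.5) * 5, rel=1e-12) == pytest.approx(2.7465, abs=1e-4)

    def test_antisymmetry(self):
        z1, p1 = fisher_z_test(0.3, 40)
        z2, p2 = fisher_z_test(-0.3, 40)
        assert z1 == -z2 and p1 == p2

    def test_compare_equality_swap_and_arithmetic(self):
        z, p = fisher_z_compare(0.4, 30, 0.4, 50)
        assert z == 0.0 and p == 1.0
        z1, p1 = fisher_z_compare(0.6, 30, 0.1, 40)
        z2, p2 = fisher_z_compare(0.1, 40, 0.6, 30)
        assert z1 == -z2 and p1 == pytest.approx(p2)
        z, _ = fisher_z_compare(0.42, 36, -0.19, 36)
        assert z == pytest.approx(2.60, abs=0.01)

    def test_domain(self):
        with pytest.raises(ValueError):
            fisher_z_test(1.0, 30)
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.2, 30)


def _data_with_exact_correlation(R, n, seed=0):
    """Rows of samples whose sample correlation matrix is exactly R."""
    m = R.shape[0]
    rng = np.random.default_rng(seed)
    base = np.column_stack([np.ones(n), rng.normal(size=(n, m))])
    q, _ = np.linalg.qr(base)
    Z = q[:, 1:] * np.sqrt(n - 1)      # exactly centered, unit variance, orthogonal
    return Z @ np.linalg.cholesky(R).T


class TestEigenProfile:
    def test_trace_conserved(self, study):
        cm, _, _ = study
        vals = eigen_profile(cm)
        assert vals.sum() == pytest.approx(cm.n_taxa, rel=1e-10)
        assert vals.min() > -1e-8
        assert np.all(np.diff(vals) <= 1e-12)

    def test_block_equicorrelation_closed_form(self):
        labels = np.repeat([1, 2], 18)
        R = np.where(labels[:, None] == labels[None, :], 0.25, 0.0)
        np.fill_diagonal(R, 1.0)
        X = _data_with_exact_correlation(R, n=200)
        vals = eigen_profile(X)
        assert vals[0] == pytest.approx(1 + 17 * 0.25, abs=1e-8)
        assert vals[1] == pytest.approx(5.25, abs=1e-8)
        np.testing.assert_allclose(vals[2:], 0.75, atol=1e-8)

    def test_independent_columns_stay_near_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3000, 10))
        vals = eigen_profile(X)
        assert vals.max() < 1.5 and vals.min() > 0.5

    def test_constant_column_rejected(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.raises(ValueError):
            eigen_profile(X)


def _loadings_with_moments(means, variances, n=36, seed=0):
    rng = np.random.default_rng(seed)
    cols = []
    for m, v in zip(means, variances):
        x = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        x = rng.permutation(x)
        x = (x - x.mean()) / x.std(ddof=1)
        cols.append(m + np.sqrt(v) * x)
    return np.column_stack(cols)


class TestCompareOrdinations:
    def test_identity_comparison_is_null(self):
        A = _loadings_with_moments([0.0, 0.1], [1.0, 0.5])
        rep = compare_ordinations(A, A)
        assert all(t == 0.0 for t in rep.t_stats)
        assert all(F == pytest.approx(1.0) for F in rep.f_stats)
        assert rep.combined_p == pytest.approx(1.0)
        assert rep.compare_z == 0.0

    def test_reproduces_published_marginal_comparison(self):
        """Original vs completely randomized marginals combine to p = 0.0031."""
        A = _loadings_with_moments([-0.274, -0.156], [1.008, 0.583], seed=1)
        B = _loadings_with_moments([0.010, 0.074], [0.331, 0.394], seed=2)
        rep = compare_ordinations(A, B)
        assert rep.combined_p == pytest.approx(0.0031, abs=5e-4)
        assert rep.t_stats[0] == pytest.approx(1.473, abs=5e-4)
        assert rep.f_stats[1] == pytest.approx(1.480, abs=5e-4)

    def test_requires_two_columns(self):
        with pytest.raises(ValueError):
            compare_ordinations(np.zeros((10, 1)), np.zeros((10, 1)))

    def test_normality_warning_reported_not_enforced(self):
        rng = np.random.default_rng(0)
        A = np.column_stack([rng.exponential(size=36) ** 3, rng.normal(size=36)])
        B = _loadings_with_moments([0.0, 0.0], [1.0, 1.0])
        with pytest.warns(UserWarning, match="normality"):
            rep = compare_ordinations(A, B)
        assert rep.normality_warning
        assert 0.0 <= rep.combined_p <= 1.0
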
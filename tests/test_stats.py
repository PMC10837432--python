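"""Permutational statistics against independent oracles.

The central oracle: for univariate Euclidean input the PERMANOVA pseudo-F
is algebraically the classical one-way ANOVA F, so scipy's f_oneway (and
exhaustive enumeration for small n) can check the distance-matrix route
without sharing any code with it.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stst
from scipy import stats as sps

from spongetrace import stats as st


def brute_force_distances(x):
    x = np.atleast_2d(np.asarray(x, float).T).T
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(((x[i] - x[j]) ** 2).sum())
    return out


class TestEuclidean:
    def test_scalar_triple(self):
        d = st.euclidean_dist([0.0, 3.0, 4.0])
        assert d[0, 1] == 3 and d[0, 2] == 4 and d[1, 2] == 1

    def test_identical_rows_zero_matrix(self):
        d = st.euclidean_dist(np.ones((4, 3)))
        assert np.all(d == 0)

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=(5, 3))
        assert np.allclose(st.euclidean_dist(x), brute_force_distances(x))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            st.euclidean_dist([1.0, np.nan, 2.0])


class TestPermanova:
    def test_two_triples_exact(self):
        """{1,2,3} vs {4,5,6}: F = 13.5; exhaustive p over C(6,3)=20
        assignments is 2/20 = 0.1."""
        d = st.euclidean_dist([1, 2, 3, 4, 5, 6])
        res = st.permanova(d, ["a"] * 3 + ["b"] * 3, permutations=999, seed=0)
        assert res.pseudo_f == pytest.approx(13.5, abs=1e-9)
        assert res.method == "exact"
        assert res.permutations == 20
        assert res.p_perm == pytest.approx(0.1, abs=1e-12)

    def test_equals_classical_anova_f(self, rng):
        """Pseudo-F == one-way ANOVA F to 1e-9 on 50 random datasets."""
        for _ in range(50):
            sizes = rng.integers(2, 7, size=rng.integers(2, 5))
            groups = [rng.normal(rng.normal(), 1.0, size=s) for s in sizes]
            x = np.concatenate(groups)
            labels = np.repeat(np.arange(len(groups)), sizes)
            res = st.permanova(st.euclidean_dist(x), labels,
                               permutations=9, seed=1)
            f_ref = sps.f_oneway(*groups).statistic
            assert res.pseudo_f == pytest.approx(f_ref, abs=1e-9, rel=1e-9)

    def test_ss_partition_closes(self, rng):
        x = rng.normal(size=12)
        res = st.permanova(st.euclidean_dist(x), np.repeat([0, 1, 2], 4),
                           permutations=99, seed=3)
        assert res.ss_total == pytest.approx(res.ss_between + res.ss_within)
        assert 0 <= res.r2 <= 1

    def test_all_identical_degenerate(self):
        d = st.euclidean_dist([2.0] * 6)
        res = st.permanova(d, [0, 0, 0, 1, 1, 1], permutations=99, seed=0)
        assert res.degenerate
        assert res.pseudo_f == 0.0 and res.p_perm == 1.0

    def test_p_confined_to_valid_range(self, rng):
        for _ in range(10):
            x = rng.normal(size=10)
            res = st.permanova(st.euclidean_dist(x), np.repeat([0, 1], 5),
                               permutations=49, seed=int(rng.integers(2 ** 31)))
            assert 1.0 / (res.permutations + 1) <= res.p_perm + 1e-15
            assert res.p_perm <= 1.0

    def test_sampled_and_exact_p_agree(self, rng):
        """Monte-Carlo p within 3*sqrt(p(1-p)/B) of the exhaustive p."""
        x = np.concatenate([rng.normal(0, 1, 5), rng.normal(1.2, 1, 5)])
        labels = np.repeat([0, 1], 5)
        d = st.euclidean_dist(x)
        exact = st.permanova(d, labels, permutations=999, seed=0)
        assert exact.method == "exact"       # 252 arrangements < 10*999
        b = 24                               # forces the sampled path: 252 > 240
        sampled = st.permanova(d, labels, permutations=b, seed=5)
        assert sampled.method == "sampled-unique"
        tol = 3 * np.sqrt(exact.p_perm * (1 - exact.p_perm) / b)
        assert abs(sampled.p_perm - exact.p_perm) <= tol + 1.0 / (b + 1)

    def test_terms_single_factor_matches_permanova(self, rng):
        x = rng.normal(size=12)
        labels = np.repeat([0, 1, 2], 4)
        d = st.euclidean_dist(x)
        one = st.permanova(d, labels, permutations=99, seed=0)
        terms = st.permanova_terms(d, {"g": labels}, permutations=99, seed=0)
        assert len(terms) == 1
        assert terms[0].pseudo_f == pytest.approx(one.pseudo_f, abs=1e-9)
        assert terms[0].ss_between == pytest.approx(one.ss_between, abs=1e-9)

    def test_terms_sequential_ss_matches_anova_lm(self, rng):
        """Two-factor sequential SS equals classical Type-I ANOVA on
        univariate data (statsmodels as the independent route)."""
        import pandas as pd
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        a = np.repeat(["u", "v"], 6)
        b = np.tile(np.repeat(["x", "y"], 3), 2)
        y = rng.normal(size=12) + (a == "u") * 0.8 + (b == "x") * 0.3
        terms = st.permanova_terms(st.euclidean_dist(y),
                                   {"A": a, "B": b}, permutations=49, seed=0)
        tab = sm.stats.anova_lm(
            smf.ols("y ~ C(A) + C(B)",
                    data=pd.DataFrame({"y": y, "A": a, "B": b})).fit(), typ=1)
        assert terms[0].ss_between == pytest.approx(tab.sum_sq["C(A)"], rel=1e-9)
        assert terms[1].ss_between == pytest.approx(tab.sum_sq["C(B)"], rel=1e-9)
        assert terms[1].ss_within == pytest.approx(tab.sum_sq["Residual"], rel=1e-9)
        assert terms[0].pseudo_f == pytest.approx(tab.F["C(A)"], rel=1e-9)


class TestPairwise:
    def test_three_groups_three_pairs_bonferroni(self, rng):
        x = np.concatenate([rng.normal(m, 1, 5) for m in (0, 0.2, 4)])
        labels = np.repeat(list("abc"), 5)
        res = st.pairwise_permanova(st.euclidean_dist(x), labels,
                                    permutations=199, seed=0)
        assert len(res) == 3
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_perm * 3))

    def test_adjusted_p_capped_at_one(self):
        # a pair with raw p = 0.4 and m = 3 must cap at 1.0
        r = st.PermanovaResult("x", 1, 0.1, 0.4, 99, 1, 0.1, 0.9, 1, 8, "exact",
                               p_adjusted=min(1.0, 0.4 * 3))
        assert r.p_adjusted == 1.0

    def test_divergent_group_detected(self, rng):
        """Only the two pairs involving the shifted group reject."""
        hits = 0
        for rep in range(20):
            g = np.random.default_rng(rep)
            x = np.concatenate([g.normal(0, 1, 6), g.normal(0, 1, 6),
                                g.normal(5, 1, 6)])
            res = st.pairwise_permanova(st.euclidean_dist(x),
                                        np.repeat(list("abc"), 6),
                                        permutations=199, seed=rep)
            by = {r.factor: r for r in res}
            if (by["a vs c"].p_adjusted <= 0.05 and by["b vs c"].p_adjusted <= 0.05
                    and by["a vs b"].p_adjusted > 0.05):
                hits += 1
        assert hits >= 18    # >= 90% of runs at this effect size


class TestKruskalWallis:
    def test_complete_separation_two_triples(self):
        """Two groups of three with complete rank separation: H = 3.857."""
        res = st.kruskal_wallis([[1.0, 2.0, 3.0], [10.0, 11.0, 12.0]])
        assert res.h == pytest.approx(27.0 / 7.0, abs=1e-12)
        assert round(res.h, 3) == 3.857
        # chi2 approximation and the exact null disagree at this n:
        assert res.p_chi2 == pytest.approx(0.0495, abs=5e-4)
        assert res.p_exact == pytest.approx(0.1, abs=1e-12)

    def test_all_tied_degenerate(self):
        res = st.kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.degenerate and res.h == 0.0

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            groups = [np.round(rng.normal(size=rng.integers(3, 8)), 1)
                      for _ in range(rng.integers(2, 5))]
            res = st.kruskal_wallis(groups, exact_max_n=0)
            ref = sps.kruskal(*groups)
            assert res.h == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_chi2 == pytest.approx(ref.pvalue, rel=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(stst.lists(stst.integers(-1000, 1000), min_size=6, max_size=12,
                      unique=True))
    def test_invariant_under_monotone_transform(self, values):
        # integer inputs keep the tie structure stable under the transform
        a, b = values[: len(values) // 2], values[len(values) // 2:]
        base = st.kruskal_wallis([a, b], exact_max_n=0).h
        f = lambda v: np.exp(np.asarray(v, float) / 400.0)
        assert st.kruskal_wallis([f(a), f(b)], exact_max_n=0).h == pytest.approx(
            base, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.kruskal_wallis([[1, 2], []])


class TestWelch:
    def test_identical_samples(self):
        res = st.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_statistic_grows_with_shift(self):
        a = np.array([1.0, 2.0, 3.0])
        ts = [abs(st.welch_t(a, a + dlt).t) for dlt in (0.5, 1.0, 2.0, 5.0)]
        assert ts == sorted(ts)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 9))
            b = rng.normal(0.5, 2, rng.integers(3, 9))
            res = st.welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(ref.statistic, rel=1e-10)
            assert res.df == pytest.approx(ref.df, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_constant_samples(self):
        res = st.welch_t([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.p == 1.0
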
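"""Group statistics: rank tests against enumeration oracles, Fisher's exact
test, covariate-adjusted comparison, and Benjamini–Hochberg control."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import evcohort as ec
from evcohort.stats import StatsError


# ---------------------------------------------------------------- oracles
def mw_exact_p_enumeration(x, y):
    """Exact two-sided Mann–Whitney p by enumerating all C(n+m, n) labelings."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n * (n + 1) / 2

    u_obs = u_of(range(n))
    mean_u = n * len(y) / 2
    dev_obs = abs(u_obs - mean_u)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(u_of(idx) - mean_u) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


def fisher_exact_p_enumeration(table):
    """Two-sided Fisher p by enumerating all 2×2 tables with fixed margins
    (probability-mass rule)."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def pmf(aa):
        return (
            math.comb(r1, aa) * math.comb(r2, c1 - aa) / math.comb(N, c1)
        )

    p_obs = pmf(a)
    return sum(
        pmf(aa)
        for aa in range(max(0, c1 - r2), min(r1, c1) + 1)
        if pmf(aa) <= p_obs * (1 + 1e-9)
    )


def kruskal_h_by_hand(samples):
    """H from the rank-sum formula (no ties)."""
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start : start + len(s)].sum()
        h += r**2 / len(s)
        start += len(s)
    return 12.0 / (N * (N + 1)) * h - 3 * (N + 1)


# ------------------------------------------------------------ Mann-Whitney
class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        res = ec.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.exact
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples(self):
        res = ec.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_matches_enumeration_oracle_8v8(self):
        rng = np.random.default_rng(12)
        for _ in range(3):
            x = rng.normal(size=8)
            y = rng.normal(0.8, 1.0, size=8)
            res = ec.mann_whitney_u(x, y)
            assert res.exact
            assert res.p_value == pytest.approx(mw_exact_p_enumeration(x, y), abs=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_matches_enumeration_all_small_n(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = ec.mann_whitney_u(x, y)
        assert res.p_value == pytest.approx(mw_exact_p_enumeration(x, y), abs=1e-12)

    def test_ties_use_asymptotic_path(self):
        res = ec.mann_whitney_u([1, 1, 2, 3], [2, 4, 5, 6])
        assert not res.exact
        assert 0 <= res.p_value <= 1

    @settings(derandomize=True, max_examples=25)
    @given(
        st.lists(st.integers(min_value=-100, max_value=100), min_size=3, max_size=8,
                 unique=True),
        st.lists(st.integers(min_value=101, max_value=300), min_size=3, max_size=8,
                 unique=True),
    )
    def test_invariant_under_monotone_transform(self, x, y):
        p1 = ec.mann_whitney_u(x, y).p_value
        fx = [math.exp(v / 50.0) for v in x]
        fy = [math.exp(v / 50.0) for v in y]
        p2 = ec.mann_whitney_u(fx, fy).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)


# ---------------------------------------------------------- Kruskal-Wallis
class TestKruskalWallis:
    def test_hand_computed_example(self):
        res = ec.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32.0 / 7.0)

    def test_identical_groups(self):
        res = ec.kruskal_wallis([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(4)
        samples = [rng.normal(loc, 1, size=6) for loc in (0.0, 0.5, 1.0)]
        res = ec.kruskal_wallis(samples)
        assert res.statistic == pytest.approx(kruskal_h_by_hand(samples), abs=1e-10)

    def test_rejects_two_groups(self):
        with pytest.raises(StatsError):
            ec.kruskal_wallis([[1, 2], [3, 4]])


# ------------------------------------------------------------ Fisher exact
class TestFisherExact:
    def test_sex_table(self):
        # 2 M / 6 F in KOA vs 5 M / 3 F in controls
        res = ec.fisher_exact_2x2([[2, 6], [5, 3]])
        assert res.p_value == pytest.approx(4050 / 12870, abs=1e-9)
        assert round(res.p_value, 3) == 0.315

    def test_identical_rows(self):
        res = ec.fisher_exact_2x2([[4, 4], [4, 4]])
        assert res.p_value == pytest.approx(1.0)

    def test_proportional_rows_p_one(self):
        res = ec.fisher_exact_2x2([[2, 4], [3, 6]])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [[[2, 6], [5, 3]], [[0, 5], [5, 0]], [[3, 3], [3, 3]], [[1, 7], [6, 2]],
         [[4, 0], [2, 6]]],
    )
    def test_matches_enumeration_oracle(self, table):
        res = ec.fisher_exact_2x2(table)
        assert res.p_value == pytest.approx(fisher_exact_p_enumeration(table), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(StatsError):
            ec.fisher_exact_2x2([[1, -2], [3, 4]])


# ------------------------------------------------ covariate-adjusted model
class TestCovariateAdjusted:
    def test_recovers_group_effect(self):
        rng = np.random.default_rng(0)
        n = 200
        group = np.repeat(["control", "KOA"], n // 2)
        age = rng.normal(50, 10, n)
        y = 2.0 * (group == "KOA") + 0.05 * age + rng.normal(0, 1, n)
        res = ec.covariate_adjusted_test(y, group, {"age": age})
        assert res.extras["coef"] == pytest.approx(2.0, abs=0.2)
        assert res.p_value < 0.01

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        n = 60
        group = np.repeat(["control", "KOA"], n // 2)
        pvals = []
        for _ in range(200):
            age = rng.normal(50, 10, n)
            y = 0.05 * age + rng.normal(0, 1, n)
            pvals.append(ec.covariate_adjusted_test(y, group, {"age": age}).p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_duplicated_covariate_raises(self):
        rng = np.random.default_rng(2)
        group = np.repeat(["control", "KOA"], 10)
        age = rng.normal(50, 10, 20)
        with pytest.raises(StatsError, match="collinear"):
            ec.covariate_adjusted_test(
                rng.normal(size=20), group, {"age": age, "age2": age}
            )

    def test_interaction_terms_reported(self):
        rng = np.random.default_rng(3)
        group = np.repeat(["control", "KOA"], 50)
        age = rng.normal(50, 10, 100)
        y = rng.normal(size=100)
        res = ec.covariate_adjusted_test(y, group, {"age": age}, interactions=True)
        assert "group:age" in res.extras["interaction_p"]


# --------------------------------------------------------------- Pearson r
class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert ec.pearson_correlation(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert ec.pearson_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 30))
        r = ec.pearson_correlation(x, y).statistic
        expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(StatsError):
            ec.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# --------------------------------------------------------- Benjamini-Hochberg
class TestBenjaminiHochberg:
    def test_hand_checked_thresholds(self):
        report = ec.benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.2], alpha=0.05)
        assert report.thresholds == pytest.approx((0.01, 0.02, 0.03, 0.04, 0.05))
        assert report.k_star == 4
        assert report.critical_value == pytest.approx(0.04)
        assert sum(report.reject.values()) == 4

    def test_all_ones_no_rejection(self):
        report = ec.benjamini_hochberg([1.0] * 6, alpha=0.05)
        assert report.k_star == 0
        assert not report.threshold_met
        assert report.critical_value == pytest.approx(0.05 / 6)

    def test_printed_critical_value(self):
        # alpha=0.05, m=38, k*=5 reproduces the published 0.00658 cutoff
        p = [0.0001, 0.0005, 0.001, 0.003, 0.0065] + [0.5] * 33
        report = ec.benjamini_hochberg(p, alpha=0.05)
        assert report.k_star == 5
        assert report.critical_value == pytest.approx(0.00658, abs=5e-6)

    def test_matches_statsmodels_rejections(self):
        rng = np.random.default_rng(6)
        p = np.concatenate([rng.uniform(0, 0.01, 5), rng.uniform(0, 1, 30)])
        report = ec.benjamini_hochberg(p, alpha=0.05, variables=range(len(p)))
        sm_reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        mine = np.array([report.reject[str(i)] for i in range(len(p))])
        assert (mine == sm_reject).all()

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2,
                 max_size=30)
    )
    def test_monotone_in_alpha(self, pvals):
        r1 = ec.benjamini_hochberg(pvals, alpha=0.02)
        r2 = ec.benjamini_hochberg(pvals, alpha=0.1)
        assert r2.k_star >= r1.k_star

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2,
                 max_size=30)
    )
    def test_rejects_superset_of_bonferroni(self, pvals):
        alpha = 0.05
        report = ec.benjamini_hochberg(pvals, alpha=alpha, variables=range(len(pvals)))
        bonf = {str(i) for i, p in enumerate(pvals) if p <= alpha / len(pvals)}
        bh = {v for v, rej in report.reject.items() if rej}
        assert bonf <= bh

    def test_invalid_p_rejected(self):
        with pytest.raises(StatsError):
            ec.benjamini_hochberg([0.5, 1.2])


def test_run_univariate_batch(strong_cohort):
    table, truth = strong_cohort
    out = ec.run_univariate(table)
    assert set(out.columns) == {"variable", "method", "statistic", "p", "exact",
                                "bh_reject"}
    assert len(out) == 38
    assert out["exact"].all()  # 8 vs 8, continuous: exact path everywhere
    # strong planted effects: grouped variables dominate the rejections
    rejected = set(out.loc[out["bh_reject"], "variable"])
    grouped = {v for v, g in truth.group_ids.items() if g != "residual"}
    assert len(rejected & grouped) >= 20
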
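import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from seasonet import (bh_qvalues, correlation_matrix, normality_screen,
                      p_threshold_for_q)


def rank_then_pearson(x, y):
    """Independent oracle: average-rank both vectors, then Pearson."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def brute_force_bh_threshold(pvals, q):
    """O(m^2) oracle: largest p such that declaring p<=it keeps BH valid."""
    p = sorted(pvals)
    m = len(p)
    best = 0.0
    for k, pk in enumerate(p, start=1):
        if pk <= q * k / m:
            best = pk
    return best


class TestCorrelationMatrix:
    def test_monotone_and_antitone_pairs(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [10, 20, 30, 40],
                           "z": [40, 30, 20, 10]}, dtype=float)
        cs = correlation_matrix(df)
        assert cs.pair("x", "y")[0] == pytest.approx(1.0)
        assert cs.pair("x", "z")[0] == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_pearson(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        df = pd.DataFrame({"x": x, "y": y}, dtype=float)
        cs = correlation_matrix(df)
        # hand value: Pearson of midranks = 1.5/sqrt(2.5) = 0.94868...
        assert cs.pair("x", "y")[0] == pytest.approx(1.5 / np.sqrt(2.5), abs=1e-12)
        assert cs.pair("x", "y")[0] == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    def test_matches_oracle_on_many_random_small_vectors(self):
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 5, size=n).astype(float)  # ties likely
            y = rng.integers(0, 5, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            df = pd.DataFrame({"x": x, "y": y})
            rho = correlation_matrix(df).pair("x", "y")[0]
            worst = max(worst, abs(rho - rank_then_pearson(x, y)))
        assert worst < 1e-12

    def test_matches_scipy_spearmanr(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(12, 8)),
                          columns=[f"v{i}" for i in range(8)])
        cs = correlation_matrix(df, exact_null_max_n=0)  # t-approx, as scipy
        ref_rho, ref_p = stats.spearmanr(df.to_numpy())
        assert np.allclose(cs.rho, ref_rho, atol=1e-12)
        off = ~np.eye(8, dtype=bool)
        assert np.allclose(cs.pval[off], ref_p[off], atol=1e-10)

    def test_exact_null_pvalues_match_full_enumeration(self):
        # tie-free n=6: compare the DP-built permutation null against a
        # brute-force enumeration of all 720 rank orderings
        import itertools as it
        rng = np.random.default_rng(22)
        base = np.arange(1, 7)
        for _ in range(10):
            x = rng.permutation(6).astype(float)
            y = rng.permutation(6).astype(float)
            df = pd.DataFrame({"x": x, "y": y})
            p = correlation_matrix(df).pair("x", "y")[1]
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            t_obs = int(rx @ ry)
            ts = np.array([int(base @ np.array(perm))
                           for perm in it.permutations(base)])
            ge = np.mean(ts >= t_obs)
            le = np.mean(ts <= t_obs)
            assert p == pytest.approx(min(1.0, 2 * min(ge, le)), abs=1e-12)

    def test_exact_null_used_for_monthly_series(self):
        # perfectly monotone tie-free pair at n=12: exact two-sided
        # p = 2/12!, far from the t approximation's 0
        df = pd.DataFrame({"x": np.arange(12.0),
                           "y": np.arange(12.0)**2 + 1})
        p = correlation_matrix(df).pair("x", "y")[1]
        import math
        assert p == pytest.approx(2 / math.factorial(12), rel=1e-9)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = correlation_matrix(pd.DataFrame({"x": x, "y": y})).pair("x", "y")[0]
        warped = correlation_matrix(
            pd.DataFrame({"x": np.exp(x), "y": y**3})).pair("x", "y")[0]
        assert warped == pytest.approx(base, abs=1e-12)

    def test_constant_variable_recorded_as_missing(self):
        df = pd.DataFrame({"flat": [1.0] * 6, "x": np.arange(6.0),
                           "y": [2, 1, 4, 3, 6, 5.0]})
        cs = correlation_matrix(df)
        assert np.isnan(cs.pair("flat", "x")[0])
        assert not np.isnan(cs.pair("x", "y")[0])

    def test_pairwise_complete_counts(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5, np.nan],
                           "y": [2, 1, 4, 3, 6, 5.0],
                           "z": np.arange(6.0)})
        cs = correlation_matrix(df)
        i, j = cs.index_of("x"), cs.index_of("y")
        assert cs.n_used[i, j] == 5
        assert cs.n_used[cs.index_of("y"), cs.index_of("z")] == 6

    def test_exact_permutation_pvalue_small_n(self):
        # perfectly monotone n=4: exact two-sided p = 2/4! = 1/12
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 5, 9]})
        cs = correlation_matrix(df, exact_max_n=9)
        assert cs.pair("x", "y")[1] == pytest.approx(2 / 24)

    def test_qval_at_least_pval(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(12, 10)))
        df.columns = [f"v{i}" for i in range(10)]
        cs = correlation_matrix(df)
        off = ~np.eye(10, dtype=bool)
        assert np.all(cs.qval[off] >= cs.pval[off] - 1e-15)


class TestBenjaminiHochberg:
    def test_worked_list(self):
        assert p_threshold_for_q([0.001, 0.01, 0.02, 0.2, 0.5], 0.05) == 0.02

    def test_all_ones_gives_zero(self):
        assert p_threshold_for_q([1.0, 1.0, 1.0], 0.05) == 0.0

    def test_single_pvalue_reduces_to_direct_comparison(self):
        assert p_threshold_for_q([0.04], 0.05) == 0.04
        assert p_threshold_for_q([0.06], 0.05) == 0.0

    def test_randomized_lists_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            q = float(rng.uniform(0.01, 0.2))
            assert p_threshold_for_q(p, q) == pytest.approx(
                brute_force_bh_threshold(p, q), abs=1e-15)

    def test_monotone_in_q_target(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        thresholds = [p_threshold_for_q(p, q) for q in (0.01, 0.05, 0.1, 0.2)]
        assert thresholds == sorted(thresholds)

    def test_qvalues_match_statsmodels(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        ours = bh_qvalues(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)

    def test_threshold_consistent_with_qvalues(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(0, 0.01, 5), rng.uniform(size=45)])
        thr = p_threshold_for_q(p, 0.05)
        q = bh_qvalues(p)
        assert np.all(q[p <= thr] <= 0.05 + 1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            p_threshold_for_q([], 0.05)


class TestNormalityScreen:
    def test_heavy_tailed_variables_flagged(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {f"v{i}": np.exp(rng.normal(0, 2, size=12)) for i in range(40)})
        rep = normality_screen(df, alpha=0.05)
        assert rep.violation_fraction > 0.5
        assert rep.recommended_method == "spearman"

    def test_exact_normal_quantiles_not_flagged(self):
        q = stats.norm.ppf(np.linspace(0.05, 0.95, 12))
        df = pd.DataFrame({"v": q})
        rep = normality_screen(df)
        assert rep.pvalues["v"] > 0.05
        assert rep.violation_fraction == 0.0

    def test_majority_violation_recommends_spearman(self):
        rng = np.random.default_rng(10)
        cols = {f"h{i}": np.exp(rng.normal(0, 2, size=12)) for i in range(9)}
        cols["n0"] = stats.norm.ppf(np.linspace(0.05, 0.95, 12))
        rep = normality_screen(pd.DataFrame(cols))
        assert rep.recommended_method == "spearman"

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            normality_screen(pd.DataFrame({"v": [1.0, 2.0]}))
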
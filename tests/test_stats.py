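"""Friedman/Kendall, Nemenyi CD, exact Wilcoxon, DeLong, BCa bootstrap."""

from itertools import product

import numpy as np
import pytest
from scipy import stats as sps

from wavepool.stats import (NEMENYI_Q, ScoreMatrix, _bca_interval, bca_ci,
                            delong, friedman, kendalls_w, nemenyi_cd,
                            nemenyi_cliques, rank_biserial, truncate_p,
                            wilcoxon_signed_rank_exact)


def make_matrix(scores):
    scores = np.asarray(scores, dtype=float)
    return ScoreMatrix(scores, [f"m{j}" for j in range(scores.shape[1])])


class TestFriedman:
    def test_full_ties_zero_statistic(self):
        res = friedman(make_matrix(np.ones((6, 4))))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_consistent_ranking_hand_value(self):
        # N=10 cases, k=3 methods, identical ordering everywhere
        scores = np.tile([1.0, 2.0, 3.0], (10, 1))
        res = friedman(make_matrix(scores))
        assert res.statistic == pytest.approx(20.0)

    def test_matches_direct_formula_oracle(self, rng):
        scores = rng.random((12, 5))
        n, k = scores.shape
        ranks = np.array([sps.rankdata(-row) for row in scores])
        rbar = ranks.mean(axis=0)
        want = 12 * n / (k * (k + 1)) * np.sum(rbar ** 2) - 3 * n * (k + 1)
        assert friedman(make_matrix(scores)).statistic == pytest.approx(want, abs=1e-10)

    def test_matches_scipy_on_tie_free_data(self, rng):
        scores = rng.standard_normal((15, 4))
        got = friedman(make_matrix(scores))
        stat, p = sps.friedmanchisquare(*scores.T)
        assert got.statistic == pytest.approx(stat, abs=1e-10)
        assert got.p_value == pytest.approx(p, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random((10, 3))
        a = friedman(make_matrix(scores)).statistic
        b = friedman(make_matrix(np.exp(5 * scores))).statistic
        assert a == pytest.approx(b, abs=1e-10)

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            make_matrix([[1.0, np.nan], [2.0, 3.0]])


class TestKendallsW:
    def test_perfect_agreement(self):
        assert kendalls_w(make_matrix(np.tile([3.0, 2.0, 1.0], (8, 1)))) == pytest.approx(1.0)

    def test_full_ties(self):
        assert kendalls_w(make_matrix(np.ones((5, 3)))) == 0.0

    def test_identity_with_friedman(self, rng):
        m = make_matrix(rng.random((9, 4)))
        res = friedman(m)
        assert kendalls_w(m) * 9 * 3 == pytest.approx(res.statistic, abs=1e-10)


class TestNemenyi:
    def test_printed_value_k6_n15(self):
        assert nemenyi_cd(6, 15) == pytest.approx(2.850 * np.sqrt(42 / 90), abs=1e-9)
        assert nemenyi_cd(6, 15) == pytest.approx(1.947, abs=2e-3)

    def test_doubling_n_shrinks_by_sqrt2(self):
        assert nemenyi_cd(4, 10) / nemenyi_cd(4, 20) == pytest.approx(np.sqrt(2))

    def test_k2_split_rule(self):
        cd = nemenyi_cd(2, 10)
        cliques = nemenyi_cliques([1.0, 1.0 + cd + 0.01], cd)
        assert [0] in [list(c) for c in cliques] and [1] in [list(c) for c in cliques]
        together = nemenyi_cliques([1.0, 1.0 + cd - 0.01], cd)
        assert [0, 1] in [list(c) for c in together]

    def test_out_of_table_k(self):
        with pytest.raises(ValueError, match="2..10"):
            nemenyi_cd(15, 10)


class TestWilcoxonExact:
    def test_five_same_sign_one_sided(self):
        res = wilcoxon_signed_rank_exact([1, 2, 3, 4, 5], [0, 0, 0, 0, 0], "greater")
        assert res.p_value == pytest.approx(1 / 32)
        assert truncate_p(res.p_value) == 0.0312

    def test_single_pair(self):
        assert wilcoxon_signed_rank_exact([1.0], [0.0], "greater").p_value == 0.5

    def test_matches_full_enumeration_oracle(self):
        ranks = np.array([1.0, 2, 3, 4, 5])
        x = np.array([0.5, 1.2, 2.1, 3.3, 4.0])
        for signs in product([1, -1], repeat=5):
            y = x - np.array(signs) * x  # differences = signs * x
            res = wilcoxon_signed_rank_exact(x, y, "greater")
            w_obs = ranks[np.array(signs) > 0].sum()
            count = sum(1 for assign in product([0, 1], repeat=5)
                        if ranks[np.array(assign) == 1].sum() >= w_obs)
            assert res.p_value == pytest.approx(count / 32)

    def test_matches_scipy_exact(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        for alt, scipy_alt in [("greater", "greater"), ("less", "less"),
                               ("two_sided", "two-sided")]:
            got = wilcoxon_signed_rank_exact(x, y, alt).p_value
            want = sps.wilcoxon(x, y, alternative=scipy_alt, method="exact").pvalue
            assert got == pytest.approx(want, abs=1e-12)

    def test_p_values_are_dyadic(self, rng):
        x, y = rng.standard_normal((2, 6))
        p = wilcoxon_signed_rank_exact(x, y, "greater").p_value
        assert (p * 2 ** 6) == pytest.approx(round(p * 2 ** 6))

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank_exact([1.0, 2.0], [1.0, 2.0])


class TestRankBiserial:
    def test_all_favorable(self):
        assert rank_biserial([2, 3, 4], [1, 1, 1]) == 1.0

    def test_mirror_symmetric_is_zero(self):
        assert rank_biserial([1.0, -1.0], [0.0, 0.0]) == 0.0

    def test_antisymmetry(self, rng):
        x, y = rng.standard_normal((2, 10))
        assert rank_biserial(x, y) == pytest.approx(-rank_biserial(y, x))

    def test_bounded(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 7))
            assert -1.0 <= rank_biserial(x, y) <= 1.0


class TestDeLong:
    def test_identical_scores(self, rng):
        y = np.array([0, 1] * 20)
        s = rng.random(40)
        res = delong(y, s, s)
        assert res.effect_size == 0.0 and res.p_value == 1.0

    def test_auc_consistency_with_roc_auc(self, rng):
        from wavepool.metrics import roc_auc

        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        a, b = rng.random((2, 60))
        res = delong(y, a, b)
        assert res.extra["auc_a"] == pytest.approx(roc_auc(y, a), abs=1e-12)
        assert res.extra["auc_b"] == pytest.approx(roc_auc(y, b), abs=1e-12)

    def test_variance_close_to_paired_bootstrap(self):
        rng = np.random.default_rng(0)
        n = 200
        y = np.array([1] * 100 + [0] * 100)
        a = rng.normal(y, 1.0)
        b = rng.normal(y, 1.5)
        res = delong(y, a, b)
        boots = []
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.min() == yy.max():
                continue
            pos, neg = idx[yy == 1], idx[yy == 0]
            da = (a[pos][:, None] > a[neg][None, :]).mean() + \
                 0.5 * (a[pos][:, None] == a[neg][None, :]).mean()
            db = (b[pos][:, None] > b[neg][None, :]).mean() + \
                 0.5 * (b[pos][:, None] == b[neg][None, :]).mean()
            boots.append(da - db)
        boot_var = np.var(boots)
        assert res.extra["var"] == pytest.approx(boot_var, rel=0.2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong(np.zeros(10), np.random.rand(10), np.random.rand(10))


class TestBcaCi:
    def test_constant_sample_zero_width(self):
        lo, hi = bca_ci(np.full(20, 3.3), np.mean, B=200,
                        rng=np.random.default_rng(0))
        assert lo == hi == pytest.approx(3.3)

    def test_reduces_to_percentile_when_z0_a_zero(self):
        thetas = np.random.default_rng(1).standard_normal(10_000)
        lo, hi = _bca_interval(thetas, 0.0, z0=0.0, a=0.0, alpha=0.05)
        assert lo == pytest.approx(np.quantile(thetas, 0.025), abs=1e-12)
        assert hi == pytest.approx(np.quantile(thetas, 0.975), abs=1e-12)

    def test_matches_scipy_bca(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(size=40)
        lo, hi = bca_ci(x, np.mean, B=4000, rng=np.random.default_rng(3))
        res = sps.bootstrap((x,), np.mean, n_resamples=4000, method="BCa",
                            random_state=np.random.default_rng(3))
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.05)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.05)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bca_ci(np.array([1.0]), np.mean)


def test_truncate_p_floor_behaviour():
    assert truncate_p(1 / 32) == 0.0312
    assert truncate_p(0.00029) == 0.0002
    assert truncate_p(0.99999) == 0.9999
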
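import itertools

import numpy as np
import pytest
from scipy import stats as sps

from transchrom.stats import (
    bh_fdr,
    chi_square_2x2,
    ks_two_sample,
    rank_sum,
    signed_rank,
)

# ---------------------------------------------------------------------------
# independent oracles


def mc_rank_sum_p(x, y, direction, n_draws=20_000, seed=0):
    """Monte-Carlo permutation estimate of the rank-sum tail probability."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    idx = np.arange(len(pooled))
    ws = np.empty(n_draws)
    for i in range(n_draws):
        rng.shuffle(idx)
        ws[i] = ranks[idx[: len(x)]].sum()
    p_ge = np.mean(ws >= w_obs)
    p_le = np.mean(ws <= w_obs)
    if direction == "greater":
        return p_ge
    if direction == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


def mc_signed_rank_p(x, y, direction, n_draws=20_000, seed=0):
    rng = np.random.default_rng(seed)
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    signs = rng.random((n_draws, len(d))) < 0.5
    ws = (ranks * signs).sum(axis=1)
    p_ge = np.mean(ws >= w_obs)
    p_le = np.mean(ws <= w_obs)
    if direction == "greater":
        return p_ge
    if direction == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


def brute_force_ks_d(x, y):
    pooled = np.concatenate([x, y])
    return max(
        abs(np.mean(np.asarray(x) <= v) - np.mean(np.asarray(y) <= v)) for v in pooled
    )


# ---------------------------------------------------------------------------
# chi-square


class TestChiSquare2x2:
    def test_closed_form_hand_value(self):
        res = chi_square_2x2(10, 5, 20, 40)
        assert res.statistic == pytest.approx(5.5556, abs=1e-3)

    def test_agrees_with_scipy_without_correction(self):
        for table in [(10, 5, 20, 40), (3, 9, 12, 2), (40, 42, 38, 44)]:
            a, b, c, d = table
            res = chi_square_2x2(a, b, c, d)
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_identical_proportions_give_null(self):
        res = chi_square_2x2(10, 10, 20, 20)
        assert res.statistic == 0 and res.p_value == 1

    def test_zero_margin_gives_null(self):
        res = chi_square_2x2(0, 0, 5, 5)
        assert res.statistic == 0 and res.p_value == 1

    @pytest.mark.parametrize("table", [(10, 5, 20, 40), (1, 7, 3, 2)])
    def test_invariant_under_transposition_and_swaps(self, table):
        a, b, c, d = table
        base = chi_square_2x2(a, b, c, d).statistic
        assert chi_square_2x2(a, c, b, d).statistic == pytest.approx(base)  # transpose
        assert chi_square_2x2(c, d, a, b).statistic == pytest.approx(base)  # row swap
        assert chi_square_2x2(b, a, d, c).statistic == pytest.approx(base)  # column swap

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# rank-sum


class TestRankSum:
    def test_exact_two_sided_small_case(self):
        res = rank_sum([1, 2], [3, 4], "two_sided")
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "rank_sum_exact"

    def test_exact_one_sided_extreme_split(self):
        # testing whether y is greater, i.e. x is less
        res = rank_sum([1, 2, 3], [4, 5, 6], "less")
        assert res.p_value == pytest.approx(1 / 20)

    def test_identical_samples_give_p_one(self):
        assert rank_sum([5, 5, 5], [5, 5, 5]).p_value == 1

    def test_exact_matches_scipy_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(2, 6)))
            y = rng.normal(size=int(rng.integers(2, 6)))
            res = rank_sum(x, y, "two_sided")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_exact_with_ties_matches_permutation_null(self):
        # all-tied groups: only 1 of C(6,3)=20 splits is as extreme
        res = rank_sum([2, 2, 2], [0, 0, 0], "greater")
        assert res.p_value == pytest.approx(1 / 20)

    def test_approximation_close_to_exact_at_boundary(self, monkeypatch):
        """At n=m=6 without ties, the corrected normal approximation must
        stay within 0.01 of the exact p for every achievable outcome."""
        from transchrom import stats as tstats

        n = m = 6
        for x_ranks in itertools.combinations(range(1, n + m + 1), n):
            x = [float(r) for r in x_ranks]
            y = [float(r) for r in range(1, n + m + 1) if r not in x_ranks]
            for direction in ("two_sided", "greater", "less"):
                exact = rank_sum(x, y, direction)
                assert exact.method == "rank_sum_exact"
                monkeypatch.setattr(tstats, "EXACT_LIMIT", 0)
                approx = rank_sum(x, y, direction)
                monkeypatch.setattr(tstats, "EXACT_LIMIT", 12)
                assert approx.method == "rank_sum_normal"
                assert abs(approx.p_value - exact.p_value) <= 0.01


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


class TestKsTwoSample:
    def test_identical_samples_have_zero_distance(self):
        assert ks_two_sample([1, 2, 3], [1, 2, 3]).statistic == 0

    def test_disjoint_supports_have_distance_one(self):
        res = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert res.statistic == 1

    def test_offset_grids_quarter_distance(self):
        res = ks_two_sample([1, 2, 3, 4], [2, 3, 4, 5])
        assert res.statistic == pytest.approx(0.25)

    def test_distance_matches_brute_force_ecdf(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(3, 30)))
            y = rng.normal(0.5, 1.2, size=int(rng.integers(3, 30)))
            assert ks_two_sample(x, y).statistic == pytest.approx(brute_force_ks_d(x, y))

    def test_p_near_permutation_oracle_on_moderate_signal(self):
        """The asymptotic p must sit close to a Monte-Carlo permutation
        estimate of P(D >= D_obs) away from the deep tail."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = rng.normal(0.25, 1, size=35)
        res = ks_two_sample(x, y)
        assert res.statistic == pytest.approx(
            sps.ks_2samp(x, y).statistic
        )
        pooled = np.concatenate([x, y])
        hits = 0
        n_draws = 5000
        for _ in range(n_draws):
            rng.shuffle(pooled)
            if brute_force_ks_d(pooled[:40], pooled[40:]) >= res.statistic - 1e-12:
                hits += 1
        assert abs(res.p_value - hits / n_draws) <= 0.01
        # and the p-value is monotone decreasing in the distance
        shifted = ks_two_sample(x, y + 2.0)
        assert shifted.statistic > res.statistic
        assert shifted.p_value < res.p_value


# ---------------------------------------------------------------------------
# signed-rank


class TestSignedRank:
    def test_constant_shift_extreme_one_sided(self):
        x = np.arange(6, dtype=float)
        res = signed_rank(x + 3.0, x, "greater")
        assert res.p_value == pytest.approx(1 / 64)

    def test_identical_pairs_give_p_one(self):
        x = [1.0, 2.0, 3.0]
        assert signed_rank(x, x).p_value == 1

    def test_single_nonzero_pair_two_sided(self):
        assert signed_rank([5.0], [1.0], "two_sided").p_value == 1

    def test_exact_matches_scipy_exact(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            x = rng.normal(size=n)
            y = x + rng.normal(0.3, 1.0, size=n)
            res = signed_rank(x, y, "two_sided")
            ref = sps.wilcoxon(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            signed_rank([1, 2], [1])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


class TestBhFdr:
    def test_step_up_hand_case(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.2]) == [pytest.approx(0.2)]

    def test_all_ones_stay_one(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_empty_list(self):
        assert bh_fdr([]) == []

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        assert bh_fdr(p) == pytest.approx(multipletests(p, method="fdr_bh")[1])

    def test_order_invariance_and_smallest_p_dominance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=20)
        q = np.array(bh_fdr(p))
        perm = rng.permutation(20)
        q_perm = np.array(bh_fdr(p[perm]))
        assert q_perm == pytest.approx(q[perm])
        assert q[np.argmin(p)] >= p.min()
        assert np.all(q <= 1)


# ---------------------------------------------------------------------------
# exact modes vs Monte-Carlo permutation oracles


class TestExactModesAgainstMonteCarlo:
    """Exact enumeration must agree with a permutation simulation within
    Monte-Carlo error on random small samples."""

    @pytest.mark.parametrize("n,m", [(2, 3), (4, 4), (5, 6), (6, 6)])
    def test_rank_sum(self, n, m):
        rng = np.random.default_rng(100 + n * 10 + m)
        x = rng.normal(size=n)
        y = rng.normal(0.8, 1, size=m)
        for direction in ("two_sided", "greater", "less"):
            p = rank_sum(x, y, direction).p_value
            p_mc = mc_rank_sum_p(x, y, direction, seed=n * 100 + m)
            se = np.sqrt(max(p_mc * (1 - p_mc), 1e-4) / 20_000)
            assert abs(p - p_mc) <= 3 * se + 1e-9

    @pytest.mark.parametrize("n", [4, 6, 9])
    def test_signed_rank(self, n):
        rng = np.random.default_rng(200 + n)
        x = rng.normal(size=n)
        y = x + rng.normal(0.5, 1, size=n)
        for direction in ("two_sided", "greater"):
            p = signed_rank(x, y, direction).p_value
            p_mc = mc_signed_rank_p(x, y, direction, seed=300 + n)
            se = np.sqrt(max(p_mc * (1 - p_mc), 1e-4) / 20_000)
            assert abs(p - p_mc) <= 3 * se + 1e-9

    def test_chi_square_against_permutation(self):
        """Permuting the 75 items of the (10,5,20,40) table across groups:
        the closed-form statistic must equal an independent contingency
        computation on every permuted table, and the asymptotic p must sit
        near the conditional permutation estimate."""
        rng = np.random.default_rng(9)
        a, b, c, d = 10, 5, 20, 40
        outcome = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        group1 = a + b
        stat_obs = chi_square_2x2(a, b, c, d).statistic
        p_ref = chi_square_2x2(a, b, c, d).p_value
        n_draws = 20_000
        hits = 0
        for i in range(n_draws):
            rng.shuffle(outcome)
            aa = int(outcome[:group1].sum())
            bb = group1 - aa
            cc = int(outcome[group1:].sum())
            dd = len(outcome) - group1 - cc
            stat = chi_square_2x2(aa, bb, cc, dd).statistic
            if i < 100:  # closed form vs independent contingency computation
                ref = sps.chi2_contingency([[aa, bb], [cc, dd]], correction=False).statistic
                assert stat == pytest.approx(ref)
            if stat >= stat_obs - 1e-12:
                hits += 1
        p_mc = hits / n_draws
        # the 1-df asymptotic p and the margin-conditional permutation p
        # differ by the usual small-count discreteness, nothing more
        assert abs(p_ref - p_mc) <= 0.025
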
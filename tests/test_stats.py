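import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import exact_two_group_pvalues
from cordmorph.morphometry import label_levels
from cordmorph.stats import (atrophy_rate, bh_fdr, correlate_profiles,
                             gradient_correlation, mmt_percent,
                             permutation_map, proximal_distal_test,
                             spearman_rho, table1_summary)


class TestPermutationMap:
    def test_identical_groups_give_large_p(self):
        rng = np.random.default_rng(0)
        grp = rng.normal(10, 1, (5, 20))
        cmap = permutation_map(grp, grp.copy(), n_perm=1000, seed=1)
        assert (cmap.p_values >= 0.5).all()

    def test_matches_exact_enumeration_4v4(self):
        rng = np.random.default_rng(1)
        ctl = rng.normal(10.0, 1.0, (4, 12))
        pat = rng.normal(9.0, 1.0, (4, 12))
        exact = exact_two_group_pvalues(ctl, pat)
        n_perm = 10_000
        cmap = permutation_map(pat, ctl, n_perm=n_perm, seed=2)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert (np.abs(cmap.p_values - exact) <= 3 * se + 2.0 / n_perm).all()

    def test_min_attainable_p_is_one_over_nperm_plus_one(self):
        pat = np.zeros((6, 3))
        ctl = np.full((6, 3), 10.0)
        cmap = permutation_map(pat, ctl, n_perm=2000, seed=3)
        assert cmap.min_attainable_p == pytest.approx(1.0 / 2001)
        assert cmap.p_values.min() >= cmap.min_attainable_p
        assert (cmap.p_values > 0).all()

    def test_p_floor_at_one_hundred_thousand_permutations(self):
        # strong separation reaches the floor 1/(100000+1) < 1e-5
        rng = np.random.default_rng(4)
        ctl = rng.normal(80.0, 1.0, (18, 2))
        pat = rng.normal(60.0, 1.0, (18, 2))
        cmap = permutation_map(pat, ctl, n_perm=100_000, seed=5)
        assert cmap.p_values.min() == pytest.approx(1.0 / 100_001)
        assert cmap.p_values.min() < 1e-5

    def test_validity_under_null(self):
        # P(p <= alpha) <= alpha (+3 binomial SE) at several alphas
        rng = np.random.default_rng(6)
        n_rep, n_perm = 400, 500
        pvals = []
        for rep in range(n_rep):
            X = rng.normal(size=(12, 1))
            cmap = permutation_map(X[:6], X[6:], n_perm=n_perm,
                                   seed=int(rng.integers(2**31)))
            pvals.append(cmap.p_values[0])
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25):
            frac = (pvals <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / n_rep)
            assert frac <= alpha + 3 * se

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            permutation_map(np.zeros((3, 4)), np.zeros((3, 5)), n_perm=100)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            permutation_map(np.zeros((1, 4)), np.zeros((3, 4)), n_perm=100)

    def test_low_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_map(np.zeros((2, 2)), np.ones((2, 2)), n_perm=50, seed=0)

    def test_shared_and_independent_shuffles_agree_statistically(self):
        rng = np.random.default_rng(7)
        ctl = rng.normal(10, 1, (8, 3))
        pat = rng.normal(9.3, 1, (8, 3))
        a = permutation_map(pat, ctl, n_perm=4000, seed=8, shared_shuffles=True)
        b = permutation_map(pat, ctl, n_perm=4000, seed=9, shared_shuffles=False)
        assert np.abs(a.p_values - b.p_values).max() < 0.05


class TestAtrophyRate:
    def test_arithmetic(self):
        ctl = np.full((3, 5), 80.0)
        pat = np.full((4, 5), 64.0)
        rate = atrophy_rate(pat, ctl)
        assert np.allclose(rate.rate_pct, 20.0)

    def test_identical_groups_zero(self):
        grp = np.random.default_rng(0).uniform(60, 90, (5, 7))
        assert np.allclose(atrophy_rate(grp, grp).rate_pct, 0.0)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(60, 90, (5, 7))
        b = rng.uniform(60, 90, (6, 7))
        fwd = atrophy_rate(a, b).rate_pct   # controls = b
        rev = atrophy_rate(b, a).rate_pct   # controls = a
        # sign flips once renormalized to a common reference mean
        assert np.allclose(rev, -fwd * b.mean(0) / a.mean(0))
        assert np.all(np.sign(fwd) == -np.sign(rev))

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError, match="control"):
            atrophy_rate(np.ones((2, 3)), np.zeros((2, 3)))


class TestSpearman:
    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_rank_then_pearson_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 15))
        x = np.round(rng.normal(size=n), 1)  # induce ties
        Y = np.round(rng.normal(size=(n, 3)), 1)
        ours = spearman_rho(x, Y)
        for c in range(3):
            ref = sps.spearmanr(x, Y[:, c]).statistic
            if np.isnan(ref):
                assert np.isnan(ours[c])
            else:
                assert ours[c] == pytest.approx(ref, abs=1e-12)


class TestCorrelateProfiles:
    def test_monotone_score_gives_rho_one(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=(8, 4))
        scores = np.exp(prof[:, 2])  # monotone in site 2
        cmap = correlate_profiles(prof, scores)
        assert cmap.rho[2] == pytest.approx(1.0)

    def test_exact_p_matches_brute_force_at_n6(self):
        from itertools import permutations as perms

        rng = np.random.default_rng(1)
        prof = rng.normal(size=(6, 3))
        scores = rng.normal(size=6)
        cmap = correlate_profiles(prof, scores, exact_max_n=10)
        # independent brute-force oracle
        for site in range(3):
            obs = sps.spearmanr(scores, prof[:, site]).statistic
            null = [sps.spearmanr(p, prof[:, site]).statistic
                    for p in perms(scores)]
            p_exact = np.mean(np.abs(null) >= abs(obs) - 1e-12)
            assert cmap.p_values[site] == pytest.approx(p_exact, abs=1e-12)

    def test_constant_score_flagged(self):
        prof = np.random.default_rng(2).normal(size=(6, 3))
        cmap = correlate_profiles(prof, np.full(6, 5.0))
        assert cmap.flagged_sites.all()
        assert np.isnan(cmap.rho).all()
        assert not cmap.significant.any()

    def test_nan_scores_dropped(self):
        rng = np.random.default_rng(3)
        prof = rng.normal(size=(8, 2))
        scores = rng.normal(size=8)
        scores[0] = np.nan
        cmap = correlate_profiles(prof, scores)
        ref = correlate_profiles(prof[1:], scores[1:])
        assert cmap.n == 7
        assert np.allclose(cmap.rho, ref.rho, equal_nan=True)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="4 subjects"):
            correlate_profiles(np.zeros((3, 2)), np.arange(3.0))


class TestGradientCorrelation:
    def test_coupled_slopes_give_rho_one(self):
        rng = np.random.default_rng(0)
        L = 120
        levels = label_levels(L)
        n = 10
        sl = levels.span_slices("C4", "C7")
        steep = np.linspace(0.1, 1.0, n)
        profiles = np.empty((n, L))
        mmt = np.empty((n, 4))
        for i in range(n):
            profiles[i] = 80.0 - steep[i] * np.arange(L) * 0.05
            mmt[i] = 90.0 - steep[i] * 10.0 * np.arange(4)
        rho, p = gradient_correlation(profiles, levels, mmt)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_identical_subjects_undefined(self):
        L = 60
        levels = label_levels(L)
        profiles = np.tile(np.linspace(80, 70, L), (5, 1))
        mmt = np.tile([90.0, 85.0, 80.0, 75.0], (5, 1))
        rho, p = gradient_correlation(profiles, levels, mmt)
        assert np.isnan(rho) and np.isnan(p)

    def test_linear_ramp_slope_is_analytic(self):
        # slope extraction check: CSA = 100 - 2 * x_mm over C4-C7
        L = 100
        levels = label_levels(L)
        x = np.arange(L) * 0.3
        prof = 100.0 - 2.0 * x
        slopes = np.polyfit(levels.span_slices("C4", "C7") * 0.3,
                            prof[levels.span_slices("C4", "C7")], 1)[0]
        assert slopes == pytest.approx(-2.0)


class TestProximalDistalTest:
    def test_all_tied_returns_p_one(self):
        c5 = np.array([70.0, 80.0, 90.0])
        stat, p = proximal_distal_test(c5, c5.copy())
        assert p == 1.0

    def test_matches_sign_flip_oracle_at_n8(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.5, 1.0, 8)
        d = np.where(d == 0, 0.1, d)
        # ensure unique magnitudes for the exact path
        d += np.arange(8) * 1e-6
        c8 = rng.uniform(50, 90, 8)
        c5 = c8 + d
        stat, p = proximal_distal_test(c5, c8)

        # oracle: enumerate all 2^8 sign assignments of |d|
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        n = len(d)
        ws = []
        for signs in range(2**n):
            bits = np.array([(signs >> i) & 1 for i in range(n)], dtype=bool)
            ws.append(ranks[bits].sum())
        ws = np.array(ws)
        total = ranks.sum()
        p_exact = np.mean(np.minimum(
            np.minimum((ws <= w_obs).mean(), (ws >= w_obs).mean()) * 2, 1.0))
        # two-sided exact p via the symmetric distribution
        lo = min(w_obs, total - w_obs)
        p_oracle = min(1.0, ((ws <= lo).sum() + (ws >= total - lo).sum()) / 2**n)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_antisymmetric_pairs_statistic_at_center(self):
        c8 = np.full(8, 70.0)
        d = np.array([1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
        stat, p = proximal_distal_test(c8 + d, c8)
        assert stat == pytest.approx(8 * 9 / 4)  # n(n+1)/4
        assert p > 0.9

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValueError):
            proximal_distal_test(np.zeros(4), np.zeros(5))


class TestTable1Summary:
    def test_percent_arithmetic(self):
        assert mmt_percent(7, "c5") == pytest.approx(70.0)
        assert mmt_percent(15, "c7") == pytest.approx(50.0)

    def test_summary_means_and_missing(self):
        records = [
            {"group": "patient", "mmt_c5": 7, "age": 30},
            {"group": "patient", "mmt_c5": 9, "age": 40},
            {"group": "control", "age": 35},
        ]
        df = table1_summary(records)
        pat_c5 = df[(df.group == "patient") & (df.field == "mmt_pct_c5")]
        assert pat_c5["mean"].iloc[0] == pytest.approx(80.0)
        ctl_c5 = df[(df.group == "control") & (df.field == "mmt_c5")]
        assert ctl_c5["n_missing"].iloc[0] == 1

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            table1_summary([{"age": 30}])


class TestBhFdr:
    def test_rejects_smallest_p_only(self):
        p = np.array([0.001, 0.2, 0.4, 0.9])
        rej = bh_fdr(p, q=0.05)
        assert rej.tolist() == [True, False, False, False]
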
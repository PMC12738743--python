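import itertools

import numpy as np
import pytest
from scipy import stats as spstats

from nfmotion import stats as _st
from nfmotion import synth


def paired_from_negative_ranks(n, neg_ranks):
    """Pairs with tie-free |differences| of ranks 1..n where the listed
    ranks carry negative differences."""
    pre = np.zeros(n)
    post = np.arange(1, n + 1, dtype=float)
    for r in neg_ranks:
        post[r - 1] = -r
    return pre, post


def wilcoxon_enumeration_oracle(d):
    """Exact two-sided p by brute force over all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = spstats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    lo = 0
    hi = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        lo += wp <= min(w_plus, w_minus) + 1e-9
        hi += wp <= min(w_plus, w_minus) + 1e-9  # symmetric distribution
    return min(1.0, 2.0 * lo / total)


PRINTED_PAIRS = [
    (10, [], 0.0, 0.002),
    (10, [3], 3.0, 0.010),
    (10, [5], 5.0, 0.020),
    (10, [7], 7.0, 0.037),
    (8, [], 0.0, 0.008),
    (8, [1], 1.0, 0.016),
    (8, [3], 3.0, 0.039),
    (8, [5], 5.0, 0.078),
]


class TestWilcoxonExact:
    @pytest.mark.parametrize("n, neg, w_expect, p_expect", PRINTED_PAIRS)
    def test_reproduces_printed_pairs(self, n, neg, w_expect, p_expect):
        pre, post = paired_from_negative_ranks(n, neg)
        res = _st.wilcoxon_exact(pre, post)
        assert res.w == w_expect
        assert round(res.p, 3) == p_expect

    def test_matches_enumeration_oracle_tiefree(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 11))
            d = rng.normal(size=n)
            while len(np.unique(np.abs(d))) < n or np.any(d == 0):
                d = rng.normal(size=n)
            res = _st.wilcoxon_exact(np.zeros(n), d)
            assert res.p == pytest.approx(wilcoxon_enumeration_oracle(d))

    def test_matches_scipy_exact(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 13))
            d = rng.normal(size=n)
            res = _st.wilcoxon_exact(np.zeros(n), d)
            ref = spstats.wilcoxon(d, method="exact")
            assert res.p == pytest.approx(ref.pvalue)
            assert res.w == pytest.approx(ref.statistic)

    def test_ties_match_enumeration(self):
        """Mid-ranked ties: the DP equals brute-force enumeration over the
        observed tied rank pattern."""
        d = np.array([1.0, -1.0, 2.0, 3.0, 3.0, -4.0, 5.0])
        res = _st.wilcoxon_exact(np.zeros(len(d)), d)
        ranks = spstats.rankdata(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([1, -1], repeat=len(d)):
            wp = sum(r for r, s in zip(ranks, signs) if s > 0)
            count += wp <= w_obs + 1e-9
        assert res.p == pytest.approx(min(1.0, 2 * count / 2 ** len(d)))

    def test_zeros_dropped(self):
        pre = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        post = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = _st.wilcoxon_exact(pre, post)
        assert res.n == 4
        assert res.w == 0.0

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            _st.wilcoxon_exact(np.ones(5), np.ones(5))

    def test_type_one_error_controlled(self):
        """Exact test is conservative at n=10 under the null."""
        rng = np.random.default_rng(0)
        rejections = 0
        trials = 500
        for _ in range(trials):
            d = rng.normal(size=10)
            if _st.wilcoxon_exact(np.zeros(10), d).p < 0.05:
                rejections += 1
        assert rejections / trials <= 0.05 + 0.02


class TestSmdBootstrap:
    def test_zero_variance_error(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="variance"):
            _st.smd_bootstrap(x, x + 1.0)

    def test_saturated_effect(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(size=8)
        post = pre + 1.0 + rng.normal(0, 1e-3, 8)
        smd, ci = _st.smd_bootstrap(pre, post, seed=0)
        assert smd > 100
        assert ci[0] > 0

    def test_point_estimate_is_dz(self, rng):
        pre = rng.normal(size=10)
        post = rng.normal(size=10)
        smd, ci = _st.smd_bootstrap(pre, post, seed=0)
        d = post - pre
        assert smd == pytest.approx(d.mean() / d.std(ddof=1))
        assert ci[0] <= smd <= ci[1]

    def test_recovery_near_published_effect(self):
        """Cohorts generated at the published steps-per-second effect size
        (0.94) recover it on average."""
        ests = []
        for s in range(300):
            pre, post = synth.gen_paired_cohort(10, true_smd=0.94, seed=s)
            smd, _ = _st.smd_bootstrap(pre, post, B=200, seed=s)
            ests.append(smd)
        assert np.mean(ests) == pytest.approx(0.94, abs=0.15)

    def test_seeded_reproducibility(self, rng):
        pre = rng.normal(size=10)
        post = pre + rng.normal(0.5, 1, 10)
        a = _st.smd_bootstrap(pre, post, seed=7)
        b = _st.smd_bootstrap(pre, post, seed=7)
        assert a == b


class TestTost:
    def test_exact_null_equivalent(self):
        pre = np.arange(10, dtype=float)
        post = pre.copy()
        res = _st.tost_equivalence(pre, post)
        assert res.p_max < 0.05
        assert res.equivalent

    def test_boundary_p_half(self):
        """Mean difference exactly on the bound: the corresponding
        one-sided t-statistic is 0, so p = 0.5 (t-distribution oracle)."""
        rng = np.random.default_rng(2)
        pre = rng.normal(size=10)
        bound = 0.3 * pre.std(ddof=1)
        noise = rng.normal(0, 0.1, 10)
        noise -= noise.mean()
        post = pre + bound + noise
        res = _st.tost_equivalence(pre, post)
        assert res.p_upper == pytest.approx(0.5, abs=1e-9)

    def test_large_shift_not_equivalent(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(size=10)
        post = pre + pre.std(ddof=1)
        res = _st.tost_equivalence(pre, post)
        assert res.p_max > 0.5
        assert not res.equivalent

    def test_monotone_in_mean_difference(self):
        rng = np.random.default_rng(4)
        pre = rng.normal(size=12)
        noise = rng.normal(0, 0.2, 12)
        noise -= noise.mean()
        p_values = []
        for shift in (0.0, 0.2, 0.5, 1.0):
            res = _st.tost_equivalence(pre, pre + shift + noise)
            p_values.append(res.p_max)
        assert p_values == sorted(p_values)

    def test_zero_pre_variance_error(self):
        with pytest.raises(ValueError):
            _st.tost_equivalence(np.ones(5), np.arange(5.0))


class TestZscoreAndCorrelate:
    def test_antimonotone_spearman(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([10.0, 8.0, 5.0, 4.0, 1.0])
        res = _st.zscore_and_correlate(x, y, method="spearman", B=200, seed=0)
        assert res.rho == pytest.approx(-1.0)

    def test_pearson_slope_recovery(self):
        """y = -0.373 x + noise at n=40: slope recovered on average
        (mirrors the published regression coefficient)."""
        slopes = []
        for s in range(100):
            rng = np.random.default_rng(s)
            x = rng.normal(size=40)
            y = -0.373 * x + rng.normal(0, 0.93, 40)
            summary = _st.regression_with_task(x, y, ["fs"] * 40)
            slopes.append(summary.slope)
        assert np.mean(slopes) == pytest.approx(-0.373, abs=0.05)

    def test_bootstrap_ci_coverage(self):
        """CI covers the true correlation ~95% of the time (Monte-Carlo,
        loose bounds for 150 replicates)."""
        true_rho = 0.6
        cov = np.array([[1.0, true_rho], [true_rho, 1.0]])
        hits = 0
        trials = 150
        for s in range(trials):
            rng = np.random.default_rng(s)
            xy = rng.multivariate_normal([0, 0], cov, size=30)
            res = _st.zscore_and_correlate(xy[:, 0], xy[:, 1],
                                           method="pearson", B=500, seed=s)
            hits += res.ci[0] <= true_rho <= res.ci[1]
        assert 0.85 <= hits / trials <= 1.0

    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            _st.zscore_and_correlate(np.ones(5), np.arange(5.0))


class TestRegressionWithTask:
    def test_single_task_reduces_to_simple(self, rng):
        x = rng.normal(size=30)
        y = 2.0 * x + rng.normal(0, 0.5, 30)
        res = _st.regression_with_task(x, y, ["baseline"] * 30)
        assert res.task_p is None and res.interaction_p is None
        assert res.slope == pytest.approx(2.0, abs=0.2)

    def test_interaction_detected_when_present(self):
        rng = np.random.default_rng(10)
        n = 60
        x = rng.normal(size=n)
        task = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        slopes = np.where(task == "a", 1.0, -1.0)
        y = slopes * x + rng.normal(0, 0.3, n)
        res = _st.regression_with_task(x, y, task)
        assert res.interaction_p < 0.001

    def test_interaction_null_uniformish(self):
        """Type-I rate of the interaction test near nominal 5%."""
        rng = np.random.default_rng(11)
        rejections = 0
        trials = 200
        for _ in range(trials):
            x = rng.normal(size=40)
            task = np.array(["a", "b"] * 20)
            y = 0.5 * x + rng.normal(0, 1, 40)
            res = _st.regression_with_task(x, y, task)
            rejections += res.interaction_p < 0.05
        assert 0.01 <= rejections / trials <= 0.11

    def test_constant_beta_rejected(self):
        with pytest.raises(ValueError):
            _st.regression_with_task(np.ones(10), np.arange(10.0), ["a"] * 10)


class TestChangeScores:
    def test_perfect_monotone_coupling(self):
        beta_pre = np.array([1.0, 1.1, 1.2, 0.9, 1.05])
        beta_post = beta_pre - np.array([0.1, 0.3, 0.5, 0.2, 0.4])
        speed_pre = np.full(5, 2.0)
        speed_post = speed_pre + np.array([0.1, 0.3, 0.5, 0.2, 0.4])
        res = _st.change_score_analysis(beta_pre, beta_post,
                                        speed_pre, speed_post, B=200, seed=0)
        assert res.rho == pytest.approx(1.0)

    def test_sign_conventions(self):
        """Beta reduction gives positive delta-beta; speed gain positive
        delta-speed."""
        res = _st.change_score_analysis(
            [1.0, 1.0, 1.0], [0.8, 0.7, 0.9],
            [2.0, 2.0, 2.0], [2.5, 2.6, 2.4], B=100, seed=0,
        )
        assert res.n == 3

    def test_noisy_participant_weakens_rho(self):
        rng = np.random.default_rng(5)
        n = 8
        dbeta = np.linspace(0.05, 0.4, n)
        dspeed = dbeta.copy()
        dspeed[3] = -0.2  # one discordant participant
        res = _st.change_score_analysis(
            np.ones(n), np.ones(n) - dbeta,
            np.ones(n), np.ones(n) + dspeed, B=200, seed=0,
        )
        assert 0.5 < res.rho < 1.0

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            _st.change_score_analysis([1, 2], [1, 2], [1, 2], [1, 2])


class TestAnalysisSets:
    def _cohort(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        pids = [f"P{i:02d}" for i in range(1, n + 1)]
        pre = {p: float(rng.normal()) for p in pids}
        post = {p: pre[p] + float(rng.normal(0.8, 1.0)) for p in pids}
        return pre, post

    def test_set_sizes(self):
        pre, post = self._cohort()
        res = _st.analysis_sets(pre, post, ["P01", "P09"], B=200, seed=0)
        assert {k: v.n for k, v in res.items()} == {
            "all": 10, "responders": 8, "excl_P01": 9, "excl_P09": 9,
        }

    def test_empty_non_responders_all_identical(self):
        pre, post = self._cohort()
        res = _st.analysis_sets(pre, post, [], B=200, seed=0)
        assert set(res) == {"all", "responders"}
        assert res["all"].w == res["responders"].w
        assert res["all"].p == res["responders"].p

    def test_leave_one_out_flags_driver(self):
        """A single subject driving the effect flips significance when
        excluded."""
        pids = [f"P{i:02d}" for i in range(1, 9)]
        pre = {p: 0.0 for p in pids}
        rng = np.random.default_rng(3)
        post = {p: float(rng.normal(0, 0.05)) for p in pids}
        post["P01"] = 5.0  # the driver
        res = _st.analysis_sets(pre, post, ["P01"], B=200, seed=0)
        assert res["all"].smd > res["excl_P01"].smd

    def test_small_set_skipped_with_warning(self):
        pre, post = self._cohort(n=3)
        with pytest.warns(UserWarning, match="fewer than 3"):
            res = _st.analysis_sets(pre, post, ["P01"], B=200, seed=0)
        assert "responders" not in res
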
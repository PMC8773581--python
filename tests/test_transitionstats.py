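"""Paired-statistics tests: exact Wilcoxon, Hedges' g, AUC, bootstrap CIs."""

import numpy as np
import pytest
from scipy import stats

from emergeeg.spectral import ParamTrend
from emergeeg.transitionstats import (
    EXACT_WILCOXON_MAX_N,
    PairedTransitionSet,
    _wilcoxon_approx,
    _wilcoxon_exact,
    auc_two_sample,
    bootstrap_ci,
    build_paired_set,
    hedges_correction,
    hedges_g_dependent,
    paired_test,
    significant_by_ci,
    wilcoxon_signed_rank,
)


def brute_force_auc(x, y):
    """Oracle: explicit pair counting with half-credit ties."""
    wins = ties = 0
    for xi in x:
        for yi in y:
            wins += yi > xi
            ties += yi == xi
    return (wins + 0.5 * ties) / (len(x) * len(y))


def wilcoxon_exact_dp(d):
    """Oracle: exact two-sided p via the rank-sum generating polynomial."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks2 = np.round(2 * stats.rankdata(np.abs(d))).astype(int)  # integers
    w_obs2 = ranks2[d > 0].sum()
    poly = np.array([1.0])
    for r in ranks2:
        new = np.zeros(len(poly) + r)
        new[: len(poly)] += poly
        new[r:] += poly
        poly = new
    poly /= poly.sum()
    p_le = poly[: w_obs2 + 1].sum()
    p_ge = poly[w_obs2:].sum()
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestBuildPairedSet:
    def _trend(self, length=120, value=1.0):
        t = np.arange(float(length))
        return ParamTrend(t, value * (t + 1.0))

    def test_full_coverage_retains_all_subjects(self):
        trends = {f"s{i}": self._trend() for i in range(6)}
        events = {f"s{i}": 60.0 for i in range(6)}
        ps = build_paired_set(trends, events, "LOR", "x")
        assert ps.n == 6 and not ps.dropped

    def test_missing_post_window_drops_subject_with_reason(self):
        trends = {"ok": self._trend(120), "short": self._trend(70)}
        events = {"ok": 60.0, "short": 60.0}
        ps = build_paired_set(trends, events, "LOR", "x")
        assert ps.n == 1
        assert "short" in ps.dropped

    def test_zero_offsets_give_identical_pre_post(self):
        trends = {"a": self._trend()}
        ps = build_paired_set(trends, {"a": 50.0}, "LOR", "x",
                              pre_offset_s=0.0, post_offset_s=0.0)
        assert ps.pre_values[0] == ps.post_values[0]

    def test_no_retained_subjects_raises(self):
        with pytest.raises(ValueError):
            build_paired_set({"a": self._trend(30)}, {"a": 60.0}, "LOR", "x")


class TestWilcoxon:
    def test_five_positive_differences(self):
        assert wilcoxon_signed_rank(np.ones(5) * 2, np.ones(5)) == pytest.approx(
            0.0625
        )  # 2 / 2^5 by enumeration

    def test_antisymmetric_differences_are_null_central(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        assert wilcoxon_signed_rank(d) == pytest.approx(1.0)

    def test_all_zero_differences_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank(np.zeros(8)) == 1.0

    def test_matches_scipy_exact_on_untied_data(self, rng):
        for _ in range(50):
            n = rng.integers(6, EXACT_WILCOXON_MAX_N + 1)
            d = rng.normal(0.3, 1.0, n)
            got = wilcoxon_signed_rank(d)
            want = stats.wilcoxon(d, method="exact").pvalue
            assert got == pytest.approx(want, abs=1e-10)

    def test_exact_path_equals_generating_function_oracle_with_ties(self, rng):
        for _ in range(100):
            n = rng.integers(5, 13)
            d = np.round(rng.normal(0.5, 1.0, n), 1)  # ties and zeros likely
            if np.all(d == 0):
                continue
            assert wilcoxon_signed_rank(d) == pytest.approx(
                wilcoxon_exact_dp(d), abs=1e-10
            )

    def test_exact_and_approx_paths_agree(self, rng):
        """At n=20 the normal approximation tracks full enumeration within 0.02."""
        for _ in range(20):
            d = rng.normal(0.25, 1.0, 20)
            ranks = stats.rankdata(np.abs(d))
            w_plus = ranks[d > 0].sum()
            assert _wilcoxon_approx(ranks, w_plus) == pytest.approx(
                wilcoxon_exact_dp(d), abs=0.02
            )
        # and the public API switches paths at the documented size
        d_small = rng.normal(0.5, 1.0, EXACT_WILCOXON_MAX_N)
        assert wilcoxon_signed_rank(d_small) == pytest.approx(
            wilcoxon_exact_dp(d_small), abs=1e-10
        )


class TestHedgesG:
    def test_hand_calculation(self):
        # differences (1,2,3): mean 2, sd 1, J = 1 - 3/7 -> g = 8/7
        g, _ = hedges_g_dependent(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]),
                                  n_boot=200, seed=0)
        assert g == pytest.approx((1 - 3 / 7) * 2.0, abs=1e-12)
        assert hedges_correction(3) == pytest.approx(1 - 3 / 7)

    def test_zero_mean_differences_give_zero_effect(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        post = np.array([2.0, 1.0, 4.0, 3.0])
        g, _ = hedges_g_dependent(pre, post, n_boot=200, seed=0)
        assert g == 0.0

    def test_sign_flip_negates_g_and_mirrors_ci(self):
        rng = np.random.default_rng(4)
        pre = rng.normal(1.0, 1.0, 12)
        post = rng.normal(0.0, 1.0, 12)
        g1, ci1 = hedges_g_dependent(pre, post, n_boot=4000, seed=11)
        g2, ci2 = hedges_g_dependent(post, pre, n_boot=4000, seed=11)
        assert g2 == pytest.approx(-g1, abs=1e-12)
        assert ci2[0] == pytest.approx(-ci1[1], abs=0.05)
        assert ci2[1] == pytest.approx(-ci1[0], abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            hedges_g_dependent(np.array([2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0]))


class TestAUC:
    def test_identity_and_separation(self):
        x = np.array([1.0, 2.0, 3.0])
        assert auc_two_sample(x, x) == 0.5
        assert auc_two_sample(x, x + 10) == 1.0
        assert auc_two_sample(x + 10, x) == 0.0

    def test_tied_example(self):
        assert auc_two_sample([1, 2, 3], [2, 3, 4]) == pytest.approx(7 / 9)

    def test_rank_formula_equals_pair_counting(self, rng):
        """1,000 random small samples, exact equality including ties."""
        for _ in range(1000):
            nx, ny = rng.integers(1, 9, size=2)
            x = rng.integers(0, 6, nx).astype(float)
            y = rng.integers(0, 6, ny).astype(float)
            assert auc_two_sample(x, y) == pytest.approx(
                brute_force_auc(x, y), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 25)
        want = roc_auc_score([0] * 30 + [1] * 25, np.concatenate([x, y]))
        assert auc_two_sample(x, y) == pytest.approx(want, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            auc_two_sample([], [1.0])


class TestBootstrapCI:
    def test_constant_data_collapses_with_warning(self):
        with pytest.warns(UserWarning):
            lo, hi = bootstrap_ci(np.mean, np.ones(10), n_boot=100, seed=0)
        assert lo == hi == 1.0

    def test_same_seed_reproduces_ci(self, rng):
        data = rng.normal(size=20)
        ci1 = bootstrap_ci(np.mean, data, n_boot=500, seed=9)
        ci2 = bootstrap_ci(np.mean, data, n_boot=500, seed=9)
        assert ci1 == ci2

    def test_ci_contains_point_estimate(self, rng):
        """The percentile CI contains the point estimate in >= 99% of datasets."""
        hits = 0
        n_sets = 150
        for _ in range(n_sets):
            data = rng.normal(size=12)
            lo, hi = bootstrap_ci(np.mean, data, n_boot=400, seed=rng.integers(2**31))
            hits += lo <= data.mean() <= hi
        assert hits >= 0.99 * n_sets

    def test_two_sample_resampling_unit(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(1, 1, 15)
        lo, hi = bootstrap_ci(
            lambda x, y: auc_two_sample(x, y), (a, b), n_boot=800, seed=3
        )
        assert 0.0 <= lo <= hi <= 1.0

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, np.ones(2), n_boot=10, seed=0)


class TestSignificance:
    def test_interval_above_half_is_significant(self):
        assert significant_by_ci((0.63, 0.84))

    def test_interval_containing_half_is_not(self):
        assert not significant_by_ci((0.28, 0.74))

    def test_touching_endpoint_counts_as_containing(self):
        assert not significant_by_ci((0.5, 0.7))
        assert not significant_by_ci((0.3, 0.5))

    def test_null_firing_rate_is_nominal(self, rng):
        """Under exchangeable groups the CI-excludes-0.5 rule fires at ~5%."""
        from emergeeg.groupcompare import auc_grid_bootstrap

        n_reps, fired = 800, 0
        for rep in range(n_reps):
            a = rng.normal(size=(15, 1))
            b = rng.normal(size=(15, 1))
            _, lo, hi = auc_grid_bootstrap(a, b, n_boot=400, seed=rep)
            fired += significant_by_ci((lo[0], hi[0]))
        assert 0.03 <= fired / n_reps <= 0.07


class TestPairedTest:
    def test_lor_decrease_yields_positive_g_and_auc_above_half(self, rng):
        pre = rng.normal(2.4, 0.1, 15)
        post = pre - rng.uniform(0.05, 0.25, 15)
        pairs = PairedTransitionSet(
            [f"s{i}" for i in range(15)], pre, post, "peen", "LOR"
        )
        res = paired_test(pairs, n_boot=2000, seed=0)
        assert res.hedges_g > 0
        assert res.auc > 0.5  # oriented as P(responsive > unresponsive)
        assert res.p_value < 0.05

    def test_ror_increase_yields_negative_g_and_auc_above_half(self, rng):
        pre = rng.normal(2.2, 0.1, 15)
        post = pre + rng.uniform(0.05, 0.25, 15)
        pairs = PairedTransitionSet(
            [f"s{i}" for i in range(15)], pre, post, "peen", "ROR"
        )
        res = paired_test(pairs, n_boot=2000, seed=0)
        assert res.hedges_g < 0
        assert res.auc > 0.5

    def test_nan_pairs_rejected_at_construction(self):
        with pytest.raises(ValueError):
            PairedTransitionSet(["a"], np.array([np.nan]), np.array([1.0]), "x", "LOR")
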
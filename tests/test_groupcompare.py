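"""Group-comparison tests: AUC grids, cluster rules, durations, exact tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emergeeg.groupcompare import (
    DurationRecord,
    align_to_event,
    auc_map,
    duration_above,
    freeman_halton,
    kruskal_dunn,
    psd_compare,
    table_distribution,
)
from emergeeg.spectral import ParamTrend, Spectrogram


def _spec(times, freqs, power):
    return Spectrogram(times, freqs, power, window_s=10.0, hop_s=1.0)


def _aligned_group(rng, n=8, n_t=30, n_f=12, shift=0.0, band=None):
    times = np.arange(-float(n_t) - 9.0, -9.0)
    freqs = np.linspace(6.0, 28.0, n_f)
    specs = []
    for _ in range(n):
        power = np.exp(rng.normal(0, 0.4, (n_t, n_f)))
        if shift:
            sel = slice(None) if band is None else band
            power[:, sel] *= np.exp(shift)
        specs.append(_spec(times, freqs, power))
    return specs


class TestPsdCompare:
    def test_identical_groups_give_exact_half_and_nothing_retained(self, rng):
        vals = np.exp(rng.normal(0, 0.3, (15, 20)))
        res = psd_compare(np.linspace(6, 30, 20), vals, vals, n_boot=200, seed=0)
        assert np.all(res.auc == 0.5)
        assert not res.sig.any() and not res.retained.any()

    def test_isolated_significant_bin_is_not_retained(self, rng):
        freqs = np.linspace(6, 30, 25)
        a = np.exp(rng.normal(0, 0.2, (15, 25)))
        b = np.exp(rng.normal(0, 0.2, (15, 25)))
        b[:, 10] *= 30.0  # one overwhelming isolated bin
        res = psd_compare(freqs, a, b, n_boot=400, seed=1)
        assert res.sig[10]
        if res.sig.sum() == 1:  # truly isolated
            assert not res.retained.any()
        assert not res.retained[10] or res.sig[9] or res.sig[11]

    def test_band_wide_alpha_shift_is_detected(self, rng):
        """A >=1 sd shift over 8-12 Hz at n=15/group retains most of the band."""
        freqs = np.arange(6.0, 30.5, 0.5)
        band = (freqs >= 8) & (freqs <= 12)
        sd_log = 0.4
        a = np.exp(rng.normal(0, sd_log, (15, len(freqs))))
        b = np.exp(rng.normal(0, sd_log, (15, len(freqs))))
        b[:, band] *= np.exp(1.5 * sd_log)  # 1.5 sd effect
        res = psd_compare(freqs, a, b, n_boot=500, seed=2)
        assert res.retained[band].mean() >= 0.5

    def test_mismatched_grids_rejected(self, rng):
        with pytest.raises(ValueError):
            psd_compare(np.arange(5.0), rng.normal(size=(5, 4)),
                        rng.normal(size=(5, 4)))


class TestAucMap:
    def test_identity_comparison_is_exactly_half_everywhere(self, rng):
        specs = _aligned_group(rng, n=6)
        m = auc_map(specs, specs, n_boot=100, seed=0, cluster_min=4)
        assert np.all(m.auc == 0.5)
        assert not m.sig_mask.any() and not m.cluster_mask.any()

    def test_label_swap_antisymmetry(self, rng):
        a = _aligned_group(rng, n=6)
        b = _aligned_group(rng, n=6, shift=0.3)
        m_ab = auc_map(a, b, n_boot=50, seed=0)
        m_ba = auc_map(b, a, n_boot=50, seed=0)
        assert np.allclose(m_ab.auc, 1.0 - m_ba.auc)

    def test_injected_effect_forms_cluster_and_mask_nesting(self, rng):
        a = _aligned_group(rng, n=12)
        b = _aligned_group(rng, n=12, shift=1.5, band=slice(6, 12))
        m = auc_map(a, b, n_boot=300, seed=3, cluster_min=10)
        assert m.cluster_mask.any()
        assert not np.any(m.cluster_mask & ~m.sig_mask)  # nesting invariant
        # the cluster sits in the shifted frequency columns
        _, cols = np.where(m.cluster_mask)
        assert np.isin(cols, np.arange(6, 12)).mean() > 0.8

    def test_misaligned_grids_rejected(self, rng):
        a = _aligned_group(rng, n=4)
        b = _aligned_group(rng, n=4)
        b[0] = _spec(b[0].times + 1.0, b[0].freqs, b[0].power)
        with pytest.raises(ValueError):
            auc_map(a, b, n_boot=10, seed=0)


class TestAlignToEvent:
    def _spec60(self):
        times = np.arange(0.0, 651.0)
        freqs = np.linspace(6, 30, 10)
        power = np.tile(times[:, None], (1, 10)) + 1.0
        return _spec(times, freqs, power)

    def test_span_600_gives_591_rows(self):
        aligned = align_to_event(self._spec60(), 600.0, span_s=600.0)
        assert len(aligned.times) == 591
        assert aligned.times[0] == -600.0 and aligned.times[-1] == -10.0
        # rows re-timestamped, data preserved
        assert np.array_equal(aligned.power[0], self._spec60().power[0])

    def test_event_too_close_to_record_end_is_fine_but_start_matters(self):
        with pytest.raises(ValueError):
            align_to_event(self._spec60(), 300.0, span_s=600.0)

    def test_realigning_an_aligned_grid_at_zero_is_identity(self):
        aligned = align_to_event(self._spec60(), 600.0, span_s=600.0)
        again = align_to_event(aligned, 0.0, span_s=600.0)
        assert np.array_equal(again.times, aligned.times)
        assert np.array_equal(again.power, aligned.power)


class TestDurationAbove:
    def _trend(self, values, hop=1.0):
        v = np.asarray(values, float)
        return ParamTrend(np.arange(len(v)) * hop, v, window_s=10.0, hop_s=hop)

    def test_saturated_trend_gives_full_span(self):
        trend = self._trend(np.full(601, 90.0))
        d = duration_above(trend, 600.0)
        assert d.duration_s == 600.0 and not d.at_ror_below

    def test_below_threshold_at_ror_gives_zero(self):
        v = np.full(601, 90.0)
        v[580:] = 70.0  # last pre-ROR window below
        d = duration_above(self._trend(v), 600.0)
        assert d.duration_s == 0.0 and d.at_ror_below

    def test_run_not_touching_ror_gives_zero_in_contiguous_mode(self):
        v = np.full(601, 70.0)
        v[480:540] = 90.0  # an earlier excursion only
        d = duration_above(self._trend(v), 600.0)
        assert d.duration_s == 0.0 and d.at_ror_below
        total = duration_above(self._trend(v), 600.0, mode="total")
        assert total.duration_s == 60.0

    def test_interrupted_run_counts_only_the_final_stretch(self):
        v = np.full(601, 90.0)
        v[400] = 70.0  # one dip breaks contiguity
        d = duration_above(self._trend(v), 600.0)
        assert d.duration_s == 600.0 - 401.0

    def test_monotone_in_threshold(self, rng):
        for _ in range(30):
            v = rng.uniform(60, 100, 301)
            trend = self._trend(v)
            durs = [duration_above(trend, 300.0, threshold=t).duration_s
                    for t in (70.0, 80.0, 90.0)]
            assert durs[0] >= durs[1] >= durs[2]

    def test_trend_not_reaching_ror_rejected(self):
        with pytest.raises(ValueError):
            duration_above(self._trend(np.full(50, 90.0)), 600.0)

    def test_duration_record_invariants(self):
        with pytest.raises(ValueError):
            DurationRecord("s", None, -1.0, False)
        with pytest.raises(ValueError):
            DurationRecord("s", None, 10.0, True)


class TestKruskalDunn:
    def test_identical_groups_are_null_central(self):
        g = np.arange(10.0)
        res = kruskal_dunn([g, g + 0.0, g + 0.0])
        assert res.kw_chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.kw_p > 0.99

    def test_fully_separated_groups_flag_extreme_pair_first(self):
        res = kruskal_dunn(
            [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])],
            labels=["lo", "mid", "hi"],
        )
        assert res.kw_p < 0.05
        best = res.dunn.sort_values("p_adj").iloc[0]
        assert {best.group_a, best.group_b} == {"lo", "hi"}

    def test_matches_scipy_kruskal(self, rng):
        groups = [rng.normal(i * 0.5, 1, 12) for i in range(3)]
        res = kruskal_dunn(groups)
        chi2, p = stats.kruskal(*groups)
        assert res.kw_chi2 == pytest.approx(chi2)
        assert res.kw_p == pytest.approx(p)

    def test_null_p_values_are_uniform(self, rng):
        """Permutation null: Kruskal-Wallis p uniform on (0,1) at KS tolerance."""
        ps = []
        pooled = rng.normal(size=30)
        for _ in range(2000):
            perm = rng.permutation(pooled)
            ps.append(stats.kruskal(perm[:10], perm[10:20], perm[20:]).pvalue)
        ks = stats.kstest(ps, "uniform")
        assert ks.statistic < 0.06  # discrete statistic; close to uniform

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn([np.array([1.0]), np.array([2.0, 3.0])])


class TestFreemanHalton:
    def test_reduces_to_fisher_exact_on_2x2(self, rng):
        for _ in range(50):
            t = rng.integers(1, 12, size=(2, 2))
            want = stats.fisher_exact(t)[1]
            assert freeman_halton(t) == pytest.approx(want, abs=1e-10)

    def test_probability_conservation_over_the_lattice(self):
        for table in ([[7, 9, 11], [8, 6, 4]], [[10, 8, 10], [5, 7, 5]],
                      [[3, 1, 4], [1, 5, 9], [2, 6, 5]]):
            lps = table_distribution(table)
            assert np.exp(lps).sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_r_fisher_test_on_2x3_tables(self):
        """Pinned to R fisher.test (probability-ordering convention)."""
        assert freeman_halton([[7, 9, 11], [8, 6, 4]]) == pytest.approx(
            0.3884509, abs=2e-4
        )
        assert freeman_halton([[10, 8, 10], [5, 7, 5]]) == pytest.approx(
            0.7954110, abs=2e-4
        )

    def test_monte_carlo_fallback_tracks_exact(self):
        t = [[7, 9, 11], [8, 6, 4]]
        exact = freeman_halton(t)
        mc = freeman_halton(t, monte_carlo=True, n_mc=50_000, seed=5)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_budget_guard_suggests_monte_carlo(self):
        with pytest.raises(ValueError, match="monte_carlo"):
            freeman_halton([[7, 9, 11], [8, 6, 4]], budget=10)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            freeman_halton([[0, 0, 0], [1, 2, 3]])
        with pytest.raises(ValueError):
            freeman_halton([[-1, 2], [3, 4]])
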
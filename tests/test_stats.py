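"""Baseline normalization, exact nonparametric tests, and correlations."""

import numpy as np
import pytest
import scipy.stats as sps

from plvnet import (TimeWindow, baseline_normalize, correlate_with_motor,
                    ks_normality, signed_rank_exact, window_vs_baseline_test)
from plvnet.netmetrics import GraphMetricSeries

from oracles import brute_signed_rank_p

STARTS = np.arange(-1.0, 2.25, 0.25)


def series(values: np.ndarray) -> GraphMetricSeries:
    w, n = values.shape
    return GraphMetricSeries(metric="degree_centrality", values=values,
                             window_starts=STARTS[:w],
                             band="high_beta",
                             channel_names=tuple(f"ch{i}" for i in range(n)))


class TestBaselineNormalize:
    def test_baseline_window_maps_to_zero(self, rng):
        vals = rng.integers(0, 20, size=(13, 6)).astype(float)
        norm = baseline_normalize(series(vals), TimeWindow(-1.0, 1.0))
        assert np.all(norm.values[norm.baseline_index] == 0)

    def test_difference_arithmetic(self):
        vals = np.array([[10.0], [12.0]])
        norm = baseline_normalize(series(vals), TimeWindow(-1.0, 1.0))
        assert norm.values[1, 0] == 2.0

    def test_constant_series_all_zero(self):
        vals = np.full((13, 4), 7.0)
        norm = baseline_normalize(series(vals), TimeWindow(-1.0, 1.0))
        assert np.all(norm.values == 0)

    def test_ratio_mode(self):
        vals = np.array([[2.0], [3.0]])
        norm = baseline_normalize(series(vals), TimeWindow(-1.0, 1.0), mode="ratio")
        assert norm.values[1, 0] == 1.5

    def test_off_grid_baseline_rejected(self):
        with pytest.raises(ValueError):
            baseline_normalize(series(np.zeros((13, 2))), TimeWindow(-0.9, 1.0))


class TestKsNormality:
    def test_gaussian_sample_passes(self):
        x = np.random.default_rng(0).normal(size=9)
        p, verdict = ks_normality(x)
        assert p > 0.05 and verdict == "normal"

    def test_lopsided_two_point_mass_fails(self):
        x = np.array([0.0] * 8 + [1.0])
        p, verdict = ks_normality(x)
        assert p < 0.05 and verdict == "non_normal"

    def test_degenerate_and_small_samples(self):
        assert ks_normality(np.ones(9))[1] == "degenerate"
        with pytest.raises(ValueError):
            ks_normality(np.array([1.0, 2.0]))


class TestSignedRankExact:
    def test_all_positive_n9(self):
        _, p, n = signed_rank_exact(np.arange(1.0, 10.0))
        assert n == 9
        assert p == 2 / 512

    def test_symmetric_differences_not_significant(self):
        _, p, _ = signed_rank_exact(np.array([-2.0, -1.0, 1.0, 2.0]))
        assert p == 1.0

    def test_all_zero_differences(self):
        _, p, n = signed_rank_exact(np.zeros(9))
        assert p == 1.0 and n == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_sign_flip_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 11))
        # integer-valued differences: exercises ties and zeros
        d = r.integers(-4, 5, size=n).astype(float)
        _, p, _ = signed_rank_exact(d)
        assert p == pytest.approx(brute_signed_rank_p(d), abs=1e-12)

    def test_matches_scipy_on_tie_free_input(self):
        r = np.random.default_rng(5)
        d = r.normal(size=10)
        _, p, _ = signed_rank_exact(d)
        assert p == pytest.approx(sps.wilcoxon(d, mode="exact").pvalue, abs=1e-12)

    def test_large_sample_normal_approximation(self):
        r = np.random.default_rng(1)
        d = r.normal(loc=0.8, size=40)
        _, p, _ = signed_rank_exact(d)
        ref = sps.wilcoxon(d, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=0.05)


class TestWindowVsBaseline:
    def _stack(self, rng, shift=0.0):
        # 9 subjects x 5 windows x 3 channels; channel 0 shifted in window 3
        stack = rng.normal(size=(9, 5, 3))
        stack[:, 3, 0] += shift
        return stack

    def test_consistent_shift_detected(self, rng):
        res = window_vs_baseline_test(self._stack(rng, shift=5.0), STARTS[:5], 0,
                                      ("a", "b", "c"))
        assert res.p[3, 0] == 2 / 512  # all 9 diffs positive
        assert res.direction[3, 0] == 1
        assert res.significant(0.05)[3, 0]

    def test_baseline_cell_not_tested(self, rng):
        res = window_vs_baseline_test(self._stack(rng), STARTS[:5], 0,
                                      ("a", "b", "c"))
        assert np.all(res.p[0] == 1.0)

    def test_identical_window_p_one(self, rng):
        stack = self._stack(rng)
        stack[:, 2, :] = stack[:, 0, :]
        res = window_vs_baseline_test(stack, STARTS[:5], 0, ("a", "b", "c"))
        assert np.all(res.p[2] == 1.0)

    def test_rank_sum_mode_runs(self, rng):
        res = window_vs_baseline_test(self._stack(rng, shift=5.0), STARTS[:5], 0,
                                      ("a", "b", "c"), mode="rank_sum")
        assert res.p[3, 0] < 0.05

    def test_fdr_adjustment_is_monotone(self, rng):
        stack = self._stack(rng, shift=5.0)
        raw = window_vs_baseline_test(stack, STARTS[:5], 0, ("a", "b", "c"))
        adj = window_vs_baseline_test(stack, STARTS[:5], 0, ("a", "b", "c"),
                                      fdr=True)
        mask = np.ones_like(raw.p, bool)
        mask[0] = False
        assert np.all(adj.p[mask] >= raw.p[mask] - 1e-12)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            window_vs_baseline_test(rng.normal(size=(4, 5, 3)), STARTS[:5], 0,
                                    ("a", "b", "c"))


class TestCorrelateWithMotor:
    def test_monotone_values_give_unit_rho(self):
        fma = np.array([30.0, 40.0, 45.0, 50.0, 55.0])
        stack = np.tile(fma[:, None, None] * 0.1, (1, 3, 2))
        res = correlate_with_motor(stack, fma, STARTS[:3], ("a", "b"))
        assert np.allclose(res.coefficient, 1.0)

    def test_reversed_scores_negate_rho(self, rng):
        # reversing the score order flips every rank correlation's sign
        fma = np.array([30.0, 40.0, 45.0, 50.0, 55.0])
        stack = rng.normal(size=(5, 3, 2))
        res = correlate_with_motor(stack, fma, STARTS[:3], ("a", "b"))
        rev = correlate_with_motor(stack, -fma, STARTS[:3], ("a", "b"))
        np.testing.assert_allclose(rev.coefficient, -res.coefficient, atol=1e-12)

    def test_independent_values_small_average_rho(self):
        rng = np.random.default_rng(3)
        fma = rng.normal(46.7, 8.0, size=9)
        rhos = []
        for _ in range(50):
            stack = rng.normal(size=(9, 1, 1))
            res = correlate_with_motor(stack, fma, STARTS[:1], ("a",))
            rhos.append(res.coefficient[0, 0])
        assert abs(np.mean(rhos)) < 0.15

    def test_constant_scores_flagged_degenerate(self, rng):
        stack = rng.normal(size=(5, 2, 2))
        res = correlate_with_motor(stack, np.full(5, 40.0), STARTS[:2], ("a", "b"))
        assert res.degenerate and np.all(np.isnan(res.coefficient))

    def test_grid_matches_scipy_cell_by_cell(self, rng):
        # vectorized rank correlation vs scipy.spearmanr, including ties
        stack = rng.integers(0, 5, size=(9, 4, 3)).astype(float)
        fma = rng.normal(46.7, 8.0, size=9)
        res = correlate_with_motor(stack, fma, STARTS[:4], ("a", "b", "c"))
        for w in range(4):
            for c in range(3):
                ref = sps.spearmanr(stack[:, w, c], fma)
                assert res.coefficient[w, c] == pytest.approx(ref.statistic)
                assert res.p[w, c] == pytest.approx(ref.pvalue)

    def test_pearson_mode(self, rng):
        fma = np.array([30.0, 40.0, 45.0, 50.0, 55.0])
        stack = rng.normal(size=(5, 2, 2))
        res = correlate_with_motor(stack, fma, STARTS[:2], ("a", "b"),
                                   method="pearson")
        ref = sps.pearsonr(stack[:, 0, 0], fma).statistic
        assert res.coefficient[0, 0] == pytest.approx(ref)
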
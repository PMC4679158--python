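"""Phase extraction, window grids and PLV estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plvnet import (BAND_BY_NAME, EpochsSet, PhaseTensor, TimeWindow,
                    generate_cohort, instantaneous_phase, plv_matrix,
                    plv_tensor, preprocess_epochs, sliding_windows)

from conftest import coupled_pair_config

HIGH_BETA = BAND_BY_NAME["high_beta"]


def phase_tensor(phases: np.ndarray, rate: float = 256.0,
                 tmin: float = -1.0) -> PhaseTensor:
    names = tuple(f"ch{i}" for i in range(phases.shape[1]))
    return PhaseTensor(phases=phases, rate=rate, tmin=tmin,
                       channel_names=names, band=HIGH_BETA)


def brute_windows(tmin, tmax, length, step):
    starts, s = [], tmin
    while s + length <= tmax + 1e-9:
        starts.append(round(s, 9))
        s += step
    return starts


class TestInstantaneousPhase:
    def test_tone_phase_slope(self):
        rate, f = 256.0, 25.0
        t = -1.0 + np.arange(1024) / rate
        data = np.cos(2 * np.pi * f * t)[None, None, :].repeat(2, axis=1)
        ep = EpochsSet(data=np.ascontiguousarray(data), rate=rate, tmin=-1.0,
                       channel_names=("a", "b"))
        ph = instantaneous_phase(ep, HIGH_BETA)
        slope = np.diff(np.unwrap(ph.phases[0, 0, 200:800])) * rate
        assert slope.mean() == pytest.approx(2 * np.pi * f, abs=0.5)
        assert ph.phases.min() > -np.pi - 1e-12
        assert ph.phases.max() <= np.pi + 1e-12

    def test_constant_lag_recovered(self):
        rate, f = 256.0, 25.0
        t = np.arange(1024) / rate
        a = np.cos(2 * np.pi * f * t)
        b = np.cos(2 * np.pi * f * t - np.pi / 4)
        ep = EpochsSet(data=np.stack([a, b])[None], rate=rate, tmin=0.0,
                       channel_names=("a", "b"))
        ph = instantaneous_phase(ep, HIGH_BETA)
        dphi = np.angle(np.exp(1j * (ph.phases[0, 0, 200:800]
                                     - ph.phases[0, 1, 200:800])))
        assert np.allclose(dphi, np.pi / 4, atol=0.02)

    def test_sign_flip_shifts_phase_by_pi(self):
        rate = 256.0
        t = np.arange(1024) / rate
        a = np.cos(2 * np.pi * 25.0 * t)
        ep = EpochsSet(data=np.stack([a, -a])[None], rate=rate, tmin=0.0,
                       channel_names=("a", "b"))
        ph = instantaneous_phase(ep, HIGH_BETA)
        dphi = np.exp(1j * (ph.phases[0, 0] - ph.phases[0, 1]))
        assert np.allclose(np.angle(dphi[200:800]), np.pi, atol=0.02) or \
            np.allclose(np.abs(np.angle(dphi[200:800])), np.pi, atol=0.02)


class TestSlidingWindows:
    def test_default_analysis_grid(self):
        ws = sliding_windows(-1.0, 3.0, 1.0, 0.25)
        assert len(ws) == 13
        assert ws[0] == TimeWindow(-1.0, 1.0)
        assert ws[-1] == TimeWindow(2.0, 1.0)

    def test_baseline_span_single_window(self):
        ws = sliding_windows(-1.0, 0.0, 1.0, 0.25)
        assert ws == [TimeWindow(-1.0, 1.0)]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(tmin=st.floats(-4, 0), span=st.floats(0.5, 8),
           length=st.floats(0.1, 2), step=st.floats(0.05, 1))
    def test_matches_enumeration_oracle(self, tmin, span, length, step):
        if span < length:
            return
        ws = sliding_windows(tmin, tmin + span, length, step)
        assert [w.start for w in ws] == pytest.approx(
            brute_windows(tmin, tmin + span, length, step), abs=1e-6)

    def test_length_exceeding_span_rejected(self):
        with pytest.raises(ValueError):
            sliding_windows(-1.0, -0.5, 1.0, 0.25)


class TestPlvMatrix:
    def test_identical_phases_give_unity(self, rng):
        p = rng.uniform(-np.pi, np.pi, size=(20, 1, 512))
        ph = phase_tensor(np.repeat(p, 3, axis=1))
        conn = plv_matrix(ph, TimeWindow(-1.0, 1.0))
        off = conn.plv[~np.eye(3, dtype=bool)]
        assert np.all(off == 1.0)
        assert np.all(np.diag(conn.plv) == 0.0)

    def test_constant_lag_gives_unity(self, rng):
        p = rng.uniform(-np.pi, np.pi, size=(20, 1, 512))
        ph = phase_tensor(np.concatenate([p, p + np.pi / 4], axis=1))
        conn = plv_matrix(ph, TimeWindow(-1.0, 1.0))
        assert conn.plv[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_phases_hit_rayleigh_floor(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(-np.pi, np.pi, size=(100, 12, 256))
        conn = plv_matrix(phase_tensor(p), TimeWindow(-1.0, 1.0))
        off = conn.plv[~np.eye(12, dtype=bool)]
        expected = np.sqrt(np.pi) / 2 / np.sqrt(100)  # 0.0886
        assert off.mean() == pytest.approx(expected, rel=0.10)

    def test_common_offset_invariance(self, rng):
        p = rng.uniform(-np.pi, np.pi, size=(15, 4, 300))
        base = plv_matrix(phase_tensor(p), TimeWindow(-1.0, 1.0)).plv
        shifted = plv_matrix(phase_tensor(p + 1.234), TimeWindow(-1.0, 1.0)).plv
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_per_trial_rerandomization_invariance(self, rng):
        p = rng.uniform(-np.pi, np.pi, size=(15, 4, 300))
        offsets = rng.uniform(-np.pi, np.pi, size=(15, 1, 1))
        base = plv_matrix(phase_tensor(p), TimeWindow(-1.0, 1.0)).plv
        rerand = plv_matrix(phase_tensor(p + offsets), TimeWindow(-1.0, 1.0)).plv
        np.testing.assert_allclose(base, rerand, atol=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_bounds_and_symmetry(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(-np.pi, np.pi, size=(5, 4, 64))
        plv = plv_matrix(phase_tensor(p, rate=64.0, tmin=0.0),
                         TimeWindow(0.0, 1.0)).plv
        assert np.all((plv >= 0) & (plv <= 1))
        np.testing.assert_array_equal(plv, plv.T)
        assert np.all(np.diag(plv) == 0)

    def test_single_trial_rejected_across_trials(self, rng):
        p = rng.uniform(-np.pi, np.pi, size=(1, 3, 300))
        with pytest.raises(ValueError):
            plv_matrix(phase_tensor(p), TimeWindow(-1.0, 1.0))
        # the within-trial estimator accepts single trials
        plv_matrix(phase_tensor(p), TimeWindow(-1.0, 1.0), mode="within_trials")


class TestPlvTensor:
    def test_default_grid_yields_52_matrices(self, rng):
        ws = sliding_windows(-1.0, 3.0)
        phases = {name: phase_tensor(rng.uniform(-np.pi, np.pi, (4, 3, 1024)))
                  for name in ("mu", "low_beta", "high_beta", "gamma")}
        tens = plv_tensor(phases, ws)
        assert len(tens) == 52

    def test_tensor_matches_per_window_estimator(self, rng):
        # the shared-accumulator path must reproduce plv_matrix exactly
        p = rng.uniform(-np.pi, np.pi, size=(8, 5, 1024))
        pt = phase_tensor(p)
        ws = sliding_windows(-1.0, 3.0)
        tens = plv_tensor({"high_beta": pt}, ws)
        for w in ws:
            np.testing.assert_allclose(tens[("high_beta", w)].plv,
                                       plv_matrix(pt, w).plv, atol=1e-12)

    def test_channel_permutation_equivariance(self, rng):
        p = rng.uniform(-np.pi, np.pi, size=(10, 5, 300))
        perm = np.array([3, 0, 4, 1, 2])
        w = TimeWindow(-1.0, 1.0)
        base = plv_matrix(phase_tensor(p), w).plv
        permuted = plv_matrix(phase_tensor(p[:, perm, :]), w).plv
        np.testing.assert_allclose(permuted, base[np.ix_(perm, perm)], atol=1e-12)


class TestCouplingMonotonicity:
    def test_stronger_coupling_stronger_plv(self):
        # same seed structure, increasing kappa -> increasing mean PLV
        means = []
        for kappa in (0.3, 0.7):
            vals = []
            for rep in range(8):
                cfg = coupled_pair_config(kappa=kappa, seed=100 + rep, n_trials=24)
                ep = generate_cohort(cfg)[0].epochs["active"]
                bands, _ = preprocess_epochs(ep, target_rate=cfg.rate)
                ph = instantaneous_phase(bands["high_beta"], HIGH_BETA)
                conn = plv_matrix(ph, TimeWindow(0.5, 1.0))
                i, j = ep.channel_index("C3"), ep.channel_index("C4")
                vals.append(conn.plv[i, j])
            means.append(np.mean(vals))
        assert means[0] < means[1]
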
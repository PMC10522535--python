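"""Travelling-wave Fourier analysis: coherence, phase, p-values, labels."""

from itertools import combinations

import numpy as np
import pytest

from somatoprf.fitting import _hrf_kernel
from somatoprf.models import HRFParams
from somatoprf.tw import (
    TravelingWaveAnalyzer,
    coherence_to_p,
    combine_forward_reverse,
    correct_pvalues,
    fourier_analysis,
    phase_to_label,
)


def hommel_closed_testing(p):
    """Exhaustive closed-testing oracle with Simes local tests (m <= 6)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    adj = np.zeros(m)
    for i in range(m):
        worst = 0.0
        for r in range(1, m + 1):
            for sub in combinations(range(m), r):
                if i in sub:
                    sp = np.sort(p[list(sub)])
                    local = min(len(sp) / (j + 1) * sp[j] for j in range(len(sp)))
                    worst = max(worst, local)
        adj[i] = min(1.0, worst)
    return adj


class TestCombineForwardReverse:
    def test_identity_when_rev_is_flipped_fwd(self, rng):
        fwd = rng.normal(0, 1, 64)
        rev = fwd[::-1].copy()
        np.testing.assert_allclose(combine_forward_reverse(fwd, rev, 0), fwd)

    def test_phase_unbiased_despite_hrf_delay(self):
        """Combined phase matches the stimulus phase to < 0.1 rad even
        though each run's response lags by the haemodynamic delay."""
        cyc, n_cycles = 8, 12
        T = cyc * n_cycles
        t = np.arange(T)
        omega = 2 * np.pi / cyc
        kernel = _hrf_kernel(HRFParams().as_array(), 2.0, 32.0)
        for phi in (0.3, 1.5, 4.0):
            neural = np.cos(omega * t - phi)
            fwd = np.convolve(np.tile(neural, 2), kernel)[T : 2 * T]  # steady state
            neural_rev = neural[::-1]
            rev = np.convolve(np.tile(neural_rev, 2), kernel)[T : 2 * T]
            combined = combine_forward_reverse(fwd, rev, lag_tp=2)
            res = fourier_analysis(combined, cyc)
            err = np.angle(np.exp(1j * (res.phase - phi)))
            assert abs(err) < 0.1

    def test_averaging_halves_noise_variance(self, rng):
        noise_f = rng.normal(0, 1, (2000, 32))
        noise_r = rng.normal(0, 1, (2000, 32))
        combined = combine_forward_reverse(noise_f, noise_r, 2)
        assert combined.var() == pytest.approx(0.5, rel=0.05)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            combine_forward_reverse(np.zeros(10), np.zeros(12))


class TestFourierAnalysis:
    def test_pure_sinusoid_coherence_one(self):
        t = np.arange(96)
        res = fourier_analysis(np.cos(2 * np.pi * t / 8), 8)
        assert res.coherence == pytest.approx(1.0)
        assert res.amplitude == pytest.approx(1.0)

    @pytest.mark.parametrize("phi", [0.0, 0.7, 2.0, 5.5])
    def test_phase_recovery_matches_dft_oracle(self, phi):
        t = np.arange(96)
        ts = 3.0 * np.cos(2 * np.pi * t / 8 - phi)
        res = fourier_analysis(ts, 8)
        assert np.angle(np.exp(1j * (res.phase - phi))) == pytest.approx(0.0, abs=1e-10)
        assert res.amplitude == pytest.approx(3.0)

    def test_white_noise_coherence_expectation(self, rng):
        """E[c^2] ~ 1/K for K non-DC bins under white noise."""
        X = rng.normal(0, 1, (4000, 96))
        res = fourier_analysis(X, 8)
        c2 = np.array([r.coherence**2 for r in res])
        assert c2.mean() == pytest.approx(1.0 / 47, rel=0.1)

    def test_non_divisible_length(self):
        with pytest.raises(ValueError):
            fourier_analysis(np.zeros(97), 8)


class TestCoherenceToP:
    def test_endpoints_and_monotonicity(self):
        assert coherence_to_p(0.0, 48) == 1.0
        assert coherence_to_p(1.0, 48) == 0.0
        c = np.linspace(0, 1, 11)
        p = coherence_to_p(c, 48)
        assert (np.diff(p) <= 0).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            coherence_to_p(1.5, 48)
        with pytest.raises(ValueError):
            coherence_to_p(0.5, 1)


class TestHommel:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(correct_pvalues([0.03]), [0.03])

    def test_identical_ps_equal_raw(self):
        """Simes local test of m identical p's is p itself, so the closed
        testing (Hommel) adjustment leaves identical p-values unchanged."""
        out = correct_pvalues([0.01] * 4)
        oracle = hommel_closed_testing([0.01] * 4)
        np.testing.assert_allclose(out, oracle)
        np.testing.assert_allclose(out, [0.01] * 4)

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_matches_closed_testing_oracle(self, m, rng):
        for _ in range(10):
            p = rng.random(m)
            np.testing.assert_allclose(
                correct_pvalues(p), hommel_closed_testing(p), atol=1e-12
            )

    def test_never_below_raw_and_monotone(self, rng):
        p = rng.random(20)
        adj = correct_pvalues(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            correct_pvalues([])


class TestPhaseToLabel:
    def test_bins_partition_circle(self):
        phases = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        labels = phase_to_label(phases, 4, offset=0.0)
        assert set(labels) == {1, 2, 3, 4}
        counts = np.bincount(labels)[1:]
        assert counts.max() - counts.min() <= 1

    def test_bin_centres_and_offset(self):
        for k in range(4):
            centre = np.pi / 4 + k * np.pi / 2
            assert phase_to_label(centre, 4, 0.0) == k + 1
        assert phase_to_label(0.3, 4, offset=0.3) == 1  # phase == offset -> bin 1
        assert phase_to_label(-0.1, 4, 0.0) == 4  # wrapping


class TestTravelingWaveAnalyzer:
    def test_amplitude_scaling_invariance_of_coherence(self, rng):
        x = rng.normal(0, 1, (5, 96)) + np.cos(2 * np.pi * np.arange(96) / 8)
        a = TravelingWaveAnalyzer(cycle_len_tp=8).fit(x)
        b = TravelingWaveAnalyzer(cycle_len_tp=8).fit(10.0 * x)
        np.testing.assert_allclose(a.coherence_, b.coherence_, rtol=1e-12)
        np.testing.assert_allclose(a.phase_, b.phase_, rtol=1e-12)

    def test_results_frame_columns(self, rng):
        x = rng.normal(0, 1, (4, 96))
        df = TravelingWaveAnalyzer(cycle_len_tp=8).fit(x).results_frame()
        assert {"coherence", "phase", "p_corrected", "label"} <= set(df.columns)
        assert df["label"].between(1, 4).all()

    def test_orderly_label_gradient_on_synthetic_tw(self):
        """Voxels preferring successive digits get successive labels."""
        from somatoprf.grid import build_tw_sequence
        from somatoprf.models import PRF2DParams, predict_timecourse, HRFParams
        from somatoprf.grid import time_reverse

        fwd_seq = build_tw_sequence("between", "forward")
        rev_seq = build_tw_sequence("between", "reverse")
        hrf = HRFParams()
        d0s = [1.0, 2.0, 3.0, 4.0]
        fwd = np.vstack(
            [predict_timecourse(PRF2DParams(d, 2.5, 0.5, 1.0), hrf, fwd_seq) for d in d0s]
        )
        rev = np.vstack(
            [predict_timecourse(PRF2DParams(d, 2.5, 0.5, 1.0), hrf, rev_seq) for d in d0s]
        )
        fwd -= fwd.mean(axis=1, keepdims=True)
        rev -= rev.mean(axis=1, keepdims=True)
        twa = TravelingWaveAnalyzer(cycle_len_tp=8).fit(fwd, rev)
        assert list(twa.labels_) == [1, 2, 3, 4]
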
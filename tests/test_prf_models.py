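"""pRF model families, HRF kernel, and BOLD prediction."""

import numpy as np
import pytest

from somatoprf.grid import GridSpec, StimulusSequence, build_tw_sequence
from somatoprf.models import (
    FWHM_PER_SIGMA,
    HRFParams,
    PRF1DBDParams,
    PRF1DWDParams,
    PRF2DParams,
    UnconstrainedWeights,
    count_free_parameters,
    eval_weights,
    evaluate_hrf,
    predict_timecourse,
    preferred_location,
)


class TestEvalWeights:
    def test_2d_centre_and_symmetry(self):
        w = eval_weights(PRF2DParams(2, 3, 1, 1))
        assert w[1, 2] == pytest.approx(1.0)
        assert w.argmax() == np.ravel_multi_index((1, 2), (4, 4))
        assert w[0, 2] == pytest.approx(w[2, 2])  # symmetric about d0

    def test_2d_hand_computed_value(self):
        # site (1,1) with centre (2.5, 2.5), sigma_d=1, sigma_pd=2:
        # exp(-(1.5^2/2 + 1.5^2/8)) = exp(-1.40625)
        w = eval_weights(PRF2DParams(2.5, 2.5, 1.0, 2.0))
        assert w[0, 0] == pytest.approx(np.exp(-1.40625), abs=1e-10)
        assert w[0, 0] == pytest.approx(0.2451, abs=5e-5)

    def test_2d_separable_outer_product(self):
        p = PRF2DParams(1.7, 3.2, 0.8, 1.4)
        w = eval_weights(p)
        gd = np.exp(-((p.d0 - np.arange(1, 5)) ** 2) / (2 * p.sigma_d**2))
        gpd = np.exp(-((p.pd0 - np.arange(1, 5)) ** 2) / (2 * p.sigma_pd**2))
        np.testing.assert_allclose(w, np.outer(gd, gpd), rtol=1e-12)

    def test_1d_models_match_2d_slices_up_to_scale(self):
        """Row/column profiles of the 1D families equal the matching 2D slice."""
        p2 = PRF2DParams(2.0, 3.0, 0.9, 0.9)
        w2 = eval_weights(p2)
        bd = PRF1DBDParams(centers=(2.0,) * 4, sigmas=(0.9,) * 4)
        wbd = eval_weights(bd)
        for j in range(4):
            ratio = w2[:, j] / wbd[:, j]
            np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)
        wd = PRF1DWDParams(centers=(3.0,) * 4, sigmas=(0.9,) * 4)
        wwd = eval_weights(wd)
        for i in range(4):
            ratio = w2[i, :] / wwd[i, :]
            np.testing.assert_allclose(ratio, ratio[0], rtol=1e-12)

    def test_unconstrained_verbatim(self):
        w0 = np.arange(16.0)
        w = eval_weights(UnconstrainedWeights(weights=tuple(w0)))
        np.testing.assert_array_equal(w.ravel(), w0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            PRF2DParams(2, 2, -1.0, 1.0)
        with pytest.raises(ValueError):
            PRF1DBDParams(centers=(2,) * 4, sigmas=(1, 0, 1, 1))


class TestPreferredLocation:
    def test_2d_returns_own_centre(self):
        d, pd, size = preferred_location(PRF2DParams(2.3, 1.8, 0.7, 1.1))
        assert (d, pd) == (2.3, 1.8)
        assert size == (0.7, 1.1)

    def test_1d_bd_argmax_scale(self):
        p = PRF1DBDParams(
            centers=(1.0, 2.0, 3.0, 4.0), sigmas=(0.5, 0.6, 0.7, 0.8),
            scales=(1.0, 3.0, 2.0, 1.0),
        )
        d, pd, size = preferred_location(p)
        assert pd == 2  # PD row with maximal scale
        assert d == 2.0 and size == (0.6,)

    def test_1d_wd_mirror(self):
        p = PRF1DWDParams(
            centers=(1.0, 2.0, 3.0, 4.0), sigmas=(0.5, 0.6, 0.7, 0.8),
            scales=(1.0, 1.0, 4.0, 1.0),
        )
        d, pd, size = preferred_location(p)
        assert d == 3 and pd == 3.0 and size == (0.7,)

    def test_tie_breaks_low_with_warning(self):
        p = PRF1DBDParams(centers=(1, 2, 3, 4), sigmas=(1,) * 4, scales=(1, 1, 1, 1))
        with pytest.warns(UserWarning, match="tie"):
            _, pd, _ = preferred_location(p)
        assert pd == 1

    def test_unconstrained_one_hot(self):
        w = np.zeros(16)
        w[GridSpec().site_index(3, 1)] = 1.0
        d, pd, size = preferred_location(UnconstrainedWeights(weights=tuple(w)))
        assert (d, pd) == (3, 1) and size is None


class TestHRF:
    def test_kernel_length_and_linearity(self, hrf):
        k = evaluate_hrf(hrf, tr=2.0, duration=32.0)
        assert len(k) == 17  # floor(32/2)+1
        k2 = evaluate_hrf(HRFParams(amplitude=2.0), tr=2.0, duration=32.0)
        np.testing.assert_allclose(k2, 2 * k, rtol=1e-12)

    def test_peak_time_increases_with_delay(self):
        tr = 0.5
        peaks = []
        for delay in (4.0, 5.0, 6.0, 7.0, 8.0):
            k = evaluate_hrf(HRFParams(peak_delay=delay), tr, 32.0)
            peaks.append(np.argmax(k) * tr)
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_undershoot_and_validation(self, hrf):
        k = evaluate_hrf(hrf, tr=1.0, duration=32.0)
        assert k.min() < 0 < k.max()  # unimodal with undershoot
        assert k.max() == pytest.approx(hrf.amplitude, rel=1e-2)
        with pytest.raises(ValueError):
            HRFParams(dispersion=-1.0)
        with pytest.raises(ValueError):
            evaluate_hrf(hrf, tr=2.0, duration=1.0)


class TestPredictTimecourse:
    def test_delta_stimulus_returns_scaled_kernel(self, grid, hrf):
        mat = np.zeros((20, 16), dtype=np.uint8)
        site = grid.site_index(2, 3)
        mat[0, site] = 1
        seq = StimulusSequence(mat, tr=2.0, cycle_len=40.0, n_cycles=1,
                               paradigm="between", direction="forward")
        p = PRF2DParams(2, 3, 1, 1)  # centre weight 1 at the pulsed site
        pred = predict_timecourse(p, hrf, seq)
        kernel = evaluate_hrf(hrf, 2.0, 32.0)
        np.testing.assert_allclose(pred[: len(kernel)], kernel, rtol=1e-10)

    def test_zero_stimulus_zero_prediction(self, hrf):
        mat = np.zeros((10, 16), dtype=np.uint8)
        seq = StimulusSequence(mat, 2.0, 20.0, 1, "between", "forward")
        assert not predict_timecourse(PRF2DParams(2, 2, 1, 1), hrf, seq).any()

    def test_periodicity_against_convolution_oracle(self, hrf):
        """BD prediction is cycle-periodic and equals brute-force convolution."""
        seq = build_tw_sequence("between", "forward", n_cycles=12)
        p = PRF2DParams(3.0, 2.0, 0.8, 1.2)
        pred = predict_timecourse(p, hrf, seq)
        # independent oracle: explicit sum over sites and kernel taps
        w = eval_weights(p).ravel()
        kernel = evaluate_hrf(hrf, seq.tr, 32.0)
        oracle = np.zeros(seq.n_timepoints)
        for t in range(seq.n_timepoints):
            for k, h in enumerate(kernel):
                if t - k >= 0:
                    oracle[t] += h * float(seq.matrix[t - k] @ w)
        np.testing.assert_allclose(pred, oracle, rtol=1e-10)
        cyc = seq.cycle_len_tp
        # steady-state cycles (beyond the kernel transient) repeat
        np.testing.assert_allclose(pred[3 * cyc : 4 * cyc], pred[4 * cyc : 5 * cyc], rtol=1e-10)


def test_free_parameter_totals():
    """9 / 16 / 16 / 21 total parameters, each including 5 HRF parameters."""
    assert count_free_parameters("2d_gaussian") == 9
    assert count_free_parameters("1d_bd") == 16
    assert count_free_parameters("1d_wd") == 16
    assert count_free_parameters("unconstrained") == 21
    with pytest.raises(ValueError):
        count_free_parameters("3d_gaussian")


def test_fwhm_sigma_ratio():
    assert FWHM_PER_SIGMA == pytest.approx(2.355, abs=5e-4)
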
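"""Preprocessing, grid-search initialisation, and nonlinear pRF fitting."""

import numpy as np
import pytest
from sklearn.base import clone

from somatoprf.fitting import (
    PRFEstimator,
    adjusted_r2,
    aic,
    fit_voxel,
    grid_search_init,
    preprocess_timeseries,
)
from somatoprf.models import HRFParams, PRF2DParams, predict_timecourse


class TestPreprocess:
    def test_constant_series_becomes_zero(self):
        out = preprocess_timeseries(np.full(100, 250.0), tr=2.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_linear_drift_removed(self):
        t = np.arange(120.0)
        out = preprocess_timeseries(1000 + 3 * t, tr=2.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_offset_invariance(self, rng):
        x = 1000 + rng.normal(0, 5, 200)
        a = preprocess_timeseries(x, tr=2.0)
        b = preprocess_timeseries(x + 500.0, tr=2.0)
        # PSC normalisation: adding an offset only rescales by the new mean
        np.testing.assert_allclose(a * x.mean(), b * (x.mean() + 500.0), rtol=1e-8)

    def test_zero_mean_per_run(self, rng):
        x = 1000 + rng.normal(0, 5, (3, 200))
        runs = [(0, 120), (120, 200)]
        out = preprocess_timeseries(x, tr=2.0, run_boundaries=runs)
        for a, b in runs:
            np.testing.assert_allclose(out[:, a:b].mean(axis=1), 0.0, atol=1e-10)

    def test_short_run_warns_detrend_only(self):
        with pytest.warns(UserWarning, match="shorter"):
            preprocess_timeseries(np.arange(20.0) + 100, tr=2.0, highpass_hz=0.01)


class TestGoodnessOfFit:
    def test_adjusted_r2_values(self):
        assert adjusted_r2(1.0, 96, 9) == 1.0
        assert adjusted_r2(0.0, 96, 9) == pytest.approx(-0.104651162790697, rel=1e-12)
        # more parameters always penalise harder at fixed r2 < 1
        vals = [adjusted_r2(0.5, 96, p) for p in (5, 9, 16, 21)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 10, 9)

    def test_aic_values(self):
        assert aic(96.0, 96, 9) == pytest.approx(18.0)  # rss = n -> 2k
        assert aic(48.0, 96, 9) == pytest.approx(96 * np.log(0.5) + 18, rel=1e-12)
        assert aic(10.0, 96, 9) < aic(20.0, 96, 9)
        assert aic(0.0, 96, 9) == -np.inf


class TestGridSearch:
    def test_lattice_point_recovered_exactly(self, short_seq):
        truth = PRF2DParams(3.0, 2.0, 1.0, 2.0)  # on the default lattice
        hrf = HRFParams()
        y = predict_timecourse(truth, hrf, short_seq)
        y = preprocess_timeseries(y, short_seq.tr,
                                  run_boundaries=short_seq.run_boundaries, to_psc=False)
        x0, rss, idx = grid_search_init(y, "2d_gaussian", short_seq)
        assert tuple(x0[:4]) == (3.0, 2.0, 1.0, 2.0)
        assert rss == pytest.approx(0.0, abs=1e-12)

    def test_rss_bounded_by_every_lattice_point(self, short_seq, rng):
        """Returned rss is the lattice argmin (checked against an
        independent enumeration with optimal linear scaling)."""
        y = rng.normal(0, 1, short_seq.n_timepoints)
        x0, rss, idx = grid_search_init(y, "2d_gaussian", short_seq)
        hrf = HRFParams()
        from somatoprf.fitting import _make_predictor

        predict = _make_predictor("2d_gaussian", short_seq, 32.0)
        h = hrf.as_array()
        for d0 in (1.0, 2.0, 3.0, 4.0):
            for pd0 in (1.0, 2.0, 3.0, 4.0):
                for sd in (0.5, 1.0, 2.0):
                    for spd in (0.5, 1.0, 2.0):
                        p = predict(np.concatenate(([d0, pd0, sd, spd], h)))
                        scale = (p @ y) / (p @ p)
                        assert rss <= np.sum((y - scale * p) ** 2) + 1e-9

    def test_nan_voxel_rejected(self, short_seq):
        y = np.full(short_seq.n_timepoints, np.nan)
        with pytest.raises(ValueError, match="finite"):
            grid_search_init(y, "2d_gaussian", short_seq)


class TestFitVoxel:
    def test_noiseless_recovery(self, short_seq):
        """Noiseless voxel: centres within 1e-3 grid units, sigma within 1e-2."""
        truth = PRF2DParams(2.3, 3.1, 0.8, 1.6)
        y = predict_timecourse(truth, HRFParams(amplitude=2.0), short_seq)
        y = preprocess_timeseries(y, short_seq.tr,
                                  run_boundaries=short_seq.run_boundaries, to_psc=False)
        res = fit_voxel(y, "2d_gaussian", short_seq)
        assert res.converged
        assert res.params.d0 == pytest.approx(truth.d0, abs=1e-3)
        assert res.params.pd0 == pytest.approx(truth.pd0, abs=1e-3)
        assert res.params.sigma_d == pytest.approx(truth.sigma_d, abs=1e-2)
        assert res.params.sigma_pd == pytest.approx(truth.sigma_pd, abs=1e-2)
        assert res.adjusted_r2 == pytest.approx(1.0, abs=1e-6)
        assert res.rss <= res.init_rss + 1e-12

    @pytest.mark.parametrize("family", ["1d_bd", "1d_wd", "unconstrained"])
    def test_descent_contract_all_families(self, family, short_seq, rng):
        y = rng.normal(0, 1, short_seq.n_timepoints)
        res = fit_voxel(y, family, short_seq, max_nfev=200)
        assert res.rss <= res.init_rss + 1e-9
        assert np.isfinite(res.aic)

    def test_unknown_family(self, short_seq):
        with pytest.raises(ValueError):
            fit_voxel(np.zeros(short_seq.n_timepoints), "nope", short_seq)


class TestPRFEstimator:
    def test_sklearn_protocol(self, short_seq):
        est = PRFEstimator(seq=short_seq, model="2d_gaussian")
        cloned = clone(est)
        assert cloned.get_params()["model"] == "2d_gaussian"
        est.set_params(model="1d_bd")
        assert est.model == "1d_bd"

    def test_fit_and_frame(self, short_seq):
        truths = [PRF2DParams(1.5, 2.0, 0.6, 1.2), PRF2DParams(3.5, 3.0, 1.0, 2.0)]
        Y = np.vstack(
            [predict_timecourse(t, HRFParams(amplitude=2.0), short_seq) for t in truths]
        )
        Y = preprocess_timeseries(Y, short_seq.tr,
                                  run_boundaries=short_seq.run_boundaries, to_psc=False)
        est = PRFEstimator(seq=short_seq, model="2d_gaussian").fit(Y)
        df = est.results_frame()
        assert list(df["voxel"]) == [0, 1]
        np.testing.assert_allclose(df["preferred_digit"], [1.5, 3.5], atol=1e-3)
        np.testing.assert_allclose(df["sigma_pd"], [1.2, 2.0], atol=1e-2)
        assert (est.adjusted_r2_ > 0.999).all()
        pred = est.predict()
        assert pred.shape == Y.shape
        assert est.score(Y) > 0.999

    def test_validation_errors(self, short_seq):
        with pytest.raises(ValueError, match="time points"):
            PRFEstimator(seq=short_seq).fit(np.zeros((2, 10)))
        with pytest.raises(ValueError, match="family"):
            PRFEstimator(seq=short_seq, model="nope").fit(
                np.zeros((1, short_seq.n_timepoints))
            )
        with pytest.raises(RuntimeError, match="not fitted"):
            PRFEstimator(seq=short_seq).predict()
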
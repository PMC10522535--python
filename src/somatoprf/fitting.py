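"""Voxel-wise preprocessing and nonlinear least-squares pRF estimation.

The estimation follows the standard pRF fitting recipe: candidate model
parameters generate a predicted BOLD time course (weight grid x stimulus,
convolved with the HRF); the residual sum of squares against the measured,
percent-signal-change voxel data is minimised by bounded nonlinear least
squares, initialised from a coarse grid search over pRF centres and sizes
to avoid local minima.  Goodness of fit is summarised by adjusted r^2
(which penalises the parameter count and may go negative; voxels are
conventionally kept at adjusted r^2 > 0) and by the least-squares AIC used
to rank model families per voxel.

:class:`PRFEstimator` is the scikit-learn style front end: construct it
with a stimulus sequence and model family, call ``fit`` on a
(voxels x time) data array, and read the per-voxel results off the fitted
attributes.  The module-level functions (``preprocess_timeseries``,
``grid_search_init``, ``fit_voxel``, ``adjusted_r2``, ``aic``) are thin
functional wrappers over the same machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .grid import StimulusSequence
from .models import (
    CENTER_BOUNDS,
    MODEL_FAMILIES,
    N_HRF_PARAMS,
    SIGMA_BOUNDS,
    HRFParams,
    PRF1DBDParams,
    PRF1DWDParams,
    PRF2DParams,
    UnconstrainedWeights,
    count_free_parameters,
)

__all__ = [
    "FitResult",
    "PRFEstimator",
    "preprocess_timeseries",
    "grid_search_init",
    "fit_voxel",
    "adjusted_r2",
    "aic",
]

_N_SPATIAL = {"2d_gaussian": 4, "1d_bd": 11, "1d_wd": 11, "unconstrained": 16}
_SCALE_BOUNDS = (1e-3, 1e3)
_WEIGHT_BOUNDS = (-1e3, 1e3)
_AMP_BOUNDS = (-1e3, 1e3)
# loose physiological ranges for the HRF shape parameters
_HRF_BOUNDS = [(2.0, 10.0), (10.0, 25.0), (0.2, 3.0), (2.0, 15.0), _AMP_BOUNDS]


# ---------------------------------------------------------------------------
# goodness-of-fit statistics


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted coefficient of determination, 1 - (1-r2)(n-1)/(n-p-1).

    Penalises r^2 for the number of fitted parameters ``p``; can be
    negative, which is why voxel selection thresholds at > 0.
    """
    if n <= p + 1:
        raise ValueError(f"adjusted r2 undefined for n={n} <= p+1={p + 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def aic(rss: float, n: int, k: int) -> float:
    """Least-squares Akaike Information Criterion, n ln(rss/n) + 2k.

    A perfect fit (rss = 0) returns ``-inf`` as a sentinel.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        return -np.inf
    return n * float(np.log(rss / n)) + 2 * k


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_timeseries(
    ts: np.ndarray,
    tr: float,
    highpass_hz: float = 0.01,
    run_boundaries: list[tuple[int, int]] | None = None,
    to_psc: bool = True,
) -> np.ndarray:
    """Detrend, high-pass filter and convert voxel data to percent signal change.

    Per run: a linear trend is removed, slow drifts below ``highpass_hz``
    are projected out on a discrete-cosine basis, and the residual is
    scaled by 100 / (pre-detrend run mean).  The output is zero-mean
    within every run.  Runs shorter than one cutoff period are only
    detrended (with a warning).

    Set ``to_psc=False`` for data already in percent-signal-change units
    (detrend/high-pass only, no rescaling).

    ``ts`` may be 1D (time,) or 2D (voxels, time).
    """
    x = np.atleast_2d(np.asarray(ts, dtype=float))
    T = x.shape[1]
    if run_boundaries is None:
        run_boundaries = [(0, T)]
    out = np.empty_like(x)
    for start, stop in run_boundaries:
        run = x[:, start:stop]
        n = stop - start
        m0 = run.mean(axis=1, keepdims=True)
        if n * tr < 1.0 / highpass_hz:
            warnings.warn(
                f"run of {n} volumes is shorter than one {highpass_hz} Hz period; "
                "detrending only",
                stacklevel=2,
            )
        # intercept + linear trend + DCT-II regressors below the cutoff
        A = _confound_design(n, tr, highpass_hz)
        beta, *_ = np.linalg.lstsq(A, run.T, rcond=None)
        resid = run - (A @ beta).T
        if to_psc:
            denom = np.where(np.abs(m0) < 1e-9, 1.0, m0)
            resid = 100.0 * resid / denom
        out[:, start:stop] = resid
    return out.reshape(np.asarray(ts).shape)


# ---------------------------------------------------------------------------
# fast model evaluation on packed parameter vectors
#
# packed layout: [spatial params..., peak_delay, undershoot_delay,
# dispersion, ratio, amplitude]
#   2d_gaussian   spatial = [d0, pd0, sigma_d, sigma_pd]
#   1d_bd / 1d_wd spatial = [c1..c4, s1..s4, k2, k3, k4]   (reference k = 1)
#   unconstrained spatial = [w0..w15]


def _gamma_pdf(t: np.ndarray, a: float, scale: float) -> np.ndarray:
    tt = np.maximum(t, 1e-12)
    return np.where(
        t > 0,
        np.exp((a - 1.0) * np.log(tt) - tt / scale - gammaln(a) - a * np.log(scale)),
        0.0,
    )


def _hrf_kernel(xh: np.ndarray, tr: float, duration: float) -> np.ndarray:
    peak_delay, undershoot_delay, dispersion, ratio, amplitude = xh
    n = int(np.floor(duration / tr)) + 1
    t = np.arange(n) * tr
    a1 = peak_delay / dispersion
    a2 = undershoot_delay / dispersion
    dense = np.arange(0.0, duration + 1e-9, min(tr, 0.1))

    def shape(tt):
        return _gamma_pdf(tt, a1, dispersion) - _gamma_pdf(tt, a2, dispersion) / ratio

    peak = float(np.max(shape(dense)))
    return amplitude * shape(t) / peak


def _weights_vec(family: str, xs: np.ndarray, dc: np.ndarray, pdc: np.ndarray) -> np.ndarray:
    """Site weights (site order) from a packed spatial parameter vector."""
    if family == "2d_gaussian":
        d0, pd0, sd, spd = xs
        return np.exp(-((d0 - dc) ** 2 / (2 * sd**2) + (pd0 - pdc) ** 2 / (2 * spd**2)))
    if family == "1d_bd":
        idx = (pdc - 1).astype(int)  # profile index = PD row
        on_axis = dc
    elif family == "1d_wd":
        idx = (dc - 1).astype(int)  # profile index = digit
        on_axis = pdc
    elif family == "unconstrained":
        return xs
    else:  # pragma: no cover
        raise ValueError(family)
    centers, sigmas = xs[0:4][idx], xs[4:8][idx]
    scales = np.concatenate(([1.0], xs[8:11]))[idx]
    return scales * np.exp(-((centers - on_axis) ** 2) / (2 * sigmas**2))


def _confound_design(n: int, tr: float, highpass_hz: float) -> np.ndarray:
    """Per-run confound design: intercept, linear trend, low-frequency DCT."""
    t = np.arange(n, dtype=float)
    design = [np.ones(n), t - t.mean()]
    if n * tr >= 1.0 / highpass_hz:
        n_reg = int(np.floor(2.0 * n * tr * highpass_hz))
        for k in range(1, n_reg + 1):
            design.append(np.cos(np.pi * k * (t + 0.5) / n))
    return np.column_stack(design)


def _run_projectors(runs: list[tuple[int, int]], tr: float, highpass_hz: float):
    """Orthonormal per-run confound bases (for projecting predictions the
    same way the measured data were detrended/high-passed)."""
    out = []
    for a, b in runs:
        Q, _ = np.linalg.qr(_confound_design(b - a, tr, highpass_hz))
        out.append((a, b, Q))
    return out


def _make_predictor(
    family: str, seq: StimulusSequence, hrf_duration: float, highpass_hz: float = 0.01
):
    """Forward model matched to the preprocessing: within each run the
    prediction is projected onto the orthogonal complement of the same
    confound design (mean, linear trend, low-frequency DCT regressors)
    that preprocessing removes from the measured data."""
    stim = seq.matrix.astype(float)
    runs = list(seq.run_boundaries)
    projs = _run_projectors(runs, seq.tr, highpass_hz)
    dc, pdc = seq.grid.digit_coords, seq.grid.pd_coords
    ns = _N_SPATIAL[family]
    tr = seq.tr

    def predict(x: np.ndarray) -> np.ndarray:
        w = _weights_vec(family, x[:ns], dc, pdc)
        neural = stim @ w
        kernel = _hrf_kernel(x[ns:], tr, hrf_duration)
        out = np.empty_like(neural)
        for a, b, Q in projs:
            seg = np.convolve(neural[a:b], kernel)[: b - a]
            out[a:b] = seg - Q @ (Q.T @ seg)
        return out

    return predict


def _family_bounds(family: str) -> tuple[np.ndarray, np.ndarray]:
    lo: list[float] = []
    hi: list[float] = []
    if family == "2d_gaussian":
        pairs = [CENTER_BOUNDS] * 2 + [SIGMA_BOUNDS] * 2
    elif family in ("1d_bd", "1d_wd"):
        pairs = [CENTER_BOUNDS] * 4 + [SIGMA_BOUNDS] * 4 + [_SCALE_BOUNDS] * 3
    elif family == "unconstrained":
        pairs = [_WEIGHT_BOUNDS] * 16
    else:
        raise ValueError(f"unknown model family {family!r}")
    pairs = pairs + _HRF_BOUNDS
    for a, b in pairs:
        lo.append(a)
        hi.append(b)
    return np.array(lo), np.array(hi)


def _unpack(family: str, x: np.ndarray):
    """Packed vector -> (spatial parameter dataclass, HRFParams)."""
    ns = _N_SPATIAL[family]
    xs, xh = x[:ns], x[ns:]
    hrf = HRFParams.from_array(xh)
    if family == "2d_gaussian":
        return PRF2DParams(*map(float, xs)), hrf
    if family in ("1d_bd", "1d_wd"):
        cls = PRF1DBDParams if family == "1d_bd" else PRF1DWDParams
        return (
            cls(
                centers=tuple(map(float, xs[0:4])),
                sigmas=tuple(map(float, xs[4:8])),
                scales=(1.0,) + tuple(map(float, xs[8:11])),
            ),
            hrf,
        )
    return UnconstrainedWeights(weights=tuple(map(float, xs))), hrf


# ---------------------------------------------------------------------------
# grid-search initialisation


class _GridSearcher:
    """Precomputed coarse-lattice search shared across voxels of one family."""

    def __init__(
        self,
        family: str,
        seq: StimulusSequence,
        hrf0: HRFParams,
        centers=(1.0, 2.0, 3.0, 4.0),
        sigmas=(0.5, 1.0, 2.0),
        hrf_duration: float = 32.0,
    ):
        self.family = family
        self.seq = seq
        self.hrf0 = hrf0
        self.hrf_duration = hrf_duration
        kernel = _hrf_kernel(
            np.array([hrf0.peak_delay, hrf0.undershoot_delay, hrf0.dispersion, hrf0.ratio, 1.0]),
            seq.tr,
            hrf_duration,
        )

        projs = _run_projectors(list(seq.run_boundaries), seq.tr, 0.01)

        def conv(v: np.ndarray) -> np.ndarray:
            out = np.empty_like(v, dtype=float)
            for a, b, Q in projs:
                seg = np.convolve(v[a:b], kernel)[: b - a]
                out[a:b] = seg - Q @ (Q.T @ seg)
            return out

        stim = seq.matrix.astype(float)
        dc, pdc = seq.grid.digit_coords, seq.grid.pd_coords
        if family == "2d_gaussian":
            self.cands = [
                (d0, pd0, sd, spd)
                for d0 in centers
                for pd0 in centers
                for sd in sigmas
                for spd in sigmas
            ]
            P = np.empty((len(self.cands), seq.n_timepoints))
            for i, xs in enumerate(self.cands):
                w = _weights_vec(family, np.array(xs), dc, pdc)
                P[i] = conv(stim @ w)
            self.P = P
            self.PP = np.einsum("ct,ct->c", P, P)
        elif family in ("1d_bd", "1d_wd"):
            idx = ((pdc if family == "1d_bd" else dc) - 1).astype(int)
            on_axis = dc if family == "1d_bd" else pdc
            self.cands = [(c, s) for c in centers for s in sigmas]
            self.X = []  # per candidate: (T, 4) one regressor per profile
            self.G = []
            for c, s in self.cands:
                prof = np.exp(-((c - on_axis) ** 2) / (2 * s**2))
                X = np.zeros((seq.n_timepoints, 4))
                for j in range(4):
                    mask = idx == j
                    X[:, j] = conv(stim[:, mask] @ prof[mask])
                self.X.append(X)
                self.G.append(X.T @ X + 1e-10 * np.eye(4))
        else:  # unconstrained: per-site regressors, linear solve
            X = np.column_stack([conv(stim[:, j]) for j in range(stim.shape[1])])
            self.X = X
            self.pinv = np.linalg.pinv(X)
            self.cands = [None]

    def search(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Best lattice point per voxel.

        Returns (x0 array (n_vox, n_params), rss (n_vox,), index (n_vox,)).
        """
        Y = np.atleast_2d(Y)
        n_vox = Y.shape[0]
        yy = np.einsum("vt,vt->v", Y, Y)
        h0 = self.hrf0.as_array()
        family = self.family
        n_params = _N_SPATIAL[family] + N_HRF_PARAMS
        x0 = np.empty((n_vox, n_params))
        if family == "2d_gaussian":
            C = Y @ self.P.T  # (n_vox, n_cand)
            rss_all = yy[:, None] - C**2 / self.PP[None, :]
            idx = np.argmin(rss_all, axis=1)
            amp = C[np.arange(n_vox), idx] / self.PP[idx]
            for v in range(n_vox):
                x0[v, :4] = self.cands[idx[v]]
                x0[v, 4:] = h0
                x0[v, -1] = h0[-1] * amp[v]
            rss = rss_all[np.arange(n_vox), idx]
        elif family in ("1d_bd", "1d_wd"):
            best_rss = np.full(n_vox, np.inf)
            idx = np.zeros(n_vox, dtype=int)
            best_k = np.zeros((n_vox, 4))
            for i, X in enumerate(self.X):
                B = X.T @ Y.T  # (4, n_vox)
                K = np.linalg.solve(self.G[i], B)
                rss_i = yy - np.einsum("jv,jv->v", K, B)
                better = rss_i < best_rss
                best_rss[better] = rss_i[better]
                idx[better] = i
                best_k[better] = K.T[better]
            for v in range(n_vox):
                c, s = self.cands[idx[v]]
                k = best_k[v]
                amp = k[0] if abs(k[0]) > 1e-6 else (np.sign(k[0]) or 1.0) * 1e-6
                scales = np.clip(k[1:] / amp, *_SCALE_BOUNDS)
                x0[v, 0:4] = c
                x0[v, 4:8] = s
                x0[v, 8:11] = scales
                x0[v, 11:] = h0
                x0[v, -1] = h0[-1] * amp
            rss = best_rss
        else:  # unconstrained
            W = Y @ self.pinv.T  # (n_vox, 16)
            resid = Y - W @ self.X.T
            rss = np.einsum("vt,vt->v", resid, resid)
            idx = np.zeros(n_vox, dtype=int)
            x0[:, :16] = W
            x0[:, 16:] = h0
        return x0, np.maximum(rss, 0.0), idx


def grid_search_init(
    ts: np.ndarray,
    model_family: str,
    seq: StimulusSequence,
    hrf0: HRFParams | None = None,
    centers=(1.0, 2.0, 3.0, 4.0),
    sigmas=(0.5, 1.0, 2.0),
) -> tuple[np.ndarray, float, int]:
    """Coarse-lattice initialisation for one voxel.

    Returns the packed initial parameter vector, its residual sum of
    squares (with the optimal linear amplitude), and the lattice index.
    Ties resolve to the lowest lattice index.
    """
    ts = np.asarray(ts, dtype=float)
    if not np.isfinite(ts).all():
        raise ValueError("voxel time series contains non-finite values; skip voxel")
    gs = _GridSearcher(model_family, seq, hrf0 or HRFParams(), centers, sigmas)
    x0, rss, idx = gs.search(ts[None, :])
    return x0[0], float(rss[0]), int(idx[0])


# ---------------------------------------------------------------------------
# per-voxel nonlinear fit


@dataclass
class FitResult:
    """Best fit of one model family to one voxel."""

    model_family: str
    params: object  # spatial parameter dataclass
    hrf: HRFParams
    x: np.ndarray  # packed parameter vector
    rss: float
    r2: float
    adjusted_r2: float
    aic: float
    n_timepoints: int
    converged: bool
    init_index: int
    init_rss: float


def _fit_one(
    y: np.ndarray,
    family: str,
    predict,
    x0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    init_rss: float,
    init_index: int,
    ftol: float = 1e-8,
    xtol: float = 1e-8,
    max_nfev: int | None = None,
) -> FitResult:
    n = y.shape[0]
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

    def residuals(x):
        return predict(x) - y

    res = least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        method="trf",
        ftol=ftol,
        xtol=xtol,
        max_nfev=max_nfev,
        x_scale="jac",
    )
    converged = bool(res.status > 0)
    x = res.x if converged else x0
    rss = float(2 * res.cost) if converged else float(np.sum(residuals(x0) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else np.nan
    k = count_free_parameters(family)
    params, hrf = _unpack(family, x)
    return FitResult(
        model_family=family,
        params=params,
        hrf=hrf,
        x=x,
        rss=rss,
        r2=r2,
        adjusted_r2=adjusted_r2(r2, n, k) if ss_tot > 0 else np.nan,
        aic=aic(rss, n, k),
        n_timepoints=n,
        converged=converged,
        init_index=init_index,
        init_rss=init_rss,
    )


def fit_voxel(
    ts: np.ndarray,
    model_family: str,
    seq: StimulusSequence,
    init: np.ndarray | None = None,
    hrf0: HRFParams | None = None,
    ftol: float = 1e-8,
    xtol: float = 1e-8,
    max_nfev: int | None = None,
) -> FitResult:
    """Fit one model family to one voxel's preprocessed time series.

    If ``init`` is omitted a grid search supplies the starting point.  The
    final residual sum of squares never exceeds the initialisation's.
    """
    if model_family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {model_family!r}")
    ts = np.asarray(ts, dtype=float)
    if init is None:
        init, init_rss, init_index = grid_search_init(ts, model_family, seq, hrf0)
    else:
        init = np.asarray(init, dtype=float)
        init_index = -1
        init_rss = np.nan
    predict = _make_predictor(model_family, seq, 32.0)
    lo, hi = _family_bounds(model_family)
    if np.isnan(init_rss):
        init_rss = float(np.sum((predict(np.clip(init, lo + 1e-9, hi - 1e-9)) - ts) ** 2))
    return _fit_one(
        ts, model_family, predict, init, lo, hi, init_rss, init_index, ftol, xtol, max_nfev
    )


# ---------------------------------------------------------------------------
# estimator front end


class PRFEstimator(BaseEstimator):
    """Voxel-wise pRF model estimator (scikit-learn style).

    Parameters
    ----------
    seq : StimulusSequence
        Stimulus description the data were acquired under (possibly a
        concatenation of runs; convolution respects run boundaries).
    model : {"2d_gaussian", "1d_bd", "1d_wd", "unconstrained"}
    hrf0 : HRFParams, optional
        Canonical HRF used for the grid search and as the HRF starting
        point; all five HRF parameters are then fitted per voxel.
    centers_lattice, sigma_lattice : tuple of float
        Grid-search lattice over pRF centres (per axis) and sizes.
    ftol, xtol : float
        Relative convergence tolerances of the least-squares solver.
    max_nfev : int or None
        Cap on residual evaluations per voxel (None = solver default).

    Attributes
    ----------
    params_ : ndarray (n_voxels, n_params)
        Packed best-fit vectors (spatial params then 5 HRF params).
    rss_, r2_, adjusted_r2_, aic_ : ndarray (n_voxels,)
    converged_ : ndarray of bool
    init_index_, init_rss_ : grid-search provenance per voxel.
    """

    def __init__(
        self,
        seq: StimulusSequence | None = None,
        model: str = "2d_gaussian",
        hrf0: HRFParams | None = None,
        centers_lattice=(1.0, 2.0, 3.0, 4.0),
        sigma_lattice=(0.5, 1.0, 2.0),
        ftol: float = 1e-8,
        xtol: float = 1e-8,
        max_nfev: int | None = None,
    ):
        self.seq = seq
        self.model = model
        self.hrf0 = hrf0
        self.centers_lattice = centers_lattice
        self.sigma_lattice = sigma_lattice
        self.ftol = ftol
        self.xtol = xtol
        self.max_nfev = max_nfev

    def fit(self, X: np.ndarray, y=None) -> "PRFEstimator":
        """Fit every row of ``X`` (voxels x time, percent signal change)."""
        if self.seq is None:
            raise ValueError("PRFEstimator requires a stimulus sequence (seq=...)")
        if self.model not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.model!r}")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.seq.n_timepoints:
            raise ValueError(
                f"data has {X.shape[1]} time points, stimulus has {self.seq.n_timepoints}"
            )
        if not np.isfinite(X).all():
            raise ValueError("data contains non-finite values")
        hrf0 = self.hrf0 or HRFParams()
        searcher = _GridSearcher(
            self.model, self.seq, hrf0, self.centers_lattice, self.sigma_lattice
        )
        x0s, init_rss, init_idx = searcher.search(X)
        predict = _make_predictor(self.model, self.seq, 32.0)
        lo, hi = _family_bounds(self.model)
        n_vox = X.shape[0]
        results = [
            _fit_one(
                X[v],
                self.model,
                predict,
                x0s[v],
                lo,
                hi,
                float(init_rss[v]),
                int(init_idx[v]),
                self.ftol,
                self.xtol,
                self.max_nfev,
            )
            for v in range(n_vox)
        ]
        self.results_ = results
        self.params_ = np.array([r.x for r in results])
        self.rss_ = np.array([r.rss for r in results])
        self.r2_ = np.array([r.r2 for r in results])
        self.adjusted_r2_ = np.array([r.adjusted_r2 for r in results])
        self.aic_ = np.array([r.aic for r in results])
        self.converged_ = np.array([r.converged for r in results])
        self.init_index_ = np.array([r.init_index for r in results])
        self.init_rss_ = np.array([r.init_rss for r in results])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self) -> np.ndarray:
        """Predicted time courses of the fitted voxels (voxels x time)."""
        self._check_fitted()
        predict = _make_predictor(self.model, self.seq, 32.0)
        return np.array([predict(r.x) for r in self.results_])

    def score(self, X: np.ndarray, y=None) -> float:
        """Mean r^2 of the fitted predictions against ``X``."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        pred = self.predict()
        ss_res = np.sum((X - pred) ** 2, axis=1)
        ss_tot = np.sum((X - X.mean(axis=1, keepdims=True)) ** 2, axis=1)
        return float(np.mean(1.0 - ss_res / ss_tot))

    def results_frame(self):
        """Per-voxel results as a tidy :class:`pandas.DataFrame`."""
        import pandas as pd

        from .models import preferred_location

        self._check_fitted()
        rows = []
        for v, r in enumerate(self.results_):
            pref_d, pref_pd, size = preferred_location(r.params)
            sigma_d = sigma_pd = np.nan
            if self.model == "2d_gaussian":
                sigma_d, sigma_pd = size
            elif self.model == "1d_bd":
                sigma_d = size[0]
            elif self.model == "1d_wd":
                sigma_pd = size[0]
            rows.append(
                {
                    "voxel": v,
                    "model": self.model,
                    "preferred_digit": pref_d,
                    "preferred_pd": pref_pd,
                    "sigma_d": sigma_d,
                    "sigma_pd": sigma_pd,
                    "rss": r.rss,
                    "r2": r.r2,
                    "adjusted_r2": r.adjusted_r2,
                    "aic": r.aic,
                    "converged": r.converged,
                }
            )
        return pd.DataFrame(rows)

    def _check_fitted(self) -> None:
        if not hasattr(self, "results_"):
            raise RuntimeError("PRFEstimator is not fitted yet; call fit() first")
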
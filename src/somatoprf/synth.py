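"""Synthetic somatotopic patches and simulated fMRI sessions.

The generator is the forward model of the analysis run generatively: a
flat lattice of voxels carries ground-truth 2D Gaussian pRF parameters
with the qualitative structure of a somatosensory hand map — the
preferred digit d0 increases smoothly across one lattice axis (the D2->D5
gradient), while the preferred proximal-distal location pd0 runs tip->base
within each "area band" and mirrors at band borders (the base-to-tip
reversals that delineate the areal borders).  Bands emulate Brodmann-style
strips with band-specific pRF size multipliers (BA2-like bands wider than
BA3b-like), pRFs are elongated within-digit (sigma_pd > sigma_d), and
size drifts upward from D2 to D5 and from tip to base.

A simulated session predicts each voxel's percent-signal-change response
to the study's travelling-wave runs (between/within/diagonal, forward and
reverse), adds polynomial drift and white (optionally AR(1)) Gaussian
noise, and embeds the result on a raw-intensity baseline so that the
preprocessing chain (detrend, high-pass, PSC conversion) is exercised.
The noise level is parametrised by temporal SNR: noise sd in PSC units is
100 / tSNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, lfilter

from .evaluation import dice_coefficient, discretize_preferred
from .fitting import _hrf_kernel
from .grid import GridSpec, StimulusSequence, build_tw_sequence, concatenate_sequences
from .models import HRFParams, PRF2DParams, eval_weights

__all__ = [
    "GroundTruthPatch",
    "SimulationConfig",
    "SimulatedSession",
    "generate_patch",
    "simulate_session",
    "score_recovery",
    "STUDY_RUNS",
]

#: Study session layout: one forward+reverse between-digit pair, two
#: forward+reverse within-digit pairs, one diagonal run.
STUDY_RUNS: tuple[tuple[str, str], ...] = (
    ("between", "forward"),
    ("between", "reverse"),
    ("within", "forward"),
    ("within", "reverse"),
    ("within", "forward"),
    ("within", "reverse"),
    ("diagonal", "forward"),
)


@dataclass
class GroundTruthPatch:
    """Lattice of voxels with true pRF parameters (one subject)."""

    truth: pd.DataFrame  # voxel, row, col, d0, pd0, sigma_d, sigma_pd, ...
    shape: tuple[int, int]
    bands: tuple[str, ...]

    @property
    def n_voxels(self) -> int:
        return len(self.truth)


@dataclass
class SimulationConfig:
    """Session simulation settings (study protocol defaults)."""

    tr: float = 2.0
    s_on: float = 4.0
    n_cycles: int = 12
    runs: tuple[tuple[str, str], ...] = STUDY_RUNS
    hrf: HRFParams = field(default_factory=HRFParams)
    tsnr: float = 50.0  # noise sd in PSC units = 100 / tsnr
    ar1_rho: float = 0.0  # optional AR(1) coefficient of the noise
    drift_amplitude: float = 0.5  # peak-to-peak linear drift per run, PSC
    baseline: float | None = 1000.0  # raw baseline; None emits PSC directly
    seed: int = 0  # noise seed; ground truth is seed-independent


@dataclass
class SimulatedSession:
    """Simulated voxel data plus its stimulus description and ground truth."""

    data: np.ndarray  # (n_voxels, T) raw intensity
    seq: StimulusSequence  # concatenated session sequence
    run_info: list[tuple[str, str, tuple[int, int]]]  # paradigm, direction, rows
    truth: pd.DataFrame
    config: SimulationConfig

    def run_data(self, paradigm: str, direction: str | None = None) -> list[np.ndarray]:
        """Raw data slices of every run matching paradigm (and direction)."""
        return [
            self.data[:, a:b]
            for p, d, (a, b) in self.run_info
            if p == paradigm and (direction is None or d == direction)
        ]

    def run_slices(self, paradigm: str, direction: str | None = None) -> list[tuple[int, int]]:
        return [
            (a, b)
            for p, d, (a, b) in self.run_info
            if p == paradigm and (direction is None or d == direction)
        ]


def generate_patch(
    shape: tuple[int, int] = (40, 40),
    bands: tuple[str, ...] = ("3a", "3b", "1", "2"),
    band_sigma_scale: dict[str, float] | None = None,
    sigma_d_base: float = 0.8,
    elongation: float = 2.0,
    digit_size_slope: float = 0.15,
    pd_size_slope: float = 0.10,
    amplitude: float = 2.0,
    jitter: float = 0.05,
    subject: int = 0,
    seed: int = 0,
) -> GroundTruthPatch:
    """Ground-truth somatotopic patch on an ``nrows x ncols`` lattice.

    Columns carry the digit gradient (d0: 1 -> 4 = D2 -> D5); rows are
    split into ``len(bands)`` horizontal area bands, each with a tip->base
    pd0 gradient whose direction mirrors at every band border.  pRF sizes
    are ``sigma_d_base`` scaled per band (default: BA2-like band 1.3x the
    BA3b-like band), grow linearly with digit (``digit_size_slope`` per
    grid unit) and with PD location (``pd_size_slope``), and are elongated
    within-digit by ``elongation`` (sigma_pd = elongation * sigma_d).
    ``jitter`` adds seeded Gaussian scatter to centres (grid units); the
    patch is fully determined by its own ``seed`` (noise seeds used later
    do not change the ground truth).
    """
    band_sigma_scale = band_sigma_scale or {"3a": 0.9, "3b": 0.8, "1": 1.0, "2": 1.3}
    nrows, ncols = shape
    rng = np.random.default_rng(seed)
    d0_cols = np.linspace(1.0, 4.0, ncols)
    band_of_row = np.minimum((np.arange(nrows) * len(bands)) // nrows, len(bands) - 1)
    rows = []
    voxel = 0
    for i in range(nrows):
        b = int(band_of_row[i])
        in_band = np.nonzero(band_of_row == b)[0]
        frac = (i - in_band[0]) / max(len(in_band) - 1, 1)
        pd0 = 1.0 + 3.0 * (frac if b % 2 == 0 else 1.0 - frac)  # mirrored gradients
        for j in range(ncols):
            d0 = float(np.clip(d0_cols[j] + rng.normal(0, jitter), 0.6, 4.4))
            pd0_v = float(np.clip(pd0 + rng.normal(0, jitter), 0.6, 4.4))
            sd = (
                sigma_d_base
                * band_sigma_scale.get(bands[b], 1.0)
                * (1.0 + digit_size_slope * (d0 - 1.0))
                * (1.0 + pd_size_slope * (pd0_v - 1.0))
            )
            rows.append(
                {
                    "voxel": voxel,
                    "row": i,
                    "col": j,
                    "d0": d0,
                    "pd0": pd0_v,
                    "sigma_d": sd,
                    "sigma_pd": elongation * sd,
                    "amplitude": amplitude,
                    "area": bands[b],
                    "digit": int(discretize_preferred(d0)),
                    "pd": int(discretize_preferred(pd0_v)),
                    "subject": subject,
                }
            )
            voxel += 1
    return GroundTruthPatch(truth=pd.DataFrame(rows), shape=shape, bands=bands)


def _session_sequences(config: SimulationConfig, grid: GridSpec):
    seqs = [
        build_tw_sequence(p, d, config.n_cycles, config.s_on, config.tr, grid)
        for p, d in config.runs
    ]
    session = concatenate_sequences(seqs)
    info = []
    offset = 0
    for (p, d), s in zip(config.runs, seqs):
        info.append((p, d, (offset, offset + s.n_timepoints)))
        offset += s.n_timepoints
    return session, info


def simulate_session(
    patch: GroundTruthPatch, config: SimulationConfig | None = None
) -> SimulatedSession:
    """Simulate raw voxel time series for one session.

    Per voxel the percent-signal-change response is the truth pRF's
    predicted time course (run-wise HRF convolution), plus a linear drift
    per run and Gaussian noise (white, or AR(1) when ``ar1_rho`` > 0),
    embedded on the raw baseline:
    ``raw = baseline * (1 + (psc + drift + noise) / 100)``.
    """
    config = config or SimulationConfig()
    grid = GridSpec()
    session, run_info = _session_sequences(config, grid)
    truth = patch.truth
    n_vox = len(truth)
    W = np.array(
        [
            eval_weights(
                PRF2DParams(r.d0, r.pd0, r.sigma_d, r.sigma_pd), grid
            ).ravel()
            * r.amplitude
            for r in truth.itertuples()
        ]
    )
    hrf = config.hrf
    kernel = _hrf_kernel(hrf.as_array(), config.tr, 32.0)
    rng = np.random.default_rng(config.seed)
    T = session.n_timepoints
    psc = np.empty((n_vox, T))
    for _, _, (a, b) in run_info:
        neural = W @ session.matrix[a:b].T.astype(float)
        psc[:, a:b] = fftconvolve(neural, kernel[None, :], axes=1)[:, : b - a]
        psc[:, a:b] += config.drift_amplitude * np.linspace(-0.5, 0.5, b - a)[None, :]
    noise_sd = 100.0 / config.tsnr if config.tsnr and np.isfinite(config.tsnr) else 0.0
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n_vox, T))
        if config.ar1_rho:
            rho = config.ar1_rho
            noise = lfilter([np.sqrt(1 - rho**2)], [1.0, -rho], noise, axis=1)
        psc = psc + noise
    if config.baseline is None:
        data = psc  # percent-signal-change units, no raw embedding
    else:
        data = config.baseline * (1.0 + psc / 100.0)
    return SimulatedSession(
        data=data, seq=session, run_info=run_info, truth=truth, config=config
    )


def score_recovery(truth: pd.DataFrame, fit_table: pd.DataFrame) -> dict:
    """Parameter-recovery metrics of a fit table against the ground truth.

    Joins on ``voxel`` and reports, per parameter present in both tables
    (d0/pd0 vs preferred_digit/preferred_pd, sigma_d, sigma_pd): bias
    (estimate - truth), RMSE, and Pearson correlation; plus the Dice
    overlap (averaged over the 4 labels) of the discretised digit and PD
    label maps.
    """
    pairs = {
        "d0": "preferred_digit",
        "pd0": "preferred_pd",
        "sigma_d": "sigma_d",
        "sigma_pd": "sigma_pd",
    }
    merged = truth.merge(fit_table, on="voxel", suffixes=("_true", "_est"))
    if merged.empty:
        raise ValueError("truth and fit tables share no voxels")

    def resolve(col: str, side: str) -> str | None:
        """Column name in the merged frame, or None if that side lacks it."""
        src = truth if side == "true" else fit_table
        if col not in src.columns:
            return None
        return f"{col}_{side}" if f"{col}_{side}" in merged.columns else col

    out: dict = {}
    for t_col, e_col in pairs.items():
        t_name = resolve(t_col, "true")
        e_name = resolve(e_col, "est")
        if t_name is None or e_name is None:
            continue
        t = merged[t_name].to_numpy(dtype=float)
        e = merged[e_name].to_numpy(dtype=float)
        ok = np.isfinite(t) & np.isfinite(e)
        if not ok.any():
            continue
        t, e = t[ok], e[ok]
        err = e - t
        corr = float(np.corrcoef(t, e)[0, 1]) if np.std(t) > 0 and np.std(e) > 0 else np.nan
        out[t_col] = {
            "bias": float(err.mean()),
            "rmse": float(np.sqrt(np.mean(err**2))),
            "median_abs_error": float(np.median(np.abs(err))),
            "correlation": corr,
        }
    if "sigma_d" in out and "sigma_pd" in out:
        # pooled size correlation across both axes (the overall sigma recovery)
        t_pool, e_pool = [], []
        for col in ("sigma_d", "sigma_pd"):
            t = merged[resolve(col, "true")].to_numpy(float)
            e = merged[resolve(col, "est")].to_numpy(float)
            ok = np.isfinite(t) & np.isfinite(e)
            t_pool.append(t[ok])
            e_pool.append(e[ok])
        t_pool = np.concatenate(t_pool)
        e_pool = np.concatenate(e_pool)
        out["sigma_pooled_correlation"] = float(np.corrcoef(t_pool, e_pool)[0, 1])
    for axis, (t_col, e_col) in {
        "digit": ("d0", "preferred_digit"),
        "pd": ("pd0", "preferred_pd"),
    }.items():
        t_name = resolve(t_col, "true")
        e_name = resolve(e_col, "est")
        if t_name is None or e_name is None:
            continue
        lt = discretize_preferred(merged[t_name].to_numpy(dtype=float))
        le = discretize_preferred(merged[e_name].to_numpy(dtype=float))
        dices = [dice_coefficient(lt, le, v) for v in (1, 2, 3, 4)]
        out[f"dice_{axis}"] = float(np.nanmean(dices))
    return out
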
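"""Population receptive field (pRF) model families and BOLD prediction.

Four model families describe the weight a voxel's population receptive
field assigns to each of the 16 stimulation sites:

* ``2d_gaussian``  - a single separable 2D Gaussian over (digit, pd) space,

  .. math::

     w(d_i, pd_i) = \\exp\\!\\left[-\\left(
         \\frac{(d_0-d_i)^2}{2\\sigma_d^2} +
         \\frac{(pd_0-pd_i)^2}{2\\sigma_{pd}^2}\\right)\\right]

* ``1d_bd`` - four independent, separately scaled 1D Gaussians over digits,
  one per PD row: ``g(d)_pd = k_pd exp[-(d0_pd - d_i)^2 / (2 sigma_pd^2)]``
  with the PD1 row's scale fixed to 1,
* ``1d_wd`` - the orthogonal construction, one Gaussian over PD per digit,
  with digit D2's scale fixed to 1,
* ``unconstrained`` - one free weight per site, no shape assumption; it
  serves as the fit ceiling (pRF size is undefined for it).

Predicted BOLD responses are the dot product of the weight grid with the
binary stimulus description, convolved with a 5-parameter double-gamma
haemodynamic response function (HRF); convolution never crosses run
boundaries.  Every family carries the 5 HRF parameters in addition to its
spatial parameters, giving the free-parameter totals 9 (2D Gaussian),
16 (each 1D Gaussian) and 21 (unconstrained).

pRF size is reported as the Gaussian standard deviation sigma in grid
units; the equivalent full width at half maximum is FWHM = 2 sqrt(2 ln 2)
sigma ~= 2.355 sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .grid import GridSpec, StimulusSequence

__all__ = [
    "FWHM_PER_SIGMA",
    "CENTER_BOUNDS",
    "SIGMA_BOUNDS",
    "MODEL_FAMILIES",
    "HRFParams",
    "PRF2DParams",
    "PRF1DBDParams",
    "PRF1DWDParams",
    "UnconstrainedWeights",
    "eval_weights",
    "preferred_location",
    "evaluate_hrf",
    "predict_timecourse",
    "count_free_parameters",
]

#: FWHM of a Gaussian per unit standard deviation, 2*sqrt(2*ln 2) ~= 2.355.
FWHM_PER_SIGMA: float = float(2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Allowed range for pRF centres, grid units (half a unit beyond the grid).
CENTER_BOUNDS: tuple[float, float] = (0.5, 4.5)

#: Allowed range for pRF sizes sigma, grid units (guards degenerate fits).
SIGMA_BOUNDS: tuple[float, float] = (0.1, 10.0)

MODEL_FAMILIES = ("2d_gaussian", "1d_bd", "1d_wd", "unconstrained")

N_HRF_PARAMS = 5


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma haemodynamic response function parameters.

    The kernel is the difference of two gamma densities sharing one
    dispersion, peak-normalised so that ``amplitude`` is the kernel
    maximum (in percent-signal-change units per unit neural drive).
    """

    peak_delay: float = 6.0  # s, time-to-peak of the positive lobe
    undershoot_delay: float = 16.0  # s, time-to-trough of the undershoot
    dispersion: float = 1.0  # s, width of both gamma lobes
    ratio: float = 6.0  # peak:undershoot amplitude ratio
    amplitude: float = 1.0  # kernel peak height

    def __post_init__(self) -> None:
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("HRF delays must be positive")
        if self.dispersion <= 0:
            raise ValueError("HRF dispersion must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("HRF amplitude must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.peak_delay, self.undershoot_delay, self.dispersion, self.ratio, self.amplitude]
        )

    @classmethod
    def from_array(cls, x) -> "HRFParams":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class PRF2DParams:
    """Separable 2D Gaussian pRF: centre (d0, pd0) and sizes per axis."""

    d0: float
    pd0: float
    sigma_d: float
    sigma_pd: float

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.sigma_pd <= 0:
            raise ValueError("pRF sizes sigma must be positive")


@dataclass(frozen=True)
class PRF1DBDParams:
    """Four scaled 1D Gaussians over digits, one per PD row (BD model).

    ``scales[0]`` (the PD1 row) is the reference and must equal 1.
    """

    centers: tuple[float, float, float, float]
    sigmas: tuple[float, float, float, float]
    scales: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("pRF sizes sigma must be positive")
        if abs(self.scales[0] - 1.0) > 1e-12:
            raise ValueError("reference scale (PD1 row) must be fixed to 1")


@dataclass(frozen=True)
class PRF1DWDParams:
    """Four scaled 1D Gaussians over PD, one per digit (WD model).

    ``scales[0]`` (digit D2) is the reference and must equal 1.
    """

    centers: tuple[float, float, float, float]
    sigmas: tuple[float, float, float, float]
    scales: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("pRF sizes sigma must be positive")
        if abs(self.scales[0] - 1.0) > 1e-12:
            raise ValueError("reference scale (digit D2) must be fixed to 1")


@dataclass(frozen=True)
class UnconstrainedWeights:
    """One free weight per stimulation site (fit-ceiling model)."""

    weights: tuple = field(default=tuple(0.0 for _ in range(16)))

    def __post_init__(self) -> None:
        if len(self.weights) != 16:
            raise ValueError("unconstrained model needs exactly 16 weights")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


def eval_weights(model_params, grid: GridSpec | None = None) -> np.ndarray:
    """Evaluate a pRF model's site weights on the grid.

    Returns a (n_digits, n_pd) array indexed ``[d-1, pd-1]``; its C-order
    flattening matches the site linear index convention.
    """
    grid = grid or GridSpec()
    d = np.arange(1, grid.n_digits + 1, dtype=float)[:, None]
    pd = np.arange(1, grid.n_pd + 1, dtype=float)[None, :]
    if isinstance(model_params, PRF2DParams):
        p = model_params
        return np.exp(
            -(
                (p.d0 - d) ** 2 / (2.0 * p.sigma_d**2)
                + (p.pd0 - pd) ** 2 / (2.0 * p.sigma_pd**2)
            )
        )
    if isinstance(model_params, PRF1DBDParams):
        p = model_params
        w = np.empty((grid.n_digits, grid.n_pd))
        for j in range(grid.n_pd):  # one Gaussian over digits per PD row
            w[:, j] = p.scales[j] * np.exp(
                -((p.centers[j] - d[:, 0]) ** 2) / (2.0 * p.sigmas[j] ** 2)
            )
        return w
    if isinstance(model_params, PRF1DWDParams):
        p = model_params
        w = np.empty((grid.n_digits, grid.n_pd))
        for i in range(grid.n_digits):  # one Gaussian over PD per digit
            w[i, :] = p.scales[i] * np.exp(
                -((p.centers[i] - pd[0, :]) ** 2) / (2.0 * p.sigmas[i] ** 2)
            )
        return w
    if isinstance(model_params, UnconstrainedWeights):
        return np.asarray(model_params.weights, dtype=float).reshape(
            grid.n_digits, grid.n_pd
        )
    raise TypeError(f"unknown pRF model parameters: {type(model_params).__name__}")


def preferred_location(model_params) -> tuple[float, float, tuple | None]:
    """Preferred (digit, pd) location and pRF size of a fitted model.

    For the 1D families, the profile with the maximal scale identifies the
    preferred location on the non-modelled axis; the peak of that profile
    gives the location on the modelled axis along with its size sigma.
    Ties in the maximal scale break towards the lowest index (warned).
    The unconstrained model returns its argmax site; size is ``None``.

    Returns
    -------
    (preferred_digit, preferred_pd, size) where size is ``(sigma_d, sigma_pd)``
    for the 2D model, ``(sigma,)`` for 1D models, and ``None`` for the
    unconstrained model.
    """
    if isinstance(model_params, PRF2DParams):
        p = model_params
        return p.d0, p.pd0, (p.sigma_d, p.sigma_pd)
    if isinstance(model_params, (PRF1DBDParams, PRF1DWDParams)):
        p = model_params
        scales = np.asarray(p.scales)
        best = int(np.argmax(scales))
        if np.sum(scales == scales[best]) > 1:
            warnings.warn(
                "tie in maximal profile scale; taking the lowest index", stacklevel=2
            )
        if isinstance(model_params, PRF1DBDParams):
            # best PD row; peak over digits in that row
            return float(p.centers[best]), float(best + 1), (float(p.sigmas[best]),)
        return float(best + 1), float(p.centers[best]), (float(p.sigmas[best]),)
    if isinstance(model_params, UnconstrainedWeights):
        w = np.asarray(model_params.weights).reshape(4, 4)
        i, j = np.unravel_index(int(np.argmax(w)), w.shape)
        return float(i + 1), float(j + 1), None
    raise TypeError(f"unknown pRF model parameters: {type(model_params).__name__}")


def evaluate_hrf(hrf: HRFParams, tr: float, duration: float = 32.0) -> np.ndarray:
    """Sample the double-gamma HRF kernel at the TR.

    The kernel has ``floor(duration/tr) + 1`` samples starting at t = 0 and
    is normalised so its (densely evaluated) peak equals ``hrf.amplitude``;
    the amplitude parameter therefore scales the kernel linearly.
    """
    if duration < tr:
        raise ValueError("HRF duration must be at least one TR")
    if hrf.dispersion <= 0:
        raise ValueError("HRF dispersion must be positive")
    n = int(np.floor(duration / tr)) + 1
    t = np.arange(n) * tr

    def shape(tt):
        a1 = hrf.peak_delay / hrf.dispersion
        a2 = hrf.undershoot_delay / hrf.dispersion
        return gamma_dist.pdf(tt, a1, scale=hrf.dispersion) - gamma_dist.pdf(
            tt, a2, scale=hrf.dispersion
        ) / hrf.ratio

    # peak-normalise on a dense grid so amplitude has PSC units and the
    # kernel varies smoothly with the delay/dispersion parameters
    dense = np.arange(0.0, duration + 1e-9, min(tr, 0.1))
    peak = float(np.max(shape(dense)))
    if peak <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return hrf.amplitude * shape(t) / peak


def predict_timecourse(
    model_params,
    hrf: HRFParams,
    seq: StimulusSequence,
    hrf_duration: float = 32.0,
) -> np.ndarray:
    """Predicted BOLD time course (percent signal change) for one voxel.

    The neural drive at each volume is the dot product of the pRF weight
    grid with the stimulus row; the drive is convolved with the HRF kernel
    independently within each run so haemodynamic blurring never crosses a
    run boundary.  Output length equals the stimulus length.
    """
    w = eval_weights(model_params, seq.grid).ravel()
    if w.shape[0] != seq.matrix.shape[1]:
        raise ValueError("pRF weight grid does not match stimulus site count")
    neural = seq.matrix @ w
    kernel = evaluate_hrf(hrf, seq.tr, hrf_duration)
    out = np.empty_like(neural, dtype=float)
    for start, stop in seq.run_boundaries:
        out[start:stop] = np.convolve(neural[start:stop], kernel)[: stop - start]
    return out


def count_free_parameters(model_family: str) -> int:
    """Total fitted parameters of a family, including the 5 HRF parameters.

    2D Gaussian: 4 spatial + 5 HRF = 9.  Each 1D Gaussian: 4 centres +
    4 sigmas + 3 free scales + 5 HRF = 16.  Unconstrained: 16 weights +
    5 HRF = 21.
    """
    spatial = {"2d_gaussian": 4, "1d_bd": 11, "1d_wd": 11, "unconstrained": 16}
    if model_family not in spatial:
        raise ValueError(
            f"unknown model family {model_family!r}; expected one of {MODEL_FAMILIES}"
        )
    return spatial[model_family] + N_HRF_PARAMS
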
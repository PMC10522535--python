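"""ROI-level pRF coverage maps: upsample, extrapolate, PCA-average, align.

A coverage map visualises the aggregate "area of influence" that an ROI's
voxel pRFs exert over sensory (digit x proximal-distal) space.  Each
voxel's fitted weight grid lives on the native 4 x 4 stimulation lattice;
the chain implemented here is

1. smooth interpolation of the 4 x 4 grid to 20 x 20 samples,
2. extrapolation to a 60 x 60 frame by solving the discrete Laplace
   equation outside the known block (Dirichlet data inside, zero-flux at
   the frame edge) to recover the "full" pRF shape,
3. a principal-component summary across voxels: the maps are flattened,
   mean-centred, and the first 3 components (typically ~90% of variance)
   reconstruct each voxel's map; subject-wise reconstructions are averaged
   with equal subject weight so no subject dominates,
4. optional peak alignment: each map is integer-shifted so its peak lands
   on the frame centre along the chosen axis before averaging, which
   summarises pRF *shape* irrespective of position in sensory space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RectBivariateSpline
from scipy.sparse.linalg import spsolve
from sklearn.decomposition import PCA

from .models import eval_weights

__all__ = [
    "CoverageMap",
    "CoverageMapper",
    "upsample_grid",
    "extrapolate_pde",
    "pca_average",
    "peak_align",
    "map_width",
]


@dataclass
class CoverageMap:
    """Coverage of sensory space for one ROI at the three resolutions."""

    native: np.ndarray  # 4 x 4
    upsampled: np.ndarray  # 20 x 20
    extrapolated: np.ndarray  # 60 x 60
    peak: tuple[int, int]  # argmax of the extrapolated field
    roi: str = ""


def upsample_grid(native: np.ndarray, size: int = 20, mode: str = "bicubic") -> np.ndarray:
    """Interpolate the native 4 x 4 weight grid onto a ``size x size`` grid.

    Samples cover the convex hull of the native lattice, so the native
    corner values are reproduced at the output corners, and (for an
    interpolating spline) all native lattice values are reproduced at
    their sample positions.
    """
    native = np.asarray(native, dtype=float)
    if not np.isfinite(native).all():
        raise ValueError("native grid contains non-finite values")
    n0, n1 = native.shape
    k = {"bicubic": 3, "bilinear": 1}[mode]
    spline = RectBivariateSpline(
        np.arange(n0), np.arange(n1), native, kx=min(k, n0 - 1), ky=min(k, n1 - 1)
    )
    return spline(np.linspace(0, n0 - 1, size), np.linspace(0, n1 - 1, size))


def extrapolate_pde(
    known: np.ndarray, frame: int = 60, tol: float = 1e-8
) -> np.ndarray:
    """Embed a known block centred in a ``frame x frame`` grid and fill the
    surround by solving the discrete Laplace equation.

    Known cells act as Dirichlet data; at the outer frame edge the 5-point
    stencil simply drops missing neighbours (zero-flux).  By the maximum
    principle the filled values stay within [min, max] of the known data.
    """
    known = np.asarray(known, dtype=float)
    h, w = known.shape
    if h > frame or w > frame:
        raise ValueError("known block larger than the target frame")
    r0, c0 = (frame - h) // 2, (frame - w) // 2
    out = np.full((frame, frame), np.nan)
    out[r0 : r0 + h, c0 : c0 + w] = known
    unknown = np.isnan(out)
    if not unknown.any():
        return out
    idx = -np.ones((frame, frame), dtype=int)
    idx[unknown] = np.arange(unknown.sum())
    rows, cols, vals = [], [], []
    rhs = np.zeros(unknown.sum())
    ui, uj = np.nonzero(unknown)
    for r, i, j in zip(range(unknown.sum()), ui, uj):
        neighbours = [
            (i + di, j + dj)
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1))
            if 0 <= i + di < frame and 0 <= j + dj < frame
        ]
        rows.append(r)
        cols.append(r)
        vals.append(float(len(neighbours)))
        for ni, nj in neighbours:
            if unknown[ni, nj]:
                rows.append(r)
                cols.append(idx[ni, nj])
                vals.append(-1.0)
            else:
                rhs[r] += out[ni, nj]
    A = sp.csr_matrix((vals, (rows, cols)), shape=(len(rhs), len(rhs)))
    sol = spsolve(A, rhs)
    resid = np.abs(A @ sol - rhs).max()
    if resid > tol:
        raise RuntimeError(f"Laplace solve residual {resid:.2e} exceeds {tol:.0e}")
    out[unknown] = sol
    return out


def pca_average(
    maps: np.ndarray,
    subject_ids,
    n_components: int = 3,
    mode: str = "pooled",
) -> tuple[np.ndarray, np.ndarray]:
    """PCA-summarised average coverage map across an ROI's voxels.

    ``maps`` is (n_voxels, H, W); ``subject_ids`` assigns each voxel map to
    a subject.  With ``mode="pooled"`` (default) one PCA is computed across
    all voxels; each subject's maps are projected onto the first
    ``n_components`` components, reconstructed, averaged within subject,
    and the subject averages are averaged with equal weight.  With
    ``mode="per_subject"`` the PCA is computed within each subject before
    reconstruction.  Returns (average map, explained variance ratio).
    """
    maps = np.asarray(maps, dtype=float)
    n_vox, H, W = maps.shape
    subject_ids = np.asarray(subject_ids)
    if subject_ids.shape[0] != n_vox:
        raise ValueError("one subject id per voxel map required")
    flat = maps.reshape(n_vox, -1)

    def reconstruct(block: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        k_eff = min(k, block.shape[0], block.shape[1])
        if k_eff < k:
            warnings.warn(
                f"fewer maps than components; reducing to {k_eff}", stacklevel=3
            )
        pca = PCA(n_components=k_eff)
        scores = pca.fit_transform(block)
        recon = pca.inverse_transform(scores)
        return recon, pca.explained_variance_ratio_

    if mode == "pooled":
        recon, evr = reconstruct(flat, n_components)
        subj_means = [
            recon[subject_ids == s].mean(axis=0) for s in np.unique(subject_ids)
        ]
    elif mode == "per_subject":
        subj_means, evrs = [], []
        for s in np.unique(subject_ids):
            rec, e = reconstruct(flat[subject_ids == s], n_components)
            subj_means.append(rec.mean(axis=0))
            evrs.append(e)
        evr = np.mean([e[: min(map(len, evrs))] for e in evrs], axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    avg = np.mean(subj_means, axis=0).reshape(H, W)
    return avg, evr


def peak_align(maps: np.ndarray, axis: str = "both") -> np.ndarray:
    """Average maps after integer-shifting each one's peak to the centre.

    ``axis`` selects the alignment direction: "digit" shifts along columns
    (axis 1), "pd" along rows (axis 0), "both" along both.  Shifts are
    integer translations (no resampling); cells shifted out of frame are
    dropped and the average is count-normalised over in-frame cells.
    Flat maps (no unique peak) are excluded with a warning.
    """
    maps = np.asarray(maps, dtype=float)
    n, H, W = maps.shape
    centre = (H // 2, W // 2)
    acc = np.zeros((H, W))
    cnt = np.zeros((H, W))
    for m in maps:
        if np.ptp(m) == 0:
            warnings.warn("flat coverage map excluded from peak alignment", stacklevel=2)
            continue
        pi, pj = np.unravel_index(int(np.argmax(m)), m.shape)
        di = centre[0] - pi if axis in ("pd", "both") else 0
        dj = centre[1] - pj if axis in ("digit", "both") else 0
        src_i = slice(max(0, -di), min(H, H - di))
        src_j = slice(max(0, -dj), min(W, W - dj))
        dst_i = slice(max(0, di), min(H, H + di))
        dst_j = slice(max(0, dj), min(W, W + dj))
        acc[dst_i, dst_j] += m[src_i, src_j]
        cnt[dst_i, dst_j] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


def map_width(coverage: np.ndarray) -> float:
    """RMS second-moment width of a (non-negative) coverage map, frame units."""
    m = np.nan_to_num(np.asarray(coverage, dtype=float))
    m = m - m.min()
    total = m.sum()
    if total <= 0:
        return float("nan")
    H, W = m.shape
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    ci = (m * ii).sum() / total
    cj = (m * jj).sum() / total
    var = (m * ((ii - ci) ** 2 + (jj - cj) ** 2)).sum() / total
    return float(np.sqrt(var))


class CoverageMapper:
    """Build coverage maps from fitted voxel pRF parameters.

    Parameters
    ----------
    upsample_size, frame : int
        Intermediate (default 20) and final (default 60) grid sizes.
    n_components : int
        PCA components kept in the across-voxel summary.
    pca_mode : {"pooled", "per_subject"}
    """

    def __init__(
        self,
        upsample_size: int = 20,
        frame: int = 60,
        n_components: int = 3,
        pca_mode: str = "pooled",
        interp_mode: str = "bicubic",
    ):
        self.upsample_size = upsample_size
        self.frame = frame
        self.n_components = n_components
        self.pca_mode = pca_mode
        self.interp_mode = interp_mode

    def voxel_map(self, model_params) -> np.ndarray:
        """Native 4x4 -> extrapolated frame for one voxel's fitted pRF."""
        native = eval_weights(model_params)
        up = upsample_grid(native, self.upsample_size, self.interp_mode)
        return extrapolate_pde(up, self.frame)

    def roi_map(
        self, params_list, subject_ids, roi: str = ""
    ) -> tuple[CoverageMap, np.ndarray]:
        """PCA-averaged coverage map of an ROI's voxels.

        Returns the :class:`CoverageMap` (native/upsampled/extrapolated at
        the ROI-average level) and the PCA explained-variance ratio.
        """
        vox_maps = np.array([self.voxel_map(p) for p in params_list])
        avg, evr = pca_average(vox_maps, subject_ids, self.n_components, self.pca_mode)
        natives = np.mean([eval_weights(p) for p in params_list], axis=0)
        up = upsample_grid(natives, self.upsample_size, self.interp_mode)
        peak = np.unravel_index(int(np.argmax(avg)), avg.shape)
        return (
            CoverageMap(
                native=natives,
                upsampled=up,
                extrapolated=avg,
                peak=(int(peak[0]), int(peak[1])),
                roi=roi,
            ),
            evr,
        )
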
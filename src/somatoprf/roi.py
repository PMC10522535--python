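"""ROI aggregation of pRF sizes and volumes, with group comparisons.

Voxels are aggregated into 16 sites per scheme: functionally by preferred
proximal-distal location x digit, or anatomically by area band x digit
(Brodmann-style strips in the synthetic patches).  Sizes are summarised
subject-wise (the subject is the observational unit), then compared across
ROIs with a one-way ANOVA followed by Tukey's HSD.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["aggregate_prf_size", "roi_volume", "compare_groups"]

#: volume of one voxel at the study's 1.25 mm isotropic resolution, mm^3
DEFAULT_VOXEL_VOLUME_MM3 = 1.25**3


def aggregate_prf_size(
    fit_table: pd.DataFrame,
    labels: pd.DataFrame,
    scheme: str = "pd",
    adjusted_r2_threshold: float = 0.0,
) -> pd.DataFrame:
    """Subject-wise ROI means of pRF size (sigma_d, sigma_pd).

    ``fit_table`` needs columns ``voxel, sigma_d, sigma_pd, adjusted_r2``;
    ``labels`` needs ``voxel, digit, pd, area, subject``.  ``scheme`` picks
    the 16-site partition: "pd" (digit x proximal-distal location) or
    "area" (digit x area band).  Voxels at adjusted r^2 <= threshold are
    dropped; empty ROIs are omitted with a warning.
    """
    if scheme not in ("pd", "area"):
        raise ValueError(f"unknown aggregation scheme {scheme!r}")
    df = fit_table.merge(labels, on="voxel")
    df = df[df["adjusted_r2"] > adjusted_r2_threshold]
    key = "pd" if scheme == "pd" else "area"
    grouped = (
        df.groupby(["subject", "digit", key], observed=True)[["sigma_d", "sigma_pd"]]
        .mean()
        .reset_index()
    )
    grouped["roi"] = (
        grouped[key].astype(str) + "_D" + (grouped["digit"].astype(int) + 1).astype(str)
    )
    n_rois = labels[key].nunique() * labels["digit"].nunique()
    if grouped["roi"].nunique() < n_rois:
        warnings.warn("some ROIs contain no surviving voxels and were omitted", stacklevel=2)
    return grouped


def roi_volume(
    labels: pd.DataFrame,
    voxel_volume: float = DEFAULT_VOXEL_VOLUME_MM3,
    scheme: str = "area",
) -> pd.DataFrame:
    """Per-ROI volume in mm^3 (voxel count x voxel volume)."""
    if voxel_volume <= 0:
        raise ValueError("voxel volume must be positive")
    key = "pd" if scheme == "pd" else "area"
    counts = labels.groupby([key, "digit"], observed=True).size().rename("n_voxels")
    out = counts.reset_index()
    out["volume_mm3"] = out["n_voxels"] * voxel_volume
    return out


def compare_groups(values_by_group: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA plus Tukey HSD pairwise comparisons.

    ``values_by_group`` maps group name -> per-subject ROI values.
    Returns a dict with keys ``F``, ``p``, ``tukey`` (a DataFrame of
    pairwise adjusted p-values and mean differences) and ``degenerate``
    (True when within-group variance is zero everywhere).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least two values per group")
    arrays = list(groups.values())
    degenerate = all(np.ptp(a) == 0 for a in arrays)
    if degenerate and len({a[0] for a in arrays}) == 1:
        F, p = 0.0, 1.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            F, p = stats.f_oneway(*arrays)
        F = float(F)
        p = float(p)
    data = np.concatenate(arrays)
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    tukey = pairwise_tukeyhsd(data, labels)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    return {"F": F, "p": p, "tukey": tukey_df, "degenerate": degenerate}
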
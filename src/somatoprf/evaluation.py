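"""Comparison of pRF maps against travelling-wave maps and across families.

Two quantitative comparisons are provided: the Dice coefficient between
discrete location label maps (how often the travelling-wave and pRF
analyses assign a voxel to the same digit / proximal-distal site), and a
pairwise AIC preference matrix (the percentage of voxels for which one
model family attains a lower AIC than another).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dice_coefficient",
    "dice_matrix",
    "aic_preference_matrix",
    "discretize_preferred",
]


def dice_coefficient(labels_a, labels_b, label_value) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of the voxels carrying one label.

    Returns NaN when neither map contains the label.
    """
    a = np.asarray(labels_a) == label_value
    b = np.asarray(labels_b) == label_value
    if a.shape != b.shape:
        raise ValueError("label maps must cover the same voxel set")
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return 2.0 * np.logical_and(a, b).sum() / denom


def dice_matrix(labels_a, labels_b, n_labels: int = 4) -> np.ndarray:
    """Full label-pair Dice matrix; entry (i, j) compares label i+1 of map A
    with label j+1 of map B."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    out = np.empty((n_labels, n_labels))
    for i in range(n_labels):
        for j in range(n_labels):
            sa = a == i + 1
            sb = b == j + 1
            denom = sa.sum() + sb.sum()
            out[i, j] = np.nan if denom == 0 else 2.0 * np.logical_and(sa, sb).sum() / denom
    return out


def discretize_preferred(preferred, n_labels: int = 4) -> np.ndarray:
    """Continuous preferred location (grid units) -> discrete label 1..n.

    Rounds to the nearest integer grid unit and clips to the grid.
    """
    return np.clip(np.rint(np.asarray(preferred, dtype=float)), 1, n_labels).astype(int)


def aic_preference_matrix(aic_by_family: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Pairwise model-preference percentages from per-voxel AIC scores.

    Entry (A, B) is the percentage of voxels where family A's AIC is lower
    than family B's; ties contribute half to each side, so
    P(A, B) + P(B, A) = 100 and the diagonal is 50 by convention.

    Returns the matrix and the family order (dict insertion order).
    """
    families = list(aic_by_family)
    arrays = [np.asarray(aic_by_family[f], dtype=float) for f in families]
    n = arrays[0].shape[0]
    for arr in arrays:
        if arr.shape[0] != n:
            raise ValueError("all families must score the same voxel set")
    m = len(families)
    out = np.full((m, m), 50.0)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            wins = np.sum(arrays[i] < arrays[j]) + 0.5 * np.sum(arrays[i] == arrays[j])
            out[i, j] = 100.0 * wins / n
    return out, families
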
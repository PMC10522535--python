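"""Flat-file input/output: TSV tables, TSV matrices, NIfTI volumes."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "write_matrix",
    "read_matrix",
    "write_nifti",
    "read_nifti",
]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: np.ndarray, path, fmt: str = "%.8g") -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt=fmt)


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def write_nifti(volume: np.ndarray, path, voxel_size_mm: float = 1.25) -> None:
    """Write a 3D/4D array as NIfTI with an isotropic affine."""
    import nibabel as nib

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def read_nifti(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata())
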
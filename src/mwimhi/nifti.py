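"""NIfTI reading/writing helpers with alignment and mask-dialect checks.

All volumes belonging to one subject must share grid shape and affine; the
pipeline performs no resampling and refuses misaligned inputs rather than
silently interpolating.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_nifti", "write_nifti", "read_mask", "check_aligned"]

AFFINE_ATOL = 1e-6


def read_nifti(path: str | Path, expect_ndim: int | None = None):
    """Load a NIfTI volume; returns ``(data, affine)`` with float data.

    ``expect_ndim`` enforces dimensionality (e.g. 4 for multi-echo input)
    with a clear error message.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if expect_ndim is not None and data.ndim != expect_ndim:
        raise ValueError(
            f"{path}: expected a {expect_ndim}D volume, got {data.ndim}D "
            f"with shape {data.shape}"
        )
    return data, img.affine


def write_nifti(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a volume as float32 NIfTI, preserving the given affine."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_mask(path: str | Path, reference_shape=None, reference_affine=None) -> np.ndarray:
    """Load a 3D mask, binarizing at > 0.5.

    Warns when the file is not already binary (e.g. {0, 255} dialects or
    interpolated atlas masks); optionally checks grid alignment against a
    reference volume.
    """
    data, affine = read_nifti(path, expect_ndim=3)
    values = np.unique(data)
    if not np.all(np.isin(values, [0.0, 1.0])):
        warnings.warn(f"{path}: mask values {values[:5]}... binarized at > 0.5",
                      stacklevel=2)
    mask = data > 0.5
    if reference_shape is not None and mask.shape != tuple(reference_shape):
        raise ValueError(
            f"{path}: mask shape {mask.shape} does not match reference "
            f"{tuple(reference_shape)}"
        )
    if reference_affine is not None:
        check_aligned(affine, reference_affine, str(path), "reference volume")
    return mask


def check_aligned(affine_a, affine_b, name_a: str, name_b: str) -> None:
    """Raise if two affines differ beyond tolerance, naming both files."""
    if not np.allclose(affine_a, affine_b, atol=AFFINE_ATOL):
        raise ValueError(
            f"affine mismatch between {name_a} and {name_b}; inputs must be "
            "pre-aligned (no resampling is performed)"
        )
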
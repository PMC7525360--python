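"""Normal-appearing white matter (NAWM) ROI construction and MWF summaries.

White-matter masks are eroded slice-by-slice with a 3×3 in-plane box to
strip partial-volume gray matter and CSF at tissue boundaries; tract ROIs
are intersected with the eroded WM mask and lesion voxels are subtracted,
leaving normal-appearing white matter only.  Per ROI the MWF distribution
is summarized by its mean, SD and their ratio, the myelin heterogeneity
index (MHI = SD / mean), a coefficient of variation that rises both when
mean myelin content falls and when the MWF distribution broadens.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["ROIStats", "erode_inplane", "build_nawm_roi", "compute_mhi", "roi_stats_table"]

logger = logging.getLogger(__name__)

#: Minimum in-ROI voxel count below which MHI is reported as undefined.
DEFAULT_MIN_VOXELS = 50


@dataclass
class ROIStats:
    """Per-ROI MWF summary for one subject."""

    roi_name: str
    n_voxels: int
    mean_mwf: float
    sd_mwf: float
    mhi: float


def _as_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"{name} must be 3D, got ndim={mask.ndim}")
    return mask > 0.5


def erode_inplane(mask: np.ndarray) -> np.ndarray:
    """In-plane morphological erosion with a 3×3×1 box.

    A voxel survives iff itself and all 8 in-plane neighbours are set;
    slices (third axis) are processed independently, so there is no
    through-plane coupling.  The result is a subset of the input.
    """
    binary = _as_binary(mask)
    structure = np.ones((3, 3, 1), dtype=bool)
    return ndimage.binary_erosion(binary, structure=structure, border_value=0)


def build_nawm_roi(
    roi: np.ndarray, wm_eroded: np.ndarray, lesions: np.ndarray | None = None
) -> np.ndarray:
    """NAWM ROI: tract ROI ∩ eroded WM, minus lesion voxels.

    ``lesions`` may be None (e.g. controls), treated as empty.
    """
    roi_b = _as_binary(roi, "roi")
    wm_b = _as_binary(wm_eroded, "wm_eroded")
    if roi_b.shape != wm_b.shape:
        raise ValueError(f"roi shape {roi_b.shape} != WM shape {wm_b.shape}")
    out = roi_b & wm_b
    if lesions is not None:
        les_b = _as_binary(lesions, "lesions")
        if les_b.shape != roi_b.shape:
            raise ValueError(f"lesion shape {les_b.shape} != roi shape {roi_b.shape}")
        out &= ~les_b
    if not out.any():
        warnings.warn("NAWM ROI is empty after WM intersection / lesion subtraction",
                      stacklevel=2)
    return out


def compute_mhi(
    mwf_volume: np.ndarray,
    roi: np.ndarray,
    roi_name: str = "roi",
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> ROIStats:
    """Myelin heterogeneity index over an ROI.

    Mean and sample SD (n−1 denominator) are taken over finite MWF values
    inside the ROI; MHI = SD / mean.  MHI is NaN, with a warning, when
    fewer than ``min_voxels`` finite voxels remain or the mean is not
    positive.
    """
    roi_b = _as_binary(roi, "roi")
    mwf_volume = np.asarray(mwf_volume, dtype=float)
    if mwf_volume.shape != roi_b.shape:
        raise ValueError(
            f"MWF volume shape {mwf_volume.shape} != roi shape {roi_b.shape}"
        )
    values = mwf_volume[roi_b]
    values = values[np.isfinite(values)]
    n = int(values.size)
    if n == 0:
        warnings.warn(f"ROI '{roi_name}': no finite MWF voxels; stats undefined",
                      stacklevel=2)
        return ROIStats(roi_name, 0, float("nan"), float("nan"), float("nan"))
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    if n < min_voxels:
        warnings.warn(
            f"ROI '{roi_name}': only {n} voxels (< {min_voxels}); MHI undefined",
            stacklevel=2,
        )
        return ROIStats(roi_name, n, mean, sd, float("nan"))
    if mean <= 0:
        warnings.warn(f"ROI '{roi_name}': non-positive mean MWF; MHI undefined",
                      stacklevel=2)
        return ROIStats(roi_name, n, mean, sd, float("nan"))
    return ROIStats(roi_name, n, mean, sd, sd / mean)


def roi_stats_table(
    mwf_volume: np.ndarray,
    wm_mask: np.ndarray,
    roi_masks: dict[str, np.ndarray],
    lesion_mask: np.ndarray | None = None,
    subject_id: str = "subject",
    min_voxels: int = DEFAULT_MIN_VOXELS,
    erode_wm: bool = True,
) -> pd.DataFrame:
    """Per-ROI NAWM MWF statistics for one subject as a tidy table.

    The WM mask is eroded in-plane (unless ``erode_wm`` is False, for masks
    already eroded upstream), each tract ROI is restricted to NAWM, and the
    MWF mean / SD / MHI are computed per ROI.
    """
    wm = erode_inplane(wm_mask) if erode_wm else _as_binary(wm_mask, "wm")
    rows = []
    for name, roi in roi_masks.items():
        nawm = build_nawm_roi(roi, wm, lesion_mask)
        stats = compute_mhi(mwf_volume, nawm, name, min_voxels)
        rows.append(
            {
                "subject_id": subject_id,
                "roi": name,
                "n_voxels": stats.n_voxels,
                "mean_mwf": stats.mean_mwf,
                "sd_mwf": stats.sd_mwf,
                "mhi": stats.mhi,
            }
        )
    return pd.DataFrame(rows)
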
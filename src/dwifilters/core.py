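"""Lesion-core modelling on augmented ADC maps.

For each diffusion-encoding direction a 3D volume of interest (VOI) is
grown from the voxels of the augmented map that fall below a threshold,
restricted to the annotated slices, decomposed into 26-connected 3D
components, and anchored to the lesion by keeping only components that
touch the (dilated) ROI.  The threshold is swept over the augmented values
observed inside the ROI and chosen to maximise the overlap -- Dice by
default -- between the ROI mask and the VOI cross-section on the index
slice.  That maximal-overlap cross-section intersected with the ROI is the
"lesion core", the sub-ROI on which directional cancer-like areas are
measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from .roi import LesionROI, dilate_lesion_roi

#: 26-connectivity in 3D; through-plane linking is required because VOIs are
#: "connected in 3D but not necessarily in the 2D index slice plane"
_STRUCT_26 = np.ones((3, 3, 3), bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)

OverlapMetric = Literal["dice", "intersection_fraction"]


@dataclass
class LesionCoreModel:
    """Optimised VOI and lesion core for one diffusion direction."""

    direction: str
    threshold_star: float
    voi: np.ndarray  # 3D boolean
    core: np.ndarray  # 2D boolean, index slice
    overlap_score: float
    degenerate: bool = False  # no threshold produced any overlap


def _overlap(voi_cross: np.ndarray, roi_mask: np.ndarray, metric: OverlapMetric) -> float:
    inter = int(np.count_nonzero(voi_cross & roi_mask))
    if metric == "dice":
        denom = int(voi_cross.sum()) + int(roi_mask.sum())
        return 2.0 * inter / denom if denom else 0.0
    if metric == "intersection_fraction":
        n_roi = int(roi_mask.sum())
        return inter / n_roi if n_roi else 0.0
    raise ValueError(f"unknown overlap metric {metric!r}")


def build_voi(
    augmented: np.ndarray,
    roi: LesionROI,
    threshold: float,
    connectivity: int = 26,
) -> np.ndarray:
    """3D VOI of below-threshold augmented voxels anchored to the ROI.

    Voxels with augmented value strictly below ``threshold``, restricted to
    the annotated slices, are labelled into 3D connected components
    (26-connectivity by default); the VOI is the union of components that
    intersect the dilated ROI on any annotated slice.  May be empty.
    """
    roi = dilate_lesion_roi(roi)
    anchor = roi.volume_mask(augmented.shape)
    below = augmented < threshold
    slab = np.zeros(augmented.shape[0], bool)
    slab[list(roi.slices)] = True
    below &= slab[:, None, None]
    if not below.any():
        return below
    struct = _STRUCT_26 if connectivity == 26 else _STRUCT_6
    labels, n = ndimage.label(below, structure=struct)
    if n == 0:
        return np.zeros_like(below)
    keep = np.unique(labels[anchor & below])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def candidate_thresholds(augmented: np.ndarray, roi: LesionROI) -> np.ndarray:
    """Threshold sweep grid: unique augmented values inside the dilated ROI
    across annotated slices, plus the slab maximum.

    Thresholding is strict (< t), so each observed value v is swept as the
    smallest float above v -- the lowest threshold that admits v.  Sweeping
    these exhausts every distinct core the ROI voxels can produce.
    """
    roi = dilate_lesion_roi(roi)
    union = roi.volume_mask(augmented.shape)
    vals = np.unique(augmented[union])
    slab_max = max(float(augmented[s].max()) for s in roi.slices)
    return np.unique(np.nextafter(np.append(vals, slab_max), np.inf))


def optimize_core_threshold(
    augmented: np.ndarray,
    roi: LesionROI,
    direction: str = "",
    metric: OverlapMetric = "dice",
    connectivity: int = 26,
) -> LesionCoreModel:
    """Pick the threshold maximising index-slice overlap; derive the core.

    Ties are broken toward the lowest threshold.  When no candidate yields
    any overlap, an empty core is returned with ``degenerate=True``.
    """
    roi = dilate_lesion_roi(roi)
    idx = roi.index_slice
    roi_mask = roi.index_mask()

    best: Optional[LesionCoreModel] = None
    for t in candidate_thresholds(augmented, roi):
        voi = build_voi(augmented, roi, float(t), connectivity=connectivity)
        score = _overlap(voi[idx], roi_mask, metric)
        if best is None or score > best.overlap_score:
            best = LesionCoreModel(
                direction=direction,
                threshold_star=float(t),
                voi=voi,
                core=voi[idx] & roi_mask,
                overlap_score=score,
            )
    assert best is not None
    if best.overlap_score == 0.0:
        best.degenerate = True
        best.core = np.zeros_like(roi_mask)
    return best


def lesion_core(model: LesionCoreModel) -> np.ndarray:
    """Lesion core: VOI cross-section at the index slice, inside the ROI."""
    return model.core
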
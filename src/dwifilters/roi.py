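"""Lesion ROI handling: annotation rescaling, dilation, index slice, mean ADC.

Radiologist ROIs are drawn at annotation (review-monitor) resolution and
mapped back to the native DWI grid so that physical area in mm^2 is
preserved as closely as possible.  A 1-pixel dilation then widens each
per-slice mask to capture periphery signal and increase sample counts.  The
annotated axial slice with the largest ROI is the "index slice" on which
lesion cores are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize

# binarisation thresholds for the interpolated mask are searched over
# [0.25, 0.75]; the candidate set is this coarse grid plus every
# interpolated value observed in that band, so the achievable pixel count
# closest to the annotation's physical area can always be selected
_AREA_THRESHOLD_BAND = (0.25, 0.75)
_AREA_THRESHOLD_GRID = np.arange(0.25, 0.7501, 0.05)


@dataclass
class LesionROI:
    """Per-slice binary lesion masks on the native DWI grid.

    ``masks`` maps axial slice index (first grid axis, 0-based) to a 2D
    boolean mask.  ``pixel_area`` is the in-plane pixel area in mm^2.
    ``dilated`` records whether the 1-pixel band has been applied.
    """

    masks: Dict[int, np.ndarray]
    pixel_area: float
    dilated: bool = False

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("ROI has no annotated slices")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        self.masks = {int(k): np.asarray(v, bool) for k, v in self.masks.items()}
        for k, m in self.masks.items():
            if m.ndim != 2:
                raise ValueError(f"mask on slice {k} is not 2D")
            if not m.any():
                raise ValueError(f"mask on slice {k} is empty")

    @property
    def index_slice(self) -> int:
        return select_index_slice(self)

    @property
    def slices(self) -> Tuple[int, ...]:
        return tuple(sorted(self.masks))

    def index_mask(self) -> np.ndarray:
        return self.masks[self.index_slice]

    def volume_mask(self, grid_shape: Tuple[int, int, int]) -> np.ndarray:
        """Expand the per-slice masks into a full 3D boolean mask."""
        out = np.zeros(grid_shape, dtype=bool)
        for k, m in self.masks.items():
            if not (0 <= k < grid_shape[0]) or m.shape != grid_shape[1:]:
                raise ValueError("ROI masks do not fit the grid")
            out[k] = m
        return out

    def physical_area(self, slice_index: int) -> float:
        """Mask area on one slice, mm^2."""
        return float(self.masks[slice_index].sum()) * self.pixel_area


def map_annotation_to_native(
    annotation_mask: np.ndarray,
    native_shape: Tuple[int, int],
    native_pixel_area: float,
) -> np.ndarray:
    """Downscale an annotation-resolution binary mask to the native grid.

    The annotation grid covers the same field of view as the native grid at
    higher pixel density, so one annotation pixel has physical area
    ``native_pixel_area * prod(native_shape) / prod(annotation_shape)``.
    The mask is bilinearly interpolated to the native shape and binarised at
    the threshold (from 0.25-0.75) whose output area best matches the
    annotation's physical area.
    """
    annotation_mask = np.asarray(annotation_mask, bool)
    if not annotation_mask.any():
        raise ValueError("annotation mask is empty")
    ann_shape = annotation_mask.shape
    if ann_shape[0] < native_shape[0] or ann_shape[1] < native_shape[1]:
        raise ValueError("annotation resolution must be >= native resolution")
    if ann_shape == tuple(native_shape):
        return annotation_mask.copy()

    ann_pixel_area = native_pixel_area * (native_shape[0] * native_shape[1]) / (
        ann_shape[0] * ann_shape[1]
    )
    target_area = annotation_mask.sum() * ann_pixel_area

    smooth = resize(
        annotation_mask.astype(float), native_shape, order=1, anti_aliasing=True
    )
    lo, hi = _AREA_THRESHOLD_BAND
    observed = np.unique(smooth[(smooth > lo) & (smooth <= hi)])
    candidates = np.concatenate([_AREA_THRESHOLD_GRID, np.nextafter(observed, 0.0)])
    best_mask, best_err = None, np.inf
    for t in candidates:
        cand = smooth > t
        err = abs(cand.sum() * native_pixel_area - target_area)
        if err < best_err:
            best_mask, best_err = cand, err
    assert best_mask is not None
    if not best_mask.any():
        # degenerate annotations smaller than a native pixel: keep the peak
        best_mask = smooth >= smooth.max()
    return best_mask


def dilate_roi(mask: np.ndarray) -> np.ndarray:
    """One morphological dilation with a 3x3 square (8-connected) element.

    Adds the 1-pixel band around the mask in all directions including
    diagonals; clipped at the image border.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot dilate an empty mask")
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool))


def dilate_lesion_roi(roi: LesionROI) -> LesionROI:
    """Apply the 1-pixel band to every annotated slice of a lesion ROI."""
    if roi.dilated:
        return roi
    return replace(
        roi, masks={k: dilate_roi(m) for k, m in roi.masks.items()}, dilated=True
    )


def select_index_slice(roi: LesionROI) -> int:
    """Annotated slice with the largest mask; ties go to the lowest index."""
    best_slice, best_area = None, -1
    for k in sorted(roi.masks):
        area = int(roi.masks[k].sum())
        if area > best_area:
            best_slice, best_area = k, area
    assert best_slice is not None
    return best_slice


def roi_mean_adc(adc_mean: np.ndarray, roi: LesionROI, use_dilated: bool = True) -> float:
    """Lesion mean ADC: average of the mean-ADC map over the ROI.

    By default the dilated ROI is used, matching the rationale for the
    1-pixel band (periphery signal, more sample points); ``use_dilated=False``
    averages over the original annotation instead.
    """
    work = dilate_lesion_roi(roi) if use_dilated and not roi.dilated else roi
    union = work.volume_mask(adc_mean.shape)
    if not union.any():
        raise ValueError("ROI does not intersect the grid")
    return float(adc_mean[union].mean())
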
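"""Independent brute-force oracles shared across test modules.

These deliberately avoid the implementation's code paths: connected
components come from skimage (the package uses scipy.ndimage), and overlap
scores are computed with explicit set arithmetic.
"""

import numpy as np
from skimage.measure import label as sk_label

from dwifilters import LesionROI
from dwifilters.core import candidate_thresholds
from dwifilters.roi import dilate_lesion_roi


def make_roi(grid_shape, slices, box, pixel_area=1.0):
    masks = {}
    for k in slices:
        m = np.zeros(grid_shape[1:], bool)
        m[box] = True
        masks[k] = m
    return LesionROI(masks=masks, pixel_area=pixel_area)


def oracle_voi(augmented, roi, threshold):
    """VOI by independent 26-connected labelling and explicit set logic."""
    roi = dilate_lesion_roi(roi)
    below = augmented < threshold
    keep_slices = set(roi.slices)
    for k in range(augmented.shape[0]):
        if k not in keep_slices:
            below[k] = False
    labels = sk_label(below, connectivity=3)
    anchor = roi.volume_mask(augmented.shape)
    kept = {l for l in np.unique(labels[anchor]) if l != 0}
    return np.isin(labels, sorted(kept)) & below


def oracle_optimum(augmented, roi):
    """Exhaustive threshold sweep with direct Dice, lowest-threshold ties."""
    droi = dilate_lesion_roi(roi)
    idx = droi.index_slice
    roi_mask = droi.masks[idx]
    best_t, best_score = None, -1.0
    for t in candidate_thresholds(augmented, droi):
        cross = oracle_voi(augmented, droi, float(t))[idx]
        inter = np.count_nonzero(cross & roi_mask)
        denom = int(cross.sum()) + int(roi_mask.sum())
        score = 2.0 * inter / denom if denom else 0.0
        if score > best_score:
            best_t, best_score = float(t), score
    return best_t, best_score
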
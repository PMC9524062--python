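"""SDAC: standard deviation of area covered by cancer-like pixels.

Pixels of the ROI are classified by the mean ADC map -- cancer-like when
ADC < 1.37e-3 mm^2/s, benign-like at or above it -- so the classification is
identical across directions.  Direction-dependence enters only through the
per-direction lesion cores: for each direction the cancer-like area is the
number of cancer-like pixels inside that direction's core times the pixel
area.  SDAC is the sample standard deviation (divisor n-1) of the three
areas; large SDAC flags anisotropic lesions as suspicious.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

from .core import LesionCoreModel
from .roi import LesionROI

#: pixelwise ADC cutoff separating cancer-like (<) from benign-like (>=), mm^2/s
ADC_PIXEL_CUTOFF = 1.37e-3


@dataclass
class SDACResult:
    """Per-direction cancer-like areas and their sample SD, for one lesion."""

    area_P: float
    area_R: float
    area_S: float
    sdac: float
    n_red: int
    n_blue: int
    adc_cutoff: float = ADC_PIXEL_CUTOFF

    @property
    def areas(self) -> Dict[str, float]:
        return {"P": self.area_P, "R": self.area_R, "S": self.area_S}

    @property
    def percent_red(self) -> float:
        total = self.n_red + self.n_blue
        return 100.0 * self.n_red / total if total else 0.0


def classify_pixels(
    adc_mean: np.ndarray, roi: LesionROI, cutoff: float = ADC_PIXEL_CUTOFF
) -> np.ndarray:
    """Cancer-like mask over the grid: mean ADC strictly below the cutoff.

    The boundary value itself is benign-like.  Returned as a full-grid
    boolean volume; combine with ROI/core masks to count lesion pixels.
    """
    roi.volume_mask(adc_mean.shape)  # validates the ROI fits the grid
    return np.asarray(adc_mean) < cutoff


def direction_area(labels: np.ndarray, core_d: np.ndarray, pixel_area: float) -> float:
    """Cancer-like area within one direction's core, mm^2."""
    labels = np.asarray(labels, bool)
    core_d = np.asarray(core_d, bool)
    if labels.shape != core_d.shape:
        raise ValueError("labels and core mask must share one shape")
    return float(np.count_nonzero(labels & core_d)) * pixel_area


def sdac(area_p: float, area_r: float, area_s: float) -> float:
    """Sample standard deviation (divisor n-1 = 2) of the three areas."""
    if min(area_p, area_r, area_s) < 0:
        raise ValueError("areas must be non-negative")
    if area_p == area_r == area_s:
        return 0.0
    return float(np.std([area_p, area_r, area_s], ddof=1))


def compute_sdac(
    adc_mean: np.ndarray,
    roi: LesionROI,
    cores: Mapping[str, LesionCoreModel],
    cutoff: float = ADC_PIXEL_CUTOFF,
) -> SDACResult:
    """SDAC and red/blue pixel counts for one lesion.

    ``cores`` maps direction P/R/S to its optimised lesion-core model; the
    red/blue tally is taken over the ROI mask on the index slice.
    """
    cancer_like = classify_pixels(adc_mean, roi, cutoff)
    idx = roi.index_slice
    roi_mask = roi.index_mask()
    red_in_roi = cancer_like[idx] & roi_mask
    n_red = int(red_in_roi.sum())
    n_blue = int(roi_mask.sum()) - n_red

    areas = {
        d: direction_area(cancer_like[idx], cores[d].core, roi.pixel_area)
        for d in ("P", "R", "S")
    }
    return SDACResult(
        area_P=areas["P"],
        area_R=areas["R"],
        area_S=areas["S"],
        sdac=sdac(areas["P"], areas["R"], areas["S"]),
        n_red=n_red,
        n_blue=n_blue,
        adc_cutoff=cutoff,
    )
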
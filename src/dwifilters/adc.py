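"""Directional ADC mapping from two-point diffusion-weighted acquisitions.

Each lesion study carries six volumes: b=0 and b=800 s/mm^2 signal for each
of the three diffusion-encoding directions, phase (P), readout (R) and
slice (S).  With a single non-zero b-value the apparent diffusion
coefficient follows from the mono-exponential decay model

    S(b) = S0 * exp(-b * ADC)   =>   ADC = ln(S0 / Sb) / b

computed voxelwise and independently per direction.  The voxelwise mean of
the three directional maps is the ADC map used for pixel classification;
"augmented" maps (directional ADC times the corresponding b=0 signal) drive
the lesion-core modelling.

All ADC values are held in mm^2/s internally; the conventional 1e-3 factor
appears only at the I/O boundary (see :mod:`dwifilters.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

DIRECTIONS = ("P", "R", "S")

#: b-values of the acquisition protocol, s/mm^2
B_VALUES = (0, 800)


def _check_congruent(*grids: np.ndarray) -> None:
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"grids must share one shape, got {sorted(shapes)}")


@dataclass
class DirectionalDWIStudy:
    """Six co-registered DWI volumes for one lesion study.

    ``signals[(d, b)]`` is the 3D signal volume for direction ``d`` in
    {"P", "R", "S"} and b-value ``b`` in {0, 800}.  ``spacing`` is
    (slice, row, col) in mm; axial slices are the first axis.
    """

    signals: Dict[Tuple[str, int], np.ndarray]
    spacing: Tuple[float, float, float]
    study_id: str = "study"

    def __post_init__(self) -> None:
        expected = {(d, b) for d in DIRECTIONS for b in B_VALUES}
        missing = expected - set(self.signals)
        if missing:
            raise ValueError(f"study {self.study_id} missing volumes: {sorted(missing)}")
        _check_congruent(*self.signals.values())
        for key, vol in self.signals.items():
            if np.any(vol < 0):
                raise ValueError(f"negative signal in volume {key}")

    @property
    def grid_shape(self) -> Tuple[int, ...]:
        return next(iter(self.signals.values())).shape

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area, mm^2."""
        return self.spacing[1] * self.spacing[2]


@dataclass
class ADCMaps:
    """Directional ADC maps, their voxelwise mean, and augmented maps."""

    adc_dir: Dict[str, np.ndarray]
    adc_mean: np.ndarray
    augmented: Dict[str, np.ndarray]
    #: voxels where ADC was undefined or negative and clamped to 0, per direction
    flagged: Dict[str, int] = field(default_factory=dict)


def directional_adc(s0: np.ndarray, sb: np.ndarray, b: float) -> Tuple[np.ndarray, np.ndarray]:
    """Two-point mono-exponential ADC estimate, per voxel.

    Voxels where either signal is non-positive, or where the estimate comes
    out negative (signal increase with b), are clamped to 0 and flagged.
    Clamped voxels read as maximally restricted diffusion, i.e. cancer-like
    under any threshold -- the conservative direction for biopsy triage.

    Returns ``(adc, flagged)`` where ``flagged`` is a boolean mask of the
    clamped voxels.
    """
    s0 = np.asarray(s0, dtype=float)
    sb = np.asarray(sb, dtype=float)
    _check_congruent(s0, sb)
    if b <= 0:
        raise ValueError("b must be positive")
    valid = (s0 > 0) & (sb > 0)
    adc = np.zeros_like(s0)
    np.divide(s0, sb, out=adc, where=valid)
    np.log(adc, out=adc, where=valid)
    adc[valid] /= b
    flagged = ~valid | (adc < 0)
    adc[flagged] = 0.0
    return adc, flagged


def mean_adc(adc_p: np.ndarray, adc_r: np.ndarray, adc_s: np.ndarray) -> np.ndarray:
    """Voxelwise arithmetic mean of the three directional ADC maps."""
    _check_congruent(adc_p, adc_r, adc_s)
    return (np.asarray(adc_p, float) + np.asarray(adc_r, float) + np.asarray(adc_s, float)) / 3.0


def augmented_map(adc_d: np.ndarray, s0_d: np.ndarray) -> np.ndarray:
    """Augmented map: directional ADC scaled voxelwise by the b=0 signal.

    Used only ordinally (for threshold sweeps), so the arbitrary signal
    units cancel out of every downstream decision.
    """
    adc_d = np.asarray(adc_d, float)
    s0_d = np.asarray(s0_d, float)
    _check_congruent(adc_d, s0_d)
    return adc_d * s0_d


def compute_adc_maps(study: DirectionalDWIStudy, b: float = 800.0) -> ADCMaps:
    """Full ADC product set for a study: directional, mean, augmented maps."""
    adc_dir: Dict[str, np.ndarray] = {}
    augmented: Dict[str, np.ndarray] = {}
    flagged: Dict[str, int] = {}
    for d in DIRECTIONS:
        adc, flag = directional_adc(study.signals[(d, 0)], study.signals[(d, int(b))], b)
        adc_dir[d] = adc
        augmented[d] = augmented_map(adc, study.signals[(d, 0)])
        flagged[d] = int(flag.sum())
    mean = mean_adc(adc_dir["P"], adc_dir["R"], adc_dir["S"])
    return ADCMaps(adc_dir=adc_dir, adc_mean=mean, augmented=augmented, flagged=flagged)
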
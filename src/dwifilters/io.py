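"""File I/O: NIfTI volumes, ROI masks, cohort tables, study layout.

Study layout on disk is one directory per lesion study containing the six
signal volumes named ``{direction}_b{value}.nii.gz`` (directions P, R, S;
b 0 and 800) and a 3D ROI mask ``roi.nii.gz`` on the same grid.  A cohort
directory holds one study directory per lesion plus ``cohort.csv`` with
columns lesion_id, pathology, morphology (and, for synthetic cohorts, the
ground-truth columns).

Arrays are held in (slice, row, col) order in memory and stored to NIfTI in
(col, row, slice) axis order with the voxel spacing on the affine diagonal.
ADC volumes and CSV columns are expressed in the conventional display unit
of 1e-3 mm^2/s at the file boundary; everything in memory is mm^2/s.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .adc import B_VALUES, DIRECTIONS, DirectionalDWIStudy
from .roi import LesionROI
from .synthetic import PhantomStudy

ADC_FILE_SCALE = 1e3  # mm^2/s -> 1e-3 mm^2/s at the file boundary


def _affine(spacing: Tuple[float, float, float]) -> np.ndarray:
    # spacing is (slice, row, col); stored axis order is (col, row, slice)
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


def write_volume(path: Path, volume: np.ndarray, spacing: Tuple[float, float, float]) -> None:
    img = nib.Nifti1Image(np.asarray(volume, np.float64).T, _affine(spacing))
    nib.save(img, str(path))


def read_volume(path: Path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64).T
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data, spacing


def write_study(study: DirectionalDWIStudy, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (d, b), vol in study.signals.items():
        write_volume(out_dir / f"{d}_b{b}.nii.gz", vol, study.spacing)


def read_study(
    study_dir: Path,
    spacing_override: Optional[Tuple[float, float, float]] = None,
    study_id: Optional[str] = None,
) -> DirectionalDWIStudy:
    """Load the six signal volumes of one study directory."""
    study_dir = Path(study_dir)
    signals: Dict[Tuple[str, int], np.ndarray] = {}
    spacing = spacing_override
    shape = None
    for d in DIRECTIONS:
        for b in B_VALUES:
            path = study_dir / f"{d}_b{b}.nii.gz"
            if not path.exists():
                raise FileNotFoundError(
                    f"missing volume for direction {d}, b={b}: {path}"
                )
            vol, sp = read_volume(path)
            if spacing is None:
                spacing = sp
            if shape is None:
                shape = vol.shape
            elif vol.shape != shape:
                raise ValueError(f"grid mismatch in {path}: {vol.shape} vs {shape}")
            signals[(d, b)] = vol
    assert spacing is not None
    return DirectionalDWIStudy(
        signals=signals, spacing=spacing, study_id=study_id or study_dir.name
    )


def write_roi(roi: LesionROI, path: Path, grid_shape: Tuple[int, int, int],
              spacing: Tuple[float, float, float]) -> None:
    write_volume(Path(path), roi.volume_mask(grid_shape).astype(np.uint8), spacing)


def read_roi(path: Path, pixel_area: Optional[float] = None) -> LesionROI:
    vol, spacing = read_volume(Path(path))
    mask = vol > 0.5
    masks = {int(k): mask[k] for k in np.flatnonzero(mask.any(axis=(1, 2)))}
    if not masks:
        raise ValueError(f"ROI mask {path} is empty")
    return LesionROI(
        masks=masks,
        pixel_area=pixel_area if pixel_area is not None else spacing[1] * spacing[2],
    )


def write_adc_map(path: Path, adc: np.ndarray, spacing: Tuple[float, float, float]) -> None:
    """ADC/augmented map to NIfTI in display units (1e-3 mm^2/s)."""
    write_volume(Path(path), np.asarray(adc) * ADC_FILE_SCALE, spacing)


def write_phantom_study(ph: PhantomStudy, out_dir: Path) -> None:
    """One phantom study directory: signals, ROI masks, truth rows."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_study(ph.study, out_dir)
    shape = ph.study.grid_shape
    for lid, roi in ph.rois.items():
        name = "roi.nii.gz" if len(ph.rois) == 1 else f"roi_{lid}.nii.gz"
        write_roi(roi, out_dir / name, shape, ph.study.spacing)


_ADC_COLUMNS = ("mean_adc", "adc_m", "adc_md", "truth_mean_adc", "mean_adc_target", "dark_value")


def write_cohort_csv(table: pd.DataFrame, path: Path) -> None:
    """Cohort table to CSV with ADC columns in 1e-3 mm^2/s."""
    out = table.copy()
    for col in _ADC_COLUMNS:
        if col in out.columns:
            out[col] = out[col] * ADC_FILE_SCALE
    out.to_csv(path, index=False)


def read_cohort_csv(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in _ADC_COLUMNS:
        if col in table.columns:
            table[col] = table[col] / ADC_FILE_SCALE
    return table


def write_report(report_dict: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=2, sort_keys=True) + "\n")
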
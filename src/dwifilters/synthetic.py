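"""Synthetic directional-DWI phantoms with known ground truth.

The clinical cohort behind this methodology is not public, so every
downstream stage is exercised on simulated lesion studies instead.  A
phantom is a 3D grid of homogeneous fibroglandular background tissue
containing one or more lesions.  Each lesion is built from:

* a footprint -- a compact ellipsoid for masses, a segmental string of
  small blobs for non-mass lesions;
* three per-direction "dark" regions of restricted diffusion, nested
  subsets of the footprint ranked by distance from the lesion boundary.
  The dark-region areas are scaled per diffusion direction (P grows, R is
  held, S shrinks) by the lesion's anisotropy parameter, so the standard
  deviation of the per-direction cancer-like areas grows linearly with it
  while the mean-ADC map (average over directions) is unaffected in
  aggregate;
* a dark ADC value solved in closed form so that the voxelwise mean of the
  three directional ADC fields, averaged over the 1-pixel-dilated lesion
  ROI, equals the requested lesion mean ADC exactly.

Signals follow the mono-exponential decay S(b) = S0 * exp(-b * ADC) per
direction, with optional Rician noise applied independently to every
magnitude volume.  Identical spec and seed give bit-identical output.

The generator emulates the acquisition geometry of the clinical protocol
(1.25 mm in-plane pixels, 2.5 mm slices, b = 0 and 800 s/mm^2) and the
cohort structure (69 lesions, 55.1% malignant, 26.1% non-mass).  It does
not attempt realistic breast anatomy, fat suppression, EPI distortion or
motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .adc import DirectionalDWIStudy, DIRECTIONS
from .roi import LesionROI, dilate_roi

#: per-direction area scaling pattern: dark-region fraction in direction d is
#: core_fraction * (1 + anisotropy * _ANISO_PATTERN[d]).  The pattern sums to
#: 0 so the direction-averaged ADC field is unchanged; two directions grow
#: together so the growth band stays dark on the mean map (two of three
#: directions restricted), keeping the band cancer-like and the SDAC response
#: to anisotropy strong.
_ANISO_PATTERN = {"P": 1.0, "R": 1.0, "S": -2.0}

#: preferred ADC of the restricted-diffusion (dark) region, mm^2/s, used when
#: deriving the dark fraction from a lesion's target mean ADC
_DARK_ADC_PREF = 0.7e-3

_MIN_ADC = 1e-5  # clamp floor for solved dark values, mm^2/s


@dataclass(frozen=True)
class PhantomSpec:
    """Acquisition geometry and background of one phantom study."""

    grid_shape: Tuple[int, int, int] = (10, 48, 48)
    pixel_spacing: float = 1.25  # mm, in-plane (square pixels)
    slice_thickness: float = 2.5  # mm
    b_values: Tuple[int, int] = (0, 800)  # s/mm^2
    background_adc: float = 1.8e-3  # mm^2/s, fibroglandular tissue
    s0_level: float = 1000.0  # arbitrary signal units
    noise_sigma: float = 0.0  # Rician sigma, signal units
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape components must be >= 1")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacings must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.background_adc <= 0 or self.s0_level <= 0:
            raise ValueError("background_adc and s0_level must be positive")

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return (self.slice_thickness, self.pixel_spacing, self.pixel_spacing)

    @property
    def pixel_area(self) -> float:
        return self.pixel_spacing**2


@dataclass(frozen=True)
class LesionSpec:
    """Ground-truth description of one simulated lesion."""

    center: Tuple[int, int, int]  # voxel coordinates (slice, row, col)
    morphology: str = "mass"  # "mass" | "non-mass"
    pathology: str = "benign"  # "benign" | "malignant"
    mean_adc_target: float = 1.2e-3  # mm^2/s, over the dilated ROI
    core_fraction: Optional[float] = None  # dark fraction of footprint; None = derive
    anisotropy: float = 0.0  # >= 0; 0 means the three directional fields coincide
    orientation: int = 0  # in-plane elongation axis: 0 = rows, 1 = cols
    extent: Tuple[float, float, float] = (6.0, 12.0, 12.0)  # mm per axis
    lesion_id: str = "lesion"

    def __post_init__(self) -> None:
        if self.morphology not in ("mass", "non-mass"):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.pathology not in ("benign", "malignant"):
            raise ValueError(f"unknown pathology {self.pathology!r}")
        if self.core_fraction is not None and not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must lie in [0, 1]")
        if self.anisotropy < 0:
            raise ValueError("anisotropy must be non-negative")
        if self.mean_adc_target <= 0:
            raise ValueError("mean_adc_target must be positive")


@dataclass
class PhantomStudy:
    """One generated study: signals, ground-truth ROIs and truth rows."""

    study: DirectionalDWIStudy
    rois: Dict[str, LesionROI]
    truth: pd.DataFrame
    adc_fields: Dict[str, np.ndarray] = field(default_factory=dict)  # designed, per direction


# ---------------------------------------------------------------------------
# footprints


def _ellipsoid(
    grid_shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    center: Tuple[float, float, float],
    radii_mm: Tuple[float, float, float],
) -> np.ndarray:
    zz, yy, xx = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    terms = (
        ((zz - center[0]) * spacing[0] / radii_mm[0]) ** 2
        + ((yy - center[1]) * spacing[1] / radii_mm[1]) ** 2
        + ((xx - center[2]) * spacing[2] / radii_mm[2]) ** 2
    )
    return terms <= 1.0


def _mass_footprint(spec: PhantomSpec, lesion: LesionSpec) -> np.ndarray:
    rz, ry, rx = (e / 2.0 for e in lesion.extent)
    if lesion.orientation == 1:
        ry, rx = rx, ry
    return _ellipsoid(spec.grid_shape, spec.spacing, lesion.center, (rz, ry, rx))


def _nonmass_footprint(
    spec: PhantomSpec, lesion: LesionSpec, rng: np.random.Generator
) -> np.ndarray:
    """Segmental pattern: 3-8 small blobs strung along a curved in-plane path."""
    n_blobs = int(rng.integers(3, 9))
    out = np.zeros(spec.grid_shape, bool)
    half = np.asarray(lesion.extent) / 2.0
    # curved path: angle drifts as we walk outward from the center
    angle = rng.uniform(0, 2 * np.pi)
    curvature = rng.uniform(-0.5, 0.5)
    step = max(half[1], half[2]) * 2.0 / max(n_blobs - 1, 1)
    pos = np.asarray(lesion.center, float)
    blob_r = max(1.5 * spec.pixel_spacing, 0.18 * max(half[1], half[2]))
    for i in range(n_blobs):
        frac = i / max(n_blobs - 1, 1)
        r_mm = (
            max(spec.slice_thickness * 0.9, half[0] * (1 - 0.5 * frac)),
            blob_r * rng.uniform(0.8, 1.3),
            blob_r * rng.uniform(0.8, 1.3),
        )
        out |= _ellipsoid(spec.grid_shape, spec.spacing, tuple(pos), r_mm)
        angle += curvature
        pos = pos + np.array(
            [0.0, np.cos(angle) * step / spec.pixel_spacing, np.sin(angle) * step / spec.pixel_spacing]
        ) * rng.uniform(0.7, 1.1)
    return out


def _footprint(spec: PhantomSpec, lesion: LesionSpec, rng: np.random.Generator) -> np.ndarray:
    fp = (
        _mass_footprint(spec, lesion)
        if lesion.morphology == "mass"
        else _nonmass_footprint(spec, lesion, rng)
    )
    if not fp.any():
        raise ValueError(f"lesion {lesion.lesion_id} has an empty footprint")
    # footprint plus the 1-pixel dilation band must stay inside the grid
    edges = (
        fp[0].any()
        or fp[-1].any()
        or fp[:, :2].any()
        or fp[:, -2:].any()
        or fp[:, :, :2].any()
        or fp[:, :, -2:].any()
    )
    if edges:
        raise ValueError(f"lesion {lesion.lesion_id} does not fit inside the grid")
    return fp


# ---------------------------------------------------------------------------
# dark (restricted-diffusion) regions and ADC fields


def _dark_sets(footprint: np.ndarray, fractions: Mapping[str, float]) -> Dict[str, np.ndarray]:
    """Nested per-direction dark regions, ranked by depth inside the footprint.

    Voxels are ordered by their per-slice Euclidean distance to the footprint
    boundary (deepest first, stable ties), and direction d takes the top
    round(fraction_d * N) voxels.  Equal fractions give identical sets.
    """
    depth = np.zeros(footprint.shape, float)
    for k in np.flatnonzero(footprint.any(axis=(1, 2))):
        depth[k] = ndimage.distance_transform_edt(footprint[k])
    flat_idx = np.flatnonzero(footprint)
    order = flat_idx[np.argsort(-depth.ravel()[flat_idx], kind="stable")]
    n = flat_idx.size
    out: Dict[str, np.ndarray] = {}
    for d, frac in fractions.items():
        k = int(round(np.clip(frac, 0.0, 1.0) * n))
        mask = np.zeros(footprint.size, bool)
        mask[order[:k]] = True
        out[d] = mask.reshape(footprint.shape)
    return out


def _dilated_footprint(footprint: np.ndarray) -> np.ndarray:
    out = np.zeros_like(footprint)
    for k in np.flatnonzero(footprint.any(axis=(1, 2))):
        out[k] = dilate_roi(footprint[k])
    return out


def _derive_dark_fraction(
    spec: PhantomSpec, target: float, n_footprint: int, n_dilated: int
) -> float:
    """Dark fraction needed to hit the target mean at the preferred dark ADC."""
    bg = spec.background_adc
    if target >= bg:
        return 0.3  # iso/hyper-intense lesion: fraction is arbitrary
    needed = (n_dilated / n_footprint) * (bg - target) / (bg - _DARK_ADC_PREF)
    return float(np.clip(needed, 0.1, 0.92))


def design_lesion_fields(
    spec: PhantomSpec, lesion: LesionSpec, rng: np.random.Generator
) -> Tuple[Dict[str, np.ndarray], np.ndarray, dict]:
    """Per-direction designed ADC fields for one lesion, plus its footprint.

    Returns ``(adc_fields, footprint, info)`` where ``adc_fields[d]`` is the
    full-grid designed ADC for direction d (background outside the lesion)
    and ``info`` records the solved dark value and realized mean.
    """
    bg = spec.background_adc
    fp = _footprint(spec, lesion, rng)
    n_fp = int(fp.sum())
    dil = _dilated_footprint(fp)
    n_dil = int(dil.sum())

    f = (
        lesion.core_fraction
        if lesion.core_fraction is not None
        else _derive_dark_fraction(spec, lesion.mean_adc_target, n_fp, n_dil)
    )
    if lesion.core_fraction is None and lesion.mean_adc_target < bg:
        # expressing an area anisotropy of a requires a dark core of
        # comparable relative size; the mean solve below compensates with a
        # brighter rim when the core is larger than the target alone implies
        f = min(0.92, max(f, 0.6 * lesion.anisotropy))
    # Per-direction fractions follow the pattern, with two guards: the
    # shrinking direction keeps a floor (a near-empty dark set cannot anchor
    # its core model against the saturating threshold), with the deficit
    # redistributed into the growing directions so the total dark mass -- and
    # hence the solved dark value -- is preserved; and no fraction exceeds
    # 0.98 (a fully dark lesion leaves no room for directional variation).
    shrink_dir = min(_ANISO_PATTERN, key=_ANISO_PATTERN.get)
    grow_dirs = [d for d in DIRECTIONS if d != shrink_dir]
    floor = min(f, max(0.10, 12.0 / n_fp))
    f_shrink = max(f * (1.0 + lesion.anisotropy * _ANISO_PATTERN[shrink_dir]), floor)
    f_grow = (3.0 * f - f_shrink) / 2.0
    if f_grow > 0.98:  # growth headroom exhausted: return the excess
        f_grow = 0.98
        f_shrink = min(0.98, max(f_shrink, 3.0 * f - 2 * 0.98))
    fractions = {d: float(np.clip(f_grow, 0.0, 0.98)) for d in grow_dirs}
    fractions[shrink_dir] = float(np.clip(f_shrink, 0.0, 0.98))
    dark = _dark_sets(fp, fractions)
    k_total = sum(int(dark[d].sum()) for d in DIRECTIONS)
    n_band = n_dil - n_fp  # dilation band stays at background
    target = lesion.mean_adc_target

    # Solve the lesion interior so the direction-averaged field over the
    # dilated ROI hits the target exactly.  Preferred: dark core at a fixed
    # restricted-diffusion value and a free rim at or above background
    # (bright rims let high-mean lesions still carry a sizeable dark core; a
    # rim below background would swallow the core into one dark blob).
    # Fallback when the rim solve is unphysical: rim at background, dark
    # value solved instead.
    clamped = False
    dark_value, rim_value = _DARK_ADC_PREF, bg
    n_rim_terms = 3 * n_fp - k_total
    if target < bg and n_rim_terms > 0 and k_total > 0:
        rim_value = (
            3.0 * n_dil * target - 3.0 * n_band * bg - k_total * _DARK_ADC_PREF
        ) / n_rim_terms
    if not (target < bg and bg <= rim_value <= 3.0e-3):
        rim_value = bg
        if k_total == 0:
            dark_value = bg
        else:
            dark_value = bg + 3.0 * n_dil * (target - bg) / k_total
        clamped = dark_value < _MIN_ADC
        dark_value = max(dark_value, _MIN_ADC)

    fields = {}
    for d in DIRECTIONS:
        fld = np.full(spec.grid_shape, bg)
        fld[fp] = rim_value
        fld[dark[d]] = dark_value
        fields[d] = fld
    mean_field = sum(fields.values()) / 3.0
    realized = float(mean_field[dil].mean())
    info = {
        "dark_value": dark_value,
        "rim_value": rim_value,
        "dark_fraction": f,
        "n_footprint_voxels": n_fp,
        "realized_mean_adc": realized,
        "clamped": clamped,
    }
    return fields, fp, info


# ---------------------------------------------------------------------------
# signal synthesis


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return signal.copy()
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def _roi_from_footprint(fp: np.ndarray, pixel_area: float) -> LesionROI:
    masks = {int(k): fp[k] for k in np.flatnonzero(fp.any(axis=(1, 2)))}
    return LesionROI(masks=masks, pixel_area=pixel_area, dilated=False)


def generate_phantom(
    spec: PhantomSpec, lesions: Sequence[LesionSpec], study_id: str = "phantom"
) -> PhantomStudy:
    """Simulate one study: six signal volumes, ROI truth, truth table.

    Lesion footprints must fit inside the grid (with room for the 1-pixel
    dilation band) and may not overlap each other.
    """
    rng = np.random.default_rng(spec.seed)
    b0, b1 = spec.b_values

    adc_fields = {d: np.full(spec.grid_shape, spec.background_adc) for d in DIRECTIONS}
    occupied = np.zeros(spec.grid_shape, bool)
    rois: Dict[str, LesionROI] = {}
    rows: List[dict] = []
    for i, lesion in enumerate(lesions):
        lid = lesion.lesion_id if lesion.lesion_id != "lesion" else f"lesion{i:03d}"
        fields, fp, info = design_lesion_fields(spec, lesion, rng)
        if (occupied & fp).any():
            raise ValueError(f"lesion {lid} overlaps a previous lesion")
        occupied |= fp
        for d in DIRECTIONS:
            adc_fields[d] = np.where(fields[d] != spec.background_adc, fields[d], adc_fields[d])
        rois[lid] = _roi_from_footprint(fp, spec.pixel_area)
        rows.append(
            {
                "lesion_id": lid,
                "pathology": lesion.pathology,
                "morphology": lesion.morphology,
                "truth_mean_adc": info["realized_mean_adc"],
                "truth_anisotropy": lesion.anisotropy,
                "mean_adc_target": lesion.mean_adc_target,
                "dark_value": info["dark_value"],
                "dark_fraction": info["dark_fraction"],
                "n_footprint_voxels": info["n_footprint_voxels"],
            }
        )

    signals: Dict[Tuple[str, int], np.ndarray] = {}
    s0 = np.full(spec.grid_shape, spec.s0_level)
    for d in DIRECTIONS:
        sb = spec.s0_level * np.exp(-b1 * adc_fields[d])
        signals[(d, b0)] = _rician(s0, spec.noise_sigma, rng)
        signals[(d, b1)] = _rician(sb, spec.noise_sigma, rng)

    study = DirectionalDWIStudy(
        signals=signals, spacing=spec.spacing, study_id=study_id
    )
    return PhantomStudy(
        study=study, rois=rois, truth=pd.DataFrame(rows), adc_fields=adc_fields
    )


# ---------------------------------------------------------------------------
# cohorts

#: joint class mix of the emulated cohort: 69 lesions with 51 masses
#: (24 benign / 27 malignant) and 18 non-masses (7 benign / 11 malignant)
DEFAULT_CLASS_MIX: Dict[Tuple[str, str], float] = {
    ("benign", "mass"): 24 / 69,
    ("malignant", "mass"): 27 / 69,
    ("benign", "non-mass"): 7 / 69,
    ("malignant", "non-mass"): 11 / 69,
}

#: per-class sampling parameters for lesion mean ADC (normal, truncated) and
#: anisotropy (uniform).  Malignant masses include a high-ADC anisotropic
#: subtype -- the lesions the directional-variance filter exists to catch.
DEFAULT_ADC_DISTRIBUTIONS: Dict[Tuple[str, str], dict] = {
    ("benign", "mass"): {
        "adc": (1.55e-3, 0.25e-3),
        "adc_bounds": (1.05e-3, 2.05e-3),
        "anisotropy": (0.0, 0.05),
    },
    ("malignant", "mass"): {
        "adc": (1.05e-3, 0.15e-3),
        "adc_bounds": (0.85e-3, 1.45e-3),
        "anisotropy": (0.0, 0.1),
        "high_adc_prob": 0.15,
        "high_adc": (1.62e-3, 0.08e-3),
        "high_adc_bounds": (1.5e-3, 1.72e-3),
        "high_adc_anisotropy": (0.35, 0.5),
    },
    ("benign", "non-mass"): {
        "adc": (1.5e-3, 0.25e-3),
        "adc_bounds": (1.0e-3, 2.0e-3),
        "anisotropy": (0.0, 0.1),
    },
    ("malignant", "non-mass"): {
        "adc": (1.3e-3, 0.35e-3),
        "adc_bounds": (0.9e-3, 2.0e-3),
        "anisotropy": (0.0, 0.2),
    },
}


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mu, lo, hi))


def sample_lesion_spec(
    rng: np.random.Generator,
    spec: PhantomSpec,
    pathology: str,
    morphology: str,
    params: Optional[dict] = None,
    lesion_id: str = "lesion",
) -> LesionSpec:
    """Draw one lesion's ground-truth parameters for a given class."""
    p = params if params is not None else DEFAULT_ADC_DISTRIBUTIONS[(pathology, morphology)]
    high = rng.random() < p.get("high_adc_prob", 0.0)
    mu, sd = p["high_adc"] if high else p["adc"]
    lo, hi = p["high_adc_bounds"] if high else p["adc_bounds"]
    target = _truncated_normal(rng, mu, sd, lo, hi)
    a_lo, a_hi = p["high_adc_anisotropy"] if high else p["anisotropy"]
    aniso = float(rng.uniform(a_lo, a_hi))

    in_plane = float(rng.uniform(9.0, 18.0))  # mm: index areas ~0.6-2.5 cm^2
    through = float(rng.uniform(5.5, 9.0))  # mm: 2-4 slices at 2.5 mm
    center = (
        spec.grid_shape[0] // 2,
        spec.grid_shape[1] // 2,
        spec.grid_shape[2] // 2,
    )
    return LesionSpec(
        center=center,
        morphology=morphology,
        pathology=pathology,
        mean_adc_target=target,
        anisotropy=aniso,
        orientation=int(rng.integers(0, 2)),
        extent=(through, in_plane, in_plane * float(rng.uniform(0.7, 1.0))),
        lesion_id=lesion_id,
    )


def sample_lesion_records(
    n_lesions: int,
    seed: int = 0,
    class_mix: Optional[Mapping[Tuple[str, str], float]] = None,
):
    """Feature-level cohort: lesion records with mean ADC and SDAC drawn
    directly from the per-class distributions, skipping image synthesis.

    Useful for statistical properties of the filtering and evaluation
    stages, where only the joint distribution of (pathology, morphology,
    mean ADC, SDAC) matters.  SDAC values approximate what the imaging
    pipeline measures: near zero for isotropic lesions, large for the
    anisotropic malignant-mass subtype.
    """
    from .filters import LesionRecord

    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    mix = dict(class_mix) if class_mix is not None else DEFAULT_CLASS_MIX
    probs = np.asarray(list(mix.values()), float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    classes = list(mix.keys())
    records = []
    for i, ci in enumerate(rng.choice(len(classes), size=n_lesions, p=probs)):
        pathology, morphology = classes[ci]
        p = DEFAULT_ADC_DISTRIBUTIONS[(pathology, morphology)]
        high = rng.random() < p.get("high_adc_prob", 0.0)
        mu, sd = p["high_adc"] if high else p["adc"]
        lo, hi = p["high_adc_bounds"] if high else p["adc_bounds"]
        target = _truncated_normal(rng, mu, sd, lo, hi)
        sdac_val = None
        if morphology == "mass":
            sdac_val = float(rng.uniform(10.0, 40.0)) if high else abs(rng.normal(1.0, 1.2))
        records.append(
            LesionRecord(
                lesion_id=f"L{i:03d}",
                pathology=pathology,
                morphology=morphology,
                mean_adc=target,
                sdac=sdac_val,
            )
        )
    return records


def generate_cohort(
    n_lesions: int,
    class_mix: Optional[Mapping[Tuple[str, str], float]] = None,
    adc_distributions: Optional[Mapping[Tuple[str, str], dict]] = None,
    seed: int = 0,
    phantom_spec: Optional[PhantomSpec] = None,
) -> Tuple[List[PhantomStudy], pd.DataFrame]:
    """Simulate a cohort of single-lesion phantom studies.

    Each lesion's class is drawn from ``class_mix`` (a mapping
    (pathology, morphology) -> probability summing to 1), its parameters
    from the per-class distributions, and its study from an independent
    child seed.  Returns the studies and the ground-truth cohort table.
    """
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    mix = dict(class_mix) if class_mix is not None else DEFAULT_CLASS_MIX
    probs = np.asarray(list(mix.values()), float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    dists = dict(adc_distributions) if adc_distributions is not None else DEFAULT_ADC_DISTRIBUTIONS
    base_spec = phantom_spec if phantom_spec is not None else PhantomSpec()

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    classes = list(mix.keys())
    draws = rng.choice(len(classes), size=n_lesions, p=probs)

    studies: List[PhantomStudy] = []
    rows: List[pd.DataFrame] = []
    child_seeds = ss.spawn(n_lesions + 1)[1:]
    for i, (ci, child) in enumerate(zip(draws, child_seeds)):
        pathology, morphology = classes[ci]
        lid = f"L{i:03d}"
        lesion_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        study_spec = replace(base_spec, seed=lesion_seed)
        lrng = np.random.default_rng(child)
        lesion = sample_lesion_spec(
            lrng, study_spec, pathology, morphology, dists.get((pathology, morphology)), lid
        )
        ph = generate_phantom(study_spec, [lesion], study_id=lid)
        studies.append(ph)
        rows.append(ph.truth)

    table = pd.concat(rows, ignore_index=True)
    return studies, table
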
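# Methods

`dwifilters` implements a lesion-triage pipeline for breast diffusion-weighted
MRI (DWI): starting from directional DWI signal volumes and radiologist ROIs,
it measures lesion mean ADC and a directional-variance feature (SDAC), applies
two sequential filters that force suspicious lesions to biopsy, and evaluates
the resulting classification at the cohort level. Because the clinical cohort
this methodology was developed on is not publicly available, the package ships
a synthetic phantom generator with fully known ground truth; every empirical
statement below is computed by the test suite or the analysis scripts.

## ADC mapping

Signals follow the mono-exponential decay model S(b) = S0·exp(−b·ADC) with
b ∈ {0, 800} s/mm². With a single non-zero b-value the estimate is the
two-point solution ADC = ln(S0/Sb)/b, computed voxelwise and independently for
each diffusion-encoding direction P (phase), R (readout), S (slice). Voxels
where either signal is non-positive, or where the estimate is negative, are
clamped to 0 and counted in a per-study flag log. Zero reads as maximally
restricted diffusion — cancer-like under every threshold — which is the
conservative direction for a never-miss-cancer application. ADC is carried in
mm²/s throughout; the conventional 10⁻³ display factor appears only at the
file boundary (NIfTI maps and CSV columns are in 10⁻³ mm²/s).

The pixel-classification map is the voxelwise arithmetic mean of the three
directional ADC maps. "Augmented" maps — directional ADC multiplied by the
same direction's b = 0 signal — drive the lesion-core modelling; they are used
only ordinally (threshold sweeps), so the arbitrary signal units cancel.

## ROI handling

ROIs are drawn per axial slice at annotation (review-monitor) resolution and
mapped to the native grid by bilinear interpolation followed by binarisation.
The binarisation threshold is searched over [0.25, 0.75] — a coarse 0.05 grid
plus every interpolated value observed in that band — and chosen to minimise
the discrepancy between the output's physical area and the annotation's. The
observed-value candidates matter: with only the coarse grid, interpolation
plateaus can leave the area error above one native pixel on ordinary convex
shapes.

Each per-slice mask is then dilated once with a 3×3 square structuring
element (a 1-pixel band in all directions including diagonals, clipped at the
image border). Lesion mean ADC is averaged over the dilated ROI across all
annotated slices; a configuration switch (`mean_on_dilated_roi`) reverts to
the raw annotation. The annotated slice with the largest mask is the index
slice; ties break to the lowest slice index.

## Lesion-core modelling

For each direction, a 3D volume of interest (VOI) is built from the voxels of
the augmented map strictly below a threshold, restricted to annotated slices,
decomposed into 26-connected 3D components (configurable to 6), and reduced
to the components that intersect the dilated ROI on any annotated slice —
off-lesion dark tissue is discarded. The VOI is monotone in the threshold.

The threshold is swept over every unique augmented value observed inside the
dilated ROI across annotated slices (each value v swept as the smallest float
above v, since the comparison is strict) plus the slab maximum, and chosen to
maximise the overlap between the VOI cross-section at the index slice and the
ROI mask there. The overlap score is the Dice coefficient by default
(configurable to intersection fraction); ties break to the lowest threshold.
The lesion core for that direction is the optimal cross-section intersected
with the ROI index mask. Cores are computed on the index slice only. Masses
get cores and SDAC; non-mass lesions are filtered on morphology alone and
skip core modelling.

## SDAC

ROI pixels are classified on the mean ADC map: cancer-like when strictly
below 1.37 × 10⁻³ mm²/s, benign-like at or above it — identical across
directions, so directionality enters only through core membership. For each
direction, the cancer-like area is the count of cancer-like pixels inside
that direction's core times the pixel area (mm²). SDAC is the sample standard
deviation (divisor n − 1 = 2) of the three areas; divisor n would not
reproduce the reference value 8.27 mm² for the areas
{39.06, 42.19, 26.56} mm², which the test suite checks.

## Filters and evaluation

* Mass filter: non-mass lesions get ADC-M = 0; masses pass through.
* SDAC filter: masses with SDAC ≥ 4.5 mm² get ADC-MD = 0 (equality is treated
  as suspicious — the conservative choice; the published behaviour is defined
  only for strict inequalities). The threshold default 4.5 mm² is the
  midpoint of the reported optimal range [4.0, 5.0] mm² and is configurable.

Both filters only zero or pass values, so ADC-MD ≤ ADC-M ≤ mean ADC holds per
lesion and the 100%-sensitivity threshold ADC_MaxMalig (the maximum filtered
value over malignant lesions) is non-increasing across ADC → ADC-M → ADC-MD.

Evaluation treats malignant as positive. The 100%-sensitivity method counts
benign lesions strictly above ADC_MaxMalig as potentially avoidable biopsies;
a lesion exactly at the threshold is biopsied, since the threshold is attained
by a malignant lesion. The likelihood-of-malignancy method fixes the cutoff at
1.5 × 10⁻³ mm²/s (configurable) and reports LR⁻ = (1 − sensitivity)/specificity,
undefined when specificity is 0, with the post-test probability chained
through pre-test odds. Paired classifiers are compared with the exact McNemar
test, implemented directly as a one-sided binomial tail on discordant counts
(no mid-p correction). ROC output is the set of operating points — one per
unique threshold value plus the all-benign point — with no AUC, which the
mass of zero-assigned values would render uninformative.

## Synthetic phantoms

A phantom is a homogeneous fibroglandular background (default ADC
1.8 × 10⁻³ mm²/s, a standard value for dense breast tissue) on the clinical
acquisition geometry (1.25 mm square pixels, 2.5 mm slices, default grid
8–10 slices of 40–48²; S0 = 1000 arbitrary units). Masses are ellipsoids;
non-mass lesions are 3–8 small blobs strung along a curved in-plane path
(segmental pattern — only the morphology class matters downstream).

Each lesion's three directional ADC fields share a footprint and differ only
in their "dark" (restricted-diffusion) region, a nested subset of the
footprint ranked by per-slice distance from the lesion boundary. The dark
fractions follow the pattern (1 + a, 1 + a, 1 − 2a) × core fraction for
directions (P, R, S), which sums to zero effect on the direction-averaged
field and keeps the growth band dark in two of three directions, so the band
stays cancer-like on the mean-ADC map and the SDAC response to the anisotropy
parameter a is linear. Two guards keep the mechanism well-posed: the shrink
direction's fraction is floored (at 0.10 of the footprint or 12 voxels,
whichever is larger) because a near-empty dark set cannot anchor its core
model against the saturating threshold, with the deficit redistributed to the
growing directions; and no fraction exceeds 0.98. At a = 0 the three fields
are identical and SDAC is exactly 0 on noise-free phantoms; mean SDAC is
monotone in a until these guards saturate.

The lesion interior is solved in closed form so the direction-averaged field,
averaged over the 1-pixel-dilated ROI, equals the requested lesion mean ADC
exactly. Preferred solution: dark region at a fixed 0.7 × 10⁻³ mm²/s with a
free rim at or above background (a bright rim lets a high-mean lesion still
carry a sizeable dark core — the lesion type the SDAC filter exists to
catch); a rim below background is rejected because it would merge the core
into one uniformly dark blob. When the rim solve is unphysical the rim pins
to background and the dark value is solved instead, clamped at 10⁻⁵ mm²/s
(clamping is recorded and the realized mean stored as truth). Noise is
Rician — the magnitude of the complex signal with independent Gaussian
perturbations of both channels — applied per direction and b-value; the
cohort default sigma is 15 signal units (1.5% of S0, in the range of clinical
breast DWI SNR).

Cohort sampling mirrors the emulated study: 69 lesions, joint class mix
24/27/7/11 (benign-mass / malignant-mass / benign-non-mass /
malignant-non-mass), giving 55.1% prevalence and 26.1% non-mass in
expectation. Per-class mean-ADC distributions are truncated normals chosen
once as clinically plausible (no public calibration data exists): benign
masses 1.55 ± 0.25, malignant masses 1.05 ± 0.15 with a 15% high-ADC
anisotropic subtype at 1.62 ± 0.08 (anisotropy 0.4–0.7), benign non-masses
1.50 ± 0.25, malignant non-masses 1.30 ± 0.35 (all × 10⁻³ mm²/s). The
malignant non-mass tail and the anisotropic mass subtype are the lesion types
that inflate the baseline 100%-sensitivity threshold and that the two filters
remove. In-plane lesion extents are drawn uniformly from 9–18 mm (index-slice
areas roughly 0.6–2.5 cm²).

What the phantoms do not emulate: breast anatomy, fat suppression, EPI
distortion, motion, coil profiles, partial-volume gradients at lesion
margins, or textured lesion interiors. Passing tests therefore demonstrate
correctness of the computational chain and the direction of the filtering
effects under controlled conditions, not clinical performance; the published
cohort-level numbers are specific to the non-public data and are not
reproduced here.

## Numerical choices and degenerate inputs

* Strict inequalities everywhere they are specified: cancer-like is
  ADC < 1.37 × 10⁻³; a VOI voxel is augmented < threshold; an avoidable biopsy
  is value > threshold; SDAC ≥ threshold filters.
* Threshold sweeps are exact over observed values (no quantisation); float
  candidates use `nextafter` to convert strict comparisons into inclusive
  sweeps.
* Empty VOIs are allowed; if no candidate threshold yields any index-slice
  overlap the core model is flagged degenerate with an empty core (in
  practice the saturating candidate always yields some overlap).
* McNemar with zero discordant pairs returns p = 1.
* LR⁻ with zero specificity is reported as undefined (null in JSON).
* Problem sizes in the tests and the acceptance script (8 × 40 × 40 grids,
  69-lesion cohorts, 20 replicates per anisotropy level) are the package's
  default study conditions for synthetic work; they are large enough that
  every filter and threshold operates away from small-sample artefacts.

## Known limitations

* The core model is optimised against the whole ROI on the index slice only;
  per-slice core models are not produced.
* SDAC uses three orthogonal directions and is orientation-dependent; it is
  not a rotation-invariant anisotropy measure (unlike tensor-derived
  fractional anisotropy, which is out of scope).
* DICOM input is not implemented; NIfTI is the sole volume format.
* The phantom's anisotropy control saturates for very dark (core fraction
  near 1) or very small lesions, where the geometry leaves no room for
  per-direction area differences.
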
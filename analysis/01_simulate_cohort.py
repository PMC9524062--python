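#!/usr/bin/env python
"""Simulate the synthetic DWI cohort.

Generates 69 single-lesion phantom studies mirroring the emulated clinical
cohort (55.1% malignant, 26.1% non-mass; 1.25 mm pixels, 2.5 mm slices,
b = 0/800 s/mm^2, Rician noise) with known ground truth.  Volumes and ROI
masks go to scratch/cohort/ (binary NIfTI); the ground-truth table goes to
results/cohort.csv.

Run from the repository root:  python analysis/01_simulate_cohort.py [seed]
"""

import sys
from pathlib import Path

from dwifilters import PhantomSpec, generate_cohort
from dwifilters import io as dio

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
N_LESIONS = 69
SPEC = PhantomSpec(grid_shape=(8, 40, 40), noise_sigma=15.0)


def main() -> None:
    out = Path("scratch/cohort")
    results = Path("results")
    results.mkdir(exist_ok=True)

    studies, truth = generate_cohort(N_LESIONS, seed=SEED, phantom_spec=SPEC)
    for ph in studies:
        dio.write_phantom_study(ph, out / ph.study.study_id)
    meta = truth.copy()
    dio.write_cohort_csv(meta, out / "cohort.csv")
    dio.write_cohort_csv(meta, results / "cohort.csv")

    n_mal = (truth.pathology == "malignant").sum()
    n_nm = (truth.morphology == "non-mass").sum()
    print(f"wrote {len(studies)} studies to {out}")
    print(f"  malignant: {n_mal}/{len(truth)} ({100 * n_mal / len(truth):.1f}%)")
    print(f"  non-mass:  {n_nm}/{len(truth)} ({100 * n_nm / len(truth):.1f}%)")
    print(f"  truth table: {results / 'cohort.csv'}")


if __name__ == "__main__":
    main()
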
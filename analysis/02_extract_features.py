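#!/usr/bin/env python
"""Extract per-lesion features from the simulated cohort.

Runs the imaging pipeline on every study written by 01_simulate_cohort.py:
directional ADC and augmented maps, ROI dilation, per-direction lesion-core
optimisation, SDAC, and the mass/directional filters.  Writes
results/features.csv with measured mean ADC, SDAC, ADC-M and ADC-MD per
lesion (ADC columns in 1e-3 mm^2/s).

Run from the repository root after 01:  python analysis/02_extract_features.py
"""

from pathlib import Path

import pandas as pd

from dwifilters import io as dio
from dwifilters.pipeline import run_cohort_directory


def main() -> None:
    root = Path("scratch/cohort")
    if not root.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    report, features = run_cohort_directory(root)

    truth = dio.read_cohort_csv(root / "cohort.csv")
    features = features.merge(
        truth[["lesion_id", "truth_mean_adc", "truth_anisotropy"]], on="lesion_id"
    )
    features["mean_adc_error_pct"] = 100 * (
        features.mean_adc / features.truth_mean_adc - 1.0
    )
    dio.write_cohort_csv(features, Path("results/features.csv"))

    masses = features[features.morphology == "mass"]
    print(f"features for {len(features)} lesions -> results/features.csv")
    print(f"  mean |ADC error| vs truth: {features.mean_adc_error_pct.abs().mean():.2f}%")
    print(f"  masses with SDAC >= 4.5 mm^2: {(masses.sdac >= 4.5).sum()}/{len(masses)}")


if __name__ == "__main__":
    main()
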
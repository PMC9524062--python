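#!/usr/bin/env python
"""Evaluate the filtered cohort with both decision methods.

From results/features.csv, applies the non-mass and SDAC filters and
computes, for ADC / ADC-M / ADC-MD: the 100%-sensitivity threshold
(ADC_MaxMalig) and the avoidable-biopsy count among benign lesions; the
LM-method confusion at the fixed 1.5e-3 mm^2/s cutoff with LR- and
post-test probability; ROC operating points; and the exact McNemar
comparison of ADC vs ADC-MD at 100% sensitivity.  Writes
results/report.json and results/roc_points.csv.

Run from the repository root after 02:  python analysis/03_evaluate_cohort.py
"""

from pathlib import Path

import pandas as pd

from dwifilters import io as dio
from dwifilters.pipeline import PipelineConfig, evaluate, records_from_table


def main() -> None:
    features = dio.read_cohort_csv(Path("results/features.csv"))
    cfg = PipelineConfig()
    cohort = records_from_table(features, cfg)
    report = evaluate(cohort, cfg)
    dio.write_report(report.to_dict(), Path("results/report.json"))

    roc_rows = [
        {"variant": v, "fpr": fpr, "sensitivity": sens}
        for v, pts in report.roc.items()
        for fpr, sens in pts
    ]
    pd.DataFrame(roc_rows).to_csv("results/roc_points.csv", index=False)

    print(f"cohort: {report.n_malignant} malignant / {report.n_benign} benign, "
          f"prevalence {report.prevalence:.3f}")
    for v in ("ADC", "ADC-M", "ADC-MD"):
        count, pct = report.avoidable[v]
        lr = report.lm[v]["lr_minus"]
        lr_s = "undefined" if lr is None else f"{lr:.2f}"
        print(f"  {v:7s} ADC_MaxMalig {report.adc_max_malig[v] * 1e3:.2f}e-3  "
              f"avoidable {count}/{report.n_benign} ({pct:.0f}%)  LR- {lr_s}")
    print(f"  exact McNemar (ADC vs ADC-MD, one-sided): p = {report.mcnemar_p:.4g}")
    print("wrote results/report.json and results/roc_points.csv")


if __name__ == "__main__":
    main()
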
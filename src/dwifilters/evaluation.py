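"""Cohort-level diagnostic evaluation of (filtered) ADC thresholding.

Two evaluation schemes are implemented, with malignant lesions as positives
and benign as negatives:

* 100%-sensitivity method: the operating threshold is ADC_MaxMalig, the
  maximum (filtered) ADC over malignant lesions; benign lesions strictly
  above it are "potentially avoidable biopsies", and sensitivity is 1 by
  construction.
* likelihood-of-malignancy (LM) method: a fixed ADC cutoff (1.5e-3 mm^2/s)
  labels lesions above it benign; performance is the negative likelihood
  ratio LR- = (1 - sensitivity) / specificity, with post-test probability
  chained through pretest odds:

      odds_pre  = p_pre / (1 - p_pre)
      odds_post = odds_pre * LR-
      p_post    = odds_post / (1 + odds_post)

Paired classifiers are compared with the exact (binomial) McNemar test on
discordant pairs, one-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .filters import LesionRecord

VARIANT_FIELDS = {"ADC": "mean_adc", "ADC-M": "adc_m", "ADC-MD": "adc_md"}


@dataclass
class CohortTable:
    rows: List[LesionRecord]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty cohort")

    @property
    def n_benign(self) -> int:
        return sum(r.pathology == "benign" for r in self.rows)

    @property
    def n_malignant(self) -> int:
        return sum(r.pathology == "malignant" for r in self.rows)

    @property
    def prevalence(self) -> float:
        """Fraction of lesions that are malignant (pretest probability)."""
        return self.n_malignant / len(self.rows)

    @property
    def nonmass_fraction(self) -> float:
        return sum(r.morphology == "non-mass" for r in self.rows) / len(self.rows)

    def values(self, variant: str) -> np.ndarray:
        f = VARIANT_FIELDS[variant]
        vals = [getattr(r, f) for r in self.rows]
        if any(v is None for v in vals):
            raise ValueError(f"variant {variant}: filters not applied to all rows")
        return np.asarray(vals, float)

    def labels(self) -> np.ndarray:
        """True for malignant (positive), False for benign (negative)."""
        return np.asarray([r.pathology == "malignant" for r in self.rows])


def adc_max_malig(cohort: CohortTable, variant: str = "ADC") -> float:
    """Maximum (filtered) ADC value over the malignant lesions, mm^2/s."""
    vals = cohort.values(variant)[cohort.labels()]
    if vals.size == 0:
        raise ValueError("cohort has no malignant lesions")
    return float(vals.max())


def avoidable_biopsies(
    cohort: CohortTable, variant: str, threshold: float
) -> Tuple[int, float]:
    """Benign lesions with value strictly above the threshold.

    Returns (count, percent of benign).  A lesion exactly at the threshold
    is biopsied: ADC_MaxMalig is attained by a malignant lesion, which must
    never be classified benign.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    benign_vals = cohort.values(variant)[~cohort.labels()]
    if benign_vals.size == 0:
        raise ValueError("cohort has no benign lesions")
    count = int((benign_vals > threshold).sum())
    return count, 100.0 * count / benign_vals.size


def confusion_at_threshold(
    cohort: CohortTable, variant: str, threshold: float
) -> Tuple[float, float, Optional[float]]:
    """(sensitivity, specificity, LR-) at a fixed ADC threshold.

    A lesion is predicted benign iff its value strictly exceeds the
    threshold.  LR- = (1 - sensitivity) / specificity; None when the
    specificity is 0 (undefined).
    """
    labels = cohort.labels()
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    vals = cohort.values(variant)
    pred_benign = vals > threshold
    tp = int((labels & ~pred_benign).sum())
    fn = int((labels & pred_benign).sum())
    tn = int((~labels & pred_benign).sum())
    fp = int((~labels & ~pred_benign).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    lr_minus = (1.0 - sens) / spec if spec > 0 else None
    return sens, spec, lr_minus


def posttest_probability(prob_pretest: float, lr_minus: float) -> float:
    """Post-test probability of malignancy after a negative (benign) call."""
    if not 0.0 < prob_pretest < 1.0:
        raise ValueError("pretest probability must lie strictly in (0, 1)")
    if lr_minus < 0:
        raise ValueError("LR- must be non-negative")
    odds_pre = prob_pretest / (1.0 - prob_pretest)
    odds_post = odds_pre * lr_minus
    return odds_post / (1.0 + odds_post)


def exact_mcnemar(b: int, c: int) -> float:
    """One-sided exact McNemar test on discordant pairs.

    ``b`` counts pairs where the second classifier is correct and the first
    wrong; ``c`` the reverse.  Under the null the discordant pairs split
    Binomial(b + c, 1/2); the one-sided p-value is P(X >= b).  With no
    discordant pairs p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return sum(math.comb(n, k) for k in range(b, n + 1)) / 2.0**n


def mcnemar_from_predictions(
    correct_1: Sequence[bool], correct_2: Sequence[bool]
) -> float:
    """Exact one-sided McNemar p from per-lesion correctness of two methods."""
    c1 = np.asarray(correct_1, bool)
    c2 = np.asarray(correct_2, bool)
    if c1.shape != c2.shape:
        raise ValueError("paired correctness vectors must have equal length")
    b = int((c2 & ~c1).sum())
    c = int((c1 & ~c2).sum())
    return exact_mcnemar(b, c)


def roc_points(cohort: CohortTable, variant: str) -> List[Tuple[float, float]]:
    """ROC operating points (1 - specificity, sensitivity), one per unique
    threshold, plus the all-benign point (0, 0).

    No AUC is computed: filtered variants assign many lesions the value 0,
    collapsing the lower part of the curve and making AUC uninformative.
    """
    labels = cohort.labels()
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    vals = cohort.values(variant)
    pts = {(0.0, 0.0)}  # threshold below every value: everything called benign
    for t in np.unique(vals):
        sens, spec, _ = confusion_at_threshold(cohort, variant, float(t))
        pts.add((round(1.0 - spec, 12), round(sens, 12)))
    return sorted(pts)


@dataclass
class EvalReport:
    """Cohort evaluation across ADC / ADC-M / ADC-MD variants."""

    n_benign: int
    n_malignant: int
    prevalence: float
    nonmass_percent: float
    adc_max_malig: Dict[str, float]
    avoidable: Dict[str, Tuple[int, float]]
    lm_threshold: float
    lm: Dict[str, Dict[str, Optional[float]]]
    mcnemar_p: Optional[float]
    roc: Dict[str, List[Tuple[float, float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_benign": self.n_benign,
            "n_malignant": self.n_malignant,
            "prevalence": self.prevalence,
            "nonmass_percent": self.nonmass_percent,
            "adc_max_malig_1e-3_mm2_s": {k: v * 1e3 for k, v in self.adc_max_malig.items()},
            "avoidable_biopsies": {
                k: {"count": c, "percent": p} for k, (c, p) in self.avoidable.items()
            },
            "lm_threshold_1e-3_mm2_s": self.lm_threshold * 1e3,
            "lm": self.lm,
            "mcnemar_p_adc_vs_adc_md": self.mcnemar_p,
            "roc": {k: [list(p) for p in v] for k, v in self.roc.items()},
        }


def evaluate_cohort(
    cohort: CohortTable,
    lm_threshold: float = 1.5e-3,
    include_roc: bool = True,
) -> EvalReport:
    """Full evaluation: both methods on all three variants, plus McNemar.

    The McNemar comparison pairs the 100%-sensitivity classifications under
    ADC alone and under ADC-MD, each at its own ADC_MaxMalig threshold (both
    classify every malignant correctly, so discordance is confined to benign
    lesions).
    """
    variants = ("ADC", "ADC-M", "ADC-MD")
    maxmalig = {v: adc_max_malig(cohort, v) for v in variants}
    avoidable = {v: avoidable_biopsies(cohort, v, maxmalig[v]) for v in variants}

    lm: Dict[str, Dict[str, Optional[float]]] = {}
    for v in variants:
        sens, spec, lr = confusion_at_threshold(cohort, v, lm_threshold)
        entry: Dict[str, Optional[float]] = {
            "sensitivity": sens,
            "specificity": spec,
            "lr_minus": lr,
        }
        if lr is not None:
            p_pre = cohort.prevalence
            entry["prob_pretest"] = p_pre
            entry["prob_posttest"] = posttest_probability(p_pre, lr)
        lm[v] = entry

    labels = cohort.labels()
    correct = {}
    for v in ("ADC", "ADC-MD"):
        pred_benign = cohort.values(v) > maxmalig[v]
        correct[v] = pred_benign != labels  # benign call correct iff lesion benign
    p = mcnemar_from_predictions(correct["ADC"], correct["ADC-MD"])

    return EvalReport(
        n_benign=cohort.n_benign,
        n_malignant=cohort.n_malignant,
        prevalence=cohort.prevalence,
        nonmass_percent=100.0 * cohort.nonmass_fraction,
        adc_max_malig=maxmalig,
        avoidable=avoidable,
        lm_threshold=lm_threshold,
        lm=lm,
        mcnemar_p=p,
        roc={v: roc_points(cohort, v) for v in variants} if include_roc else {},
    )
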
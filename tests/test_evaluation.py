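import numpy as np
import pytest
from scipy import stats

from dwifilters import (
    CohortTable,
    LesionRecord,
    adc_max_malig,
    apply_filters,
    avoidable_biopsies,
    confusion_at_threshold,
    evaluate_cohort,
    exact_mcnemar,
    posttest_probability,
    roc_points,
    sample_lesion_records,
)


def make_cohort(benign_values, malignant_values):
    rows = []
    for i, v in enumerate(benign_values):
        rows.append(apply_filters(LesionRecord(f"b{i}", "benign", "mass", v, sdac=0.0)))
    for i, v in enumerate(malignant_values):
        rows.append(apply_filters(LesionRecord(f"m{i}", "malignant", "mass", v, sdac=0.0)))
    return CohortTable(rows=rows)


class TestAdcMaxMalig:
    def test_single_malignant(self):
        c = make_cohort([1.8e-3], [1.2e-3])
        assert adc_max_malig(c) == pytest.approx(1.2e-3)

    def test_max_over_malignant_rows(self):
        c = make_cohort([2.0e-3], [1.89e-3, 0.0, 1.53e-3])
        assert adc_max_malig(c) == pytest.approx(1.89e-3)

    def test_matches_linear_scan_oracle(self, rng):
        vals = rng.random(30) * 2e-3
        c = make_cohort(vals[:10], vals[10:])
        assert adc_max_malig(c) == pytest.approx(max(vals[10:]))


class TestAvoidableBiopsies:
    def test_threshold_at_global_max_gives_zero(self):
        c = make_cohort([1.6e-3, 1.9e-3], [1.2e-3])
        count, _ = avoidable_biopsies(c, "ADC", 1.9e-3)
        assert count == 0

    def test_strict_comparison(self):
        c = make_cohort([1.6e-3, 1.9e-3, 1.2e-3], [1.0e-3])
        count, percent = avoidable_biopsies(c, "ADC", 1.53e-3)
        assert count == 2
        assert percent == pytest.approx(100 * 2 / 3)

    def test_sensitivity_is_one_at_maxmalig_over_random_cohorts(self, rng):
        """At each variant's ADC_MaxMalig no malignant is called benign."""
        for trial in range(100):
            recs = sample_lesion_records(40, seed=trial)
            c = CohortTable(rows=[apply_filters(r) for r in recs])
            if c.n_benign == 0 or c.n_malignant == 0:
                continue
            for variant in ("ADC", "ADC-M", "ADC-MD"):
                t = adc_max_malig(c, variant)
                sens, _, _ = confusion_at_threshold(c, variant, t)
                assert sens == 1.0

    def test_filter_ordering_of_thresholds(self):
        """ADC_MaxMalig is non-increasing across ADC -> ADC-M -> ADC-MD."""
        for seed in range(100):
            recs = sample_lesion_records(40, seed=1000 + seed)
            c = CohortTable(rows=[apply_filters(r) for r in recs])
            if c.n_malignant == 0:
                continue
            t = [adc_max_malig(c, v) for v in ("ADC", "ADC-M", "ADC-MD")]
            assert t[0] >= t[1] >= t[2]


class TestConfusion:
    def test_perfect_separation(self):
        c = make_cohort([1.8e-3, 1.9e-3], [1.0e-3, 1.1e-3])
        sens, spec, lr = confusion_at_threshold(c, "ADC", 1.5e-3)
        assert (sens, spec, lr) == (1.0, 1.0, 0.0)

    def test_reference_arithmetic(self):
        """TP 37, FN 1, TN 13, FP 18 -> LR- = (1/38)/(13/31)."""
        benign = [2.0e-3] * 13 + [1.0e-3] * 18  # 13 above threshold (TN)
        malignant = [1.0e-3] * 37 + [2.0e-3]  # 1 above threshold (FN)
        c = make_cohort(benign, malignant)
        sens, spec, lr = confusion_at_threshold(c, "ADC", 1.5e-3)
        assert sens == pytest.approx(37 / 38)
        assert spec == pytest.approx(13 / 31)
        assert lr == pytest.approx((1 / 38) / (13 / 31))
        assert lr == pytest.approx(0.0627, abs=5e-4)

    def test_undefined_lr_when_specificity_zero(self):
        c = make_cohort([1.0e-3], [1.2e-3])
        _, spec, lr = confusion_at_threshold(c, "ADC", 1.5e-3)
        assert spec == 0.0 and lr is None


class TestPosttestProbability:
    def test_neutral_test_keeps_prior(self):
        assert posttest_probability(0.5, 1.0) == pytest.approx(0.5)

    def test_zero_lr_gives_zero(self):
        assert posttest_probability(0.3, 0.0) == 0.0

    def test_hand_calculator_chain(self):
        assert posttest_probability(0.551, 0.06) == pytest.approx(0.0686, abs=5e-4)

    def test_monotone_in_both_arguments(self):
        ps = [posttest_probability(p, 0.3) for p in (0.1, 0.3, 0.5, 0.7)]
        assert ps == sorted(ps)
        ls = [posttest_probability(0.5, l) for l in (0.0, 0.1, 0.5, 1.0)]
        assert ls == sorted(ls)

    def test_degenerate_prior_rejected(self):
        for p in (0.0, 1.0):
            with pytest.raises(ValueError):
                posttest_probability(p, 0.5)


class TestExactMcNemar:
    def test_three_wins_no_losses(self):
        assert exact_mcnemar(3, 0) == pytest.approx(0.125)

    def test_ten_wins_no_losses(self):
        assert exact_mcnemar(10, 0) == pytest.approx(2.0**-10)

    def test_symmetric_counts_not_significant(self):
        for n in (1, 4, 9):
            assert exact_mcnemar(n, n) >= 0.5

    def test_no_discordant_pairs(self):
        assert exact_mcnemar(0, 0) == 1.0

    def test_matches_binomial_oracle_all_counts_to_20(self):
        for n in range(1, 21):
            for b in range(n + 1):
                expected = stats.binomtest(b, n, 0.5, alternative="greater").pvalue
                assert exact_mcnemar(b, n - b) == pytest.approx(expected, rel=1e-12)


class TestRocPoints:
    def test_perfect_separation_contains_ideal_point(self):
        c = make_cohort([1.8e-3, 1.9e-3], [1.0e-3, 1.1e-3])
        assert (0.0, 1.0) in set(roc_points(c, "ADC"))

    def test_all_equal_values_degenerate_endpoints(self):
        c = make_cohort([1.5e-3, 1.5e-3], [1.5e-3])
        assert set(roc_points(c, "ADC")) == {(0.0, 0.0), (1.0, 1.0)}

    def test_matches_threshold_sweep_oracle(self, rng):
        vals = np.round(rng.random(24), 2) * 1e-3
        c = make_cohort(vals[:12], vals[12:])
        labels = np.array([False] * 12 + [True] * 12)
        expected = {(0.0, 0.0)}
        for t in np.unique(vals):
            benign_call = vals > t
            sens = ((labels) & ~benign_call).sum() / labels.sum()
            spec = ((~labels) & benign_call).sum() / (~labels).sum()
            expected.add((round(1 - spec, 12), round(sens, 12)))
        assert set(roc_points(c, "ADC")) == expected

    def test_contains_100pct_sensitivity_point(self, rng):
        vals = rng.random(30) * 2e-3
        c = make_cohort(vals[:15], vals[15:])
        t = adc_max_malig(c)
        sens, spec, _ = confusion_at_threshold(c, "ADC", t)
        assert sens == 1.0
        assert (round(1 - spec, 12), 1.0) in set(roc_points(c, "ADC"))


def test_evaluate_cohort_report_structure():
    recs = sample_lesion_records(69, seed=3)
    c = CohortTable(rows=[apply_filters(r) for r in recs])
    report = evaluate_cohort(c)
    d = report.to_dict()
    assert d["n_benign"] + d["n_malignant"] == 69
    assert set(d["adc_max_malig_1e-3_mm2_s"]) == {"ADC", "ADC-M", "ADC-MD"}
    assert 0.0 <= d["mcnemar_p_adc_vs_adc_md"] <= 1.0
    for v, entry in d["lm"].items():
        assert 0.0 <= entry["sensitivity"] <= 1.0
        assert 0.0 <= entry["specificity"] <= 1.0
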
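"""Allele-count spectra, recurrence labels and RP-vs-USH statistics."""

import numpy as np
import pytest
from scipy import stats

from usherspect.simulate import DEFAULT_FOUNDERS
from usherspect.spectrum import (
    SpectrumRow,
    allele_type_breakdown,
    classify_recurrent,
    combination_contingency,
    contingency_test,
    truncating_fraction,
    variant_enrichment,
)

from conftest import make_variant


def row(ac_pair, scope="all_participants", n=8710, key="k"):
    n_het, n_hom = ac_pair
    ac = n_het + 2 * n_hom
    return SpectrumRow(key, n_het, n_hom, ac, ac / (2 * n), scope)


def test_spectrum_row_enforces_allele_identity():
    with pytest.raises(ValueError, match="AC"):
        SpectrumRow("k", 2, 1, 3, 0.001, "all_participants")
    with pytest.raises(ValueError, match="labels"):
        SpectrumRow("k", 2, 1, 4, 0.001, "solved_rp", label="founder")


def test_full_cohort_spectrum_matches_planted_counts(pipeline_result):
    """Most frequent allele: 120 het + 1 hom -> AC 122, ALT freq 0.0070."""
    spectrum = pipeline_result.spectra["all_participants"]
    top = spectrum[0]
    assert (top.n_het, top.n_hom, top.ac) == (120, 1, 122)
    assert round(top.alt_freq, 4) == 0.0070
    assert top.label == "hot_spot"
    second = spectrum[1]
    assert (second.n_het, second.n_hom, second.ac) == (83, 8, 99)
    assert round(second.alt_freq, 4) == 0.0057
    assert second.label == "founder"
    # AC identity and descending order hold on every row
    assert all(r.ac == r.n_het + 2 * r.n_hom for r in spectrum)
    assert all(a.ac >= b.ac for a, b in zip(spectrum, spectrum[1:]))


def test_solved_scope_spectrum_uses_patient_denominators(pipeline_result):
    """Solved-scope frequencies divide by 2 x patients (436 / 380 / 56)."""
    solved = {r.variant_key: r for r in pipeline_result.spectra["solved_patients"]}
    rp = {r.variant_key: r for r in pipeline_result.spectra["solved_rp"]}
    top_key = DEFAULT_FOUNDERS[0].variant.key
    assert (solved[top_key].n_het, solved[top_key].n_hom) == (49, 1)
    assert solved[top_key].ac == 51
    assert round(solved[top_key].alt_freq, 4) == round(51 / 436, 4) == 0.1170
    assert rp[top_key].ac == 48
    assert round(rp[top_key].alt_freq, 4) == round(48 / 380, 4) == 0.1263
    assert all(r.label == "none" for r in pipeline_result.spectra["solved_rp"])


def test_classify_recurrent_reproduces_all_eleven_labels():
    """9 founder + 2 hot-spot labels among the recurrent alleles: presence in
    any non-East-Asian subpopulation marks a hot spot."""
    expected = {
        "c.2802T>G": "hot_spot",
        "c.11156G>A": "hot_spot",
    }
    labels = {}
    for spec in DEFAULT_FOUNDERS:
        r = row((spec.cohort_het, spec.cohort_hom), key=spec.variant.key)
        labels[spec.variant.hgvs_c] = classify_recurrent(r, spec.variant)
    assert sum(1 for v in labels.values() if v == "founder") == 9
    assert sum(1 for v in labels.values() if v == "hot_spot") == 2
    for hgvs, label in expected.items():
        assert labels[hgvs] == label


def test_classify_recurrent_threshold_and_zero_frequencies():
    below = row((9, 0))
    assert classify_recurrent(below, make_variant()) == "none"
    # an explicit zero in a non-EAS column counts as absent -> founder
    zero_non_eas = make_variant(db_freqs={"gnomad_afr": 0.0, "gnomad_eas": 1e-4})
    assert classify_recurrent(row((10, 0)), zero_non_eas) == "founder"
    positive_non_eas = make_variant(db_freqs={"gnomad_afr": 1e-5})
    assert classify_recurrent(row((10, 0)), positive_non_eas) == "hot_spot"


def test_truncating_fraction_from_breakdowns():
    """The emulated cohort's per-consequence allele counts give truncating shares
    36.9% (RP) and 69.6% (USH)."""
    rp = {"missense": 244, "splice_intronic": 75, "frameshift": 44,
          "nonsense": 24, "inframe": 1}
    ush = {"missense": 17, "splice_intronic": 18, "frameshift": 12,
           "nonsense": 9, "inframe": 0}
    assert sum(rp.values()) == 388 and sum(ush.values()) == 56
    assert round(100 * truncating_fraction(rp), 1) == 36.9
    assert truncating_fraction(rp) == 143 / 388
    assert round(100 * truncating_fraction(ush), 1) == 69.6
    assert truncating_fraction(ush) == 39 / 56
    assert truncating_fraction({}) == 0.0


def test_allele_type_breakdown_counts_homozygotes_twice(pipeline_result):
    cases = pipeline_result.resolved
    cohort = pipeline_result.cohort
    rp = allele_type_breakdown(cases, cohort, "RP")
    ush = allele_type_breakdown(cases, cohort, "USH")
    both = allele_type_breakdown(cases, cohort)
    assert sum(ush.values()) == 56  # 2 alleles per USH patient
    for cons in rp:
        assert both[cons] == rp[cons] + ush[cons]
    total_causal = sum(c.n_causal_alleles for c in cases)
    assert sum(both.values()) == total_causal
    assert allele_type_breakdown([], cohort) == {
        c: 0 for c in ("missense", "splice_intronic", "frameshift",
                       "nonsense", "inframe")
    }


def test_contingency_chi_square_agrees_with_independent_computation():
    """Chi-square path checked against the textbook statistic computed from
    scratch with numpy, and against scipy, on a representative 2x3 table."""
    table = np.array([[75, 89, 26], [1, 15, 12]])
    res = contingency_test(table, method="chi2")
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    by_hand = float(((table - expected) ** 2 / expected).sum())
    assert res.test == "chi_square"
    assert res.statistic == pytest.approx(by_hand, abs=1e-9)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    assert res.statistic == pytest.approx(chi2, abs=1e-9)
    assert res.p_value == pytest.approx(p, abs=1e-12)
    assert res.tier == "***"


def test_contingency_auto_takes_fisher_for_sparse_tables():
    sparse = [[75, 89, 26], [1, 15, 12]]  # expected min = 28*38/218 < 5
    res = contingency_test(sparse)
    assert res.test == "fisher_exact"
    assert res.statistic is None
    assert 0 < res.p_value < 0.001
    # p-value cross-checked against the scipy 2x2 special case
    two_by_two = [[12, 30], [25, 10]]
    mine = contingency_test(two_by_two, method="fisher")
    _, scipy_p = stats.fisher_exact(two_by_two)
    assert mine.p_value == pytest.approx(scipy_p, rel=1e-9)


def test_identical_distributions_are_not_significant():
    res = contingency_test([[40, 40, 20], [40, 40, 20]], method="chi2")
    assert res.p_value == pytest.approx(1.0)
    assert res.tier == ""


def test_contingency_requires_both_phenotypes(pipeline_result):
    rp_only = [c for c in pipeline_result.resolved if c.phenotype == "RP"]
    with pytest.raises(ValueError, match="USH"):
        combination_contingency(rp_only)


def test_fixture_combination_contrast(pipeline_result):
    res = combination_contingency(pipeline_result.resolved)
    assert res.table == ((75, 89, 26), (1, 15, 12))
    assert res.tier == "***"


def test_variant_enrichment_flags(pipeline_result):
    flags = variant_enrichment(
        pipeline_result.spectra["solved_rp"], pipeline_result.spectra["solved_ush"]
    )
    nonsense_founder = DEFAULT_FOUNDERS[9].variant.key  # RP 4/380, USH 3/56
    f = flags[nonsense_founder]
    assert f["enriched_rp"] and f["enriched_ush"] and f["ush_over_rp"]
    rp_only = DEFAULT_FOUNDERS[3].variant.key  # absent from solved USH
    f2 = flags[rp_only]
    assert f2["enriched_rp"] and not f2["enriched_ush"] and not f2["ush_over_rp"]
    assert variant_enrichment([], []) == {}


def test_summary_metrics_headline_values(pipeline_result):
    s = pipeline_result.summary
    assert s["solved_total"] == 218 and s["n_ird"] == 1334
    assert round(s["solved_fraction_overall"], 4) == 0.1634
    assert round(s["solved_fraction_rp"], 4) == round(190 / 1278, 4)
    assert round(s["solved_fraction_ush"], 2) == 0.50
    assert (s["n_homozygous"], s["n_compound_het"]) == (23, 195)
    assert round(s["homozygous_fraction"], 4) == round(23 / 218, 4)
    assert s["total_plp_ac"] == 665 and s["top_k_ac"] == 384
    assert round(s["top_k_allele_share"], 4) == 0.5774
    assert s["n_distinct_plp"] == 136
    assert round(s["truncating_share_distinct"], 3) == 0.735
    assert s["n_de_novo"] == 1
    for cls, (mean, sd) in (("missense_missense", (43.73, 17.0)),
                            ("truncating_truncating", (36.04, 12.3))):
        got = s["age_by_combination"][cls]
        assert got["n"] > 0
        assert abs(got["mean"] - mean) < 6.0  # drawn from that age model
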
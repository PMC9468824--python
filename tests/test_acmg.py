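"""ACMG evidence assignment and five-class combination."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from usherspect.acmg import (
    AcmgParams,
    ClassifiedVariant,
    CohortContext,
    DEFAULT_STRENGTHS,
    Evidence,
    EvidenceSet,
    assign_evidence,
    combine,
    is_disease_causing,
    reclassify,
)

from acmg_oracle import build_evidence_set, enumerate_count_vectors, oracle_class
from conftest import make_variant


def ev(*codes: str) -> EvidenceSet:
    return EvidenceSet(codes)


# ---------------------------------------------------------------------------
# combine


def test_combiner_equals_bruteforce_table_for_all_small_multisets():
    """combine() agrees with an independently transcribed copy of the
    published combining table on every evidence multiset of size <= 6."""
    n = 0
    for counts in enumerate_count_vectors(6):
        expected = oracle_class(
            counts["very_strong"], counts["strong"], counts["moderate"],
            counts["supporting"], counts["stand_alone"], counts["benign_strong"],
            counts["benign_supporting"],
        )
        got = combine(build_evidence_set(counts))
        assert got == expected, f"{counts}: {got} != {expected}"
        n += 1
    assert n > 1000  # the enumeration is genuinely exhaustive


@pytest.mark.parametrize(
    "codes, expected",
    [
        (("PVS1", "PM2"), "LP"),
        ((), "VUS"),
        (("PM2", "PP3", "PM3", "PP1"), "LP"),  # two moderate + two supporting
        (("BA1",), "B"),
        (("PVS1", "PS2"), "P"),
        (("PVS1", "PM3", "PP5"), "P"),  # very strong + moderate + supporting
        (("PVS1", "PP1", "PP5"), "P"),  # very strong + two supporting
        (("PM2", "PP3"), "VUS"),
        (("BS1", "BP7"), "LB"),
        (("BP1", "BP7"), "LB"),
        (("PM2", "BP7"), "VUS"),  # contradictory evidence
        (("PS2", "PM2"), "LP"),
    ],
)
def test_combiner_worked_examples(codes, expected):
    assert combine(ev(*codes)) == expected


def test_combiner_is_order_and_identity_independent():
    assert combine(ev("PM2", "PM3", "PP3", "PP1")) == combine(
        ev("PP1", "PP3", "PM3", "PM2")
    )
    # verdict depends on strengths, not on which codes carry them
    assert combine(ev("PM1", "PM4", "PP2", "PP4")) == combine(
        ev("PM2", "PM3", "PP3", "PP5")
    )


_RANK = {"B": 0, "LB": 1, "VUS": 2, "LP": 3, "P": 4}
_PATH_CODES = ["PVS1", "PS1", "PS2", "PM1", "PM2", "PM3", "PP1", "PP3", "PP5"]
_BENIGN_CODES = ["BA1", "BS1", "BS2", "BP1", "BP7"]


@settings(derandomize=True, max_examples=300)
@given(
    st.sets(st.sampled_from(_PATH_CODES + _BENIGN_CODES), max_size=6),
    st.sampled_from(_PATH_CODES + _BENIGN_CODES),
)
def test_combiner_monotonicity(codes, extra):
    """Adding a pathogenic-side code never moves the verdict toward benign
    and adding a benign-side code never moves it toward pathogenic."""
    if extra in codes:
        return
    before = combine(ev(*codes))
    after = combine(ev(*codes, extra))
    if extra in _PATH_CODES:
        assert _RANK[after] >= _RANK[before]
    else:
        assert _RANK[after] <= _RANK[before]


def test_strength_override_requires_note_and_changes_weight():
    with pytest.raises(ValueError, match="note"):
        Evidence("PM3", "strong")
    strong_pm3 = Evidence("PM3", "strong", note="in trans in many patients")
    assert combine(EvidenceSet([strong_pm3, Evidence("PP3", "supporting"),
                                Evidence("PP5", "supporting")])) == "LP"


# ---------------------------------------------------------------------------
# assign_evidence


def test_pp3_requires_three_of_four_deleterious_predictors():
    """A predictor panel of D,D,D,T fires PP3; unavailable verdicts never
    count toward the threshold."""
    v = make_variant(
        db_freqs={"gnomad_eas": 1.16e-4},
        predictor_verdicts={"SIFT": "deleterious", "LRT": "deleterious",
                            "MutationTaster": "deleterious",
                            "FATHMM": "tolerated"},
    )
    assert "PP3" in assign_evidence(v)
    v2 = make_variant(
        predictor_verdicts={"SIFT": "deleterious", "LRT": "deleterious",
                            "MutationTaster": "unavailable",
                            "FATHMM": "unavailable"},
    )
    assert "PP3" not in assign_evidence(v2)


def test_truncating_absent_variant_gets_pvs1_and_pm2():
    v = make_variant(consequence="splice_intronic", region="intronic_splice",
                     hgvs_c="c.4251+1G>A", db_freqs={})
    codes = assign_evidence(v)
    assert "PVS1" in codes and "PM2" in codes
    assert combine(codes) == "LP"


def test_pm2_ceiling_blocks_common_eas_alleles():
    v = make_variant(db_freqs={"gnomad_eas": 3.27e-3})
    assert "PM2" not in assign_evidence(v)
    v2 = make_variant(db_freqs={"gnomad_eas": 5.44e-5, "g1000_eas": 0.0})
    assert "PM2" in assign_evidence(v2)


def test_synonymous_tolerated_variant_gets_bp7_only():
    v = make_variant(
        consequence="synonymous",
        predictor_verdicts={p: "tolerated"
                            for p in ("SIFT", "LRT", "MutationTaster", "FATHMM")},
    )
    codes = assign_evidence(v)
    assert codes.codes() == ["BP7"]
    assert combine(codes) == "VUS"


def test_context_codes_de_novo_in_trans_segregation_and_ba1():
    v = make_variant(db_freqs={"gnomad_global": 0.06})
    ctx = CohortContext(
        de_novo_keys=frozenset({v.key}),
        cosegregating_keys=frozenset({v.key}),
        in_trans_patients={v.key: 5},
    )
    codes = assign_evidence(v, ctx)
    assert {"PS2", "PP1", "PM3", "BA1"} <= set(codes.codes())
    assert codes["PM3"].strength == "strong"
    weaker = assign_evidence(v, CohortContext(in_trans_patients={v.key: 2}))
    assert weaker["PM3"].strength == "moderate"


# ---------------------------------------------------------------------------
# reclassification


def test_reclassify_requires_note_and_preserves_provenance():
    v = make_variant(hgvs_c="c.15520-1G>A", consequence="splice_intronic",
                     region="intronic_splice")
    auto = ClassifiedVariant(v, ev("PP5"), "VUS")
    up = reclassify(auto, "LP", "conflicting ClinVar entry; panel review")
    assert up.acmg_class == "LP" and up.reclassified
    assert "VUS -> LP" in up.note
    assert is_disease_causing(up)
    same = reclassify(auto, "VUS", "panel confirmed uncertainty")
    assert same.reclassified and "confirmed" in same.note
    with pytest.raises(ValueError, match="note"):
        reclassify(auto, "LP", "  ")


def test_classified_variant_must_match_combiner_unless_reclassified():
    v = make_variant()
    with pytest.raises(ValueError, match="does not follow"):
        ClassifiedVariant(v, ev(), "P")


def test_is_disease_causing_boundaries():
    v = make_variant()
    assert is_disease_causing(ClassifiedVariant(v, ev("PVS1", "PS2"), "P"))
    assert not is_disease_causing(ClassifiedVariant(v, ev(), "VUS"))
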
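"""Biallelic resolution, phase provenance, de-novo detection."""

import pytest

from usherspect.acmg import ClassifiedVariant, EvidenceSet
from usherspect.model import Cohort, Trio
from usherspect.resolution import (
    combination_class,
    detect_de_novo,
    find_carriers,
    resolve_patients,
)

from conftest import make_call, make_patient, make_variant


def classified(variant, acmg_class):
    ev = {"P": ("PVS1", "PS2"), "LP": ("PVS1", "PM2"), "VUS": ()}[acmg_class]
    return ClassifiedVariant(variant, EvidenceSet(ev), acmg_class)


@pytest.fixture
def micro():
    """Hand-built micro-cohort: trio proband, homozygote, carrier, control."""
    mis = make_variant(pos=100, hgvs_c="c.2802T>G")
    spl = make_variant(pos=200, consequence="splice_intronic",
                       region="intronic_splice", hgvs_c="c.8559-2A>G")
    non = make_variant(pos=300, consequence="nonsense", hgvs_c="c.9469C>T")
    vus = make_variant(pos=400, hgvs_c="c.1000A>G")
    people = [
        make_patient("TRIO", "RP", father_id="DAD", mother_id="MOM",
                     family_id="F1"),
        make_patient("DAD", "healthy", family_id="F1"),
        make_patient("MOM", "healthy", family_id="F1"),
        make_patient("HOM", "USH"),
        make_patient("CARRIER", "RP"),
        make_patient("VUSPAIR", "RP"),
        make_patient("CTRL", "healthy"),
        make_patient("SINGLETON", "RP"),
    ]
    calls = [
        make_call("TRIO", mis),       # de novo (absent in both parents)
        make_call("TRIO", spl),       # maternal
        make_call("MOM", spl),
        make_call("HOM", spl, "hom"),
        make_call("CARRIER", mis),
        make_call("VUSPAIR", mis),
        make_call("VUSPAIR", vus),
        make_call("CTRL", mis),
        make_call("CTRL", spl),
        make_call("SINGLETON", mis),
        make_call("SINGLETON", non),
    ]
    ref_depths = {("DAD", mis.key): 80, ("MOM", mis.key): 90,
                  ("DAD", spl.key): 70}
    cohort = Cohort(people, [mis, spl, non, vus], calls, ref_depths)
    classifications = {
        mis.key: classified(mis, "LP"),
        spl.key: classified(spl, "P"),
        non.key: classified(non, "LP"),
        vus.key: classified(vus, "VUS"),
    }
    return cohort, classifications, (mis, spl, non, vus)


def test_resolution_configurations_and_eligibility(micro):
    cohort, classifications, (mis, spl, non, vus) = micro
    cases = {c.participant_id: c for c in resolve_patients(cohort, classifications)}
    assert set(cases) == {"TRIO", "HOM", "SINGLETON"}
    assert cases["TRIO"].configuration == "compound_het"
    assert cases["TRIO"].phase_status == "trio_phased"
    assert cases["TRIO"].de_novo_variants == (mis.key,)
    assert cases["HOM"].configuration == "homozygous"
    assert cases["HOM"].phase_status == "inferred"
    assert cases["HOM"].n_causal_alleles == 2
    # compound het without parents counts as solved, flagged phase-unknown
    assert cases["SINGLETON"].phase_status == "unknown"
    # one het P/LP allele, or het P/LP + VUS, is not a diagnosis
    assert "CARRIER" not in cases and "VUSPAIR" not in cases
    # control participants are never resolved, whatever they carry
    assert "CTRL" not in cases


def test_carriers_include_controls_and_single_allele_patients(micro):
    cohort, classifications, (mis, spl, non, vus) = micro
    cases = resolve_patients(cohort, classifications)
    carriers = {c.participant_id: c for c in find_carriers(cohort, classifications, cases)}
    assert set(carriers) == {"CARRIER", "VUSPAIR", "CTRL", "MOM"}
    assert carriers["CTRL"].variant_keys == (mis.key, spl.key)
    assert carriers["VUSPAIR"].variant_keys == (mis.key,)  # the VUS is excluded


def test_counting_identity_on_reference_fixture(pipeline_result):
    cases = pipeline_result.resolved
    hom = sum(1 for c in cases if c.configuration == "homozygous")
    chet = sum(1 for c in cases if c.configuration == "compound_het")
    assert hom + chet == len(cases) == 218
    assert len({c.participant_id for c in cases}) == len(cases)
    controls = {
        p.participant_id
        for p in pipeline_result.cohort.participants.values()
        if p.cohort == "control"
    }
    assert not controls & {c.participant_id for c in cases}


def test_de_novo_requires_parent_coverage(micro):
    cohort, classifications, (mis, spl, non, vus) = micro
    trio = Trio("TRIO", "DAD", "MOM")
    assert detect_de_novo(cohort, trio, mis.key) is True
    assert detect_de_novo(cohort, trio, spl.key) is False  # maternal
    # without parental reference depth the status is unevaluable
    assert detect_de_novo(cohort, trio, non.key) is False
    # adequate coverage is required, not just any coverage
    assert detect_de_novo(cohort, trio, mis.key, min_depth=95) is False
    broken = Trio("TRIO", "DAD", "GHOST")
    assert detect_de_novo(cohort, broken, mis.key) is False


@pytest.mark.parametrize(
    "consequences, zygosities, expected",
    [
        (["missense", "splice_intronic"], ["het", "het"], "missense_truncating"),
        (["nonsense"], ["hom"], "truncating_truncating"),
        (["missense", "missense"], ["het", "het"], "missense_missense"),
        (["missense"], ["hom"], "missense_missense"),
        (["inframe", "missense"], ["het", "het"], "missense_missense"),
        # >2 alleles: the two truncating-first alleles set the class
        (["frameshift", "inframe", "missense"], ["het", "het", "het"],
         "missense_truncating"),
        (["nonsense", "frameshift", "missense"], ["het", "het", "het"],
         "truncating_truncating"),
    ],
)
def test_combination_class(consequences, zygosities, expected):
    variants, calls = [], []
    for i, (cons, zyg) in enumerate(zip(consequences, zygosities)):
        region = "intronic_splice" if cons == "splice_intronic" else "coding"
        v = make_variant(pos=100 + i, consequence=cons, region=region)
        variants.append(v)
        calls.append(make_call("P1", v, zyg))
    cohort = Cohort([make_patient("P1")], variants, calls)
    assert combination_class(calls, cohort) == expected


def test_degenerate_cohort_resolves_nothing():
    cohort = Cohort([make_patient("P1")], [], [])
    assert resolve_patients(cohort, {}) == []
    assert find_carriers(cohort, {}, []) == []
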
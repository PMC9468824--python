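"""Biallelic genotype resolution, phase provenance and de-novo detection.

A patient of the disease cohort is *genetically solved* when they carry a
homozygous P/LP allele or at least two distinct heterozygous P/LP alleles
(presumed compound heterozygous).  Phase is taken from pedigrees only:

* ``trio_phased`` — parental genotypes prove two causal alleles reside on
  opposite haplotypes (distinct parental origins, or one parental allele
  plus one trio-confirmed de-novo event);
* ``inferred`` — homozygous genotypes, whose biallelic state needs no
  phasing;
* ``unknown`` — compound heterozygotes without informative parents.  These
  patients still count as solved, but every such case is logged: the two
  alleles could in principle lie on the same haplotype.

Control-cohort participants are never resolved; together with
single-allele patients they are reported as carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .model import Cohort, GenotypeCall, Trio
from .qc import is_truncating
from .acmg import ClassifiedVariant, is_disease_causing

__all__ = [
    "ResolvedCase",
    "Carrier",
    "resolve_patients",
    "find_carriers",
    "detect_de_novo",
    "combination_class",
]

log = logging.getLogger(__name__)

COMBINATION_CLASSES = ("missense_missense", "missense_truncating", "truncating_truncating")


@dataclass(frozen=True)
class ResolvedCase:
    participant_id: str
    phenotype: str
    variants: tuple[GenotypeCall, ...]
    configuration: str  # "homozygous" | "compound_het"
    phase_status: str  # "trio_phased" | "inferred" | "unknown"
    combination_class: str
    de_novo_variants: tuple[str, ...] = ()

    @property
    def n_causal_alleles(self) -> int:
        return sum(c.allele_count for c in self.variants)

    @property
    def variant_keys(self) -> tuple[str, ...]:
        return tuple(c.variant_key for c in self.variants)


@dataclass(frozen=True)
class Carrier:
    participant_id: str
    cohort: str
    variant_keys: tuple[str, ...]


def detect_de_novo(
    cohort: Cohort, trio: Trio, variant_key: str, min_depth: int = 30
) -> bool:
    """True when a trio proves a proband allele arose de novo.

    Requires the proband to carry the allele while neither enrolled parent
    has any genotype call for it, *and* both parents to show adequate
    reference coverage (>= ``min_depth``) at the site — otherwise parental
    dropout cannot be excluded and the status is unevaluable (False, with a
    warning).
    """
    proband_keys = {c.variant_key for c in cohort.calls_of_participant(trio.proband_id)}
    if variant_key not in proband_keys:
        return False
    for parent in (trio.father_id, trio.mother_id):
        if parent not in cohort.participants:
            log.warning(
                "de novo status of %s in %s unevaluable: parent %s not enrolled",
                variant_key,
                trio.proband_id,
                parent,
            )
            return False
        if any(
            c.variant_key == variant_key for c in cohort.calls_of_participant(parent)
        ):
            return False  # inherited
        ref_depth = cohort.ref_depths.get((parent, variant_key))
        if ref_depth is None or ref_depth < min_depth:
            log.warning(
                "de novo status of %s in %s unevaluable: parent %s lacks adequate "
                "reference coverage at the site",
                variant_key,
                trio.proband_id,
                parent,
            )
            return False
    return True


def _impact_rank(cohort: Cohort, call: GenotypeCall) -> tuple[int, str]:
    """Sort key placing truncating alleles first (ties broken by key)."""
    truncating = is_truncating(cohort.variants[call.variant_key])
    return (0 if truncating else 1, call.variant_key)


def combination_class(case_calls, cohort: Cohort) -> str:
    """Class of the causal pair: missense/missense, missense/truncating or
    truncating/truncating.

    Non-truncating consequences (missense and inframe) count as the
    "missense" side.  Homozygous cases use their single variant twice; for
    patients with more than two causal alleles the two highest-impact
    (truncating-first) alleles define the class.
    """
    calls = sorted(case_calls, key=lambda c: _impact_rank(cohort, c))
    flags: list[bool] = []
    for c in calls:
        t = is_truncating(cohort.variants[c.variant_key])
        flags.extend([t, t] if c.zygosity == "hom" else [t])
    n_trunc = sum(sorted(flags, reverse=True)[:2])
    if n_trunc == 2:
        return "truncating_truncating"
    return "missense_truncating" if n_trunc == 1 else "missense_missense"


def _phase_from_trio(
    cohort: Cohort, trio: Trio, calls: list[GenotypeCall], de_novo: set[str]
) -> str:
    """trio_phased when two causal alleles have distinct proven origins."""
    origins: set[str] = set()
    for call in calls:
        if call.variant_key in de_novo:
            origins.add("de_novo")
            continue
        for label, parent in (("father", trio.father_id), ("mother", trio.mother_id)):
            if any(
                c.variant_key == call.variant_key
                for c in cohort.calls_of_participant(parent)
            ):
                origins.add(label)
    return "trio_phased" if len(origins) >= 2 else "unknown"


def resolve_patients(
    cohort: Cohort,
    classifications: Mapping[str, ClassifiedVariant],
    min_depth: int = 30,
) -> list[ResolvedCase]:
    """Identify genetically solved disease-cohort patients.

    Expects a QC-passed cohort and its variant classifications.  Patients
    with more than two P/LP alleles are resolved with all alleles recorded;
    ``n_causal_alleles`` then exceeds two.
    """
    trios_by_proband = {t.proband_id: t for t in cohort.trios()}
    cases: list[ResolvedCase] = []
    for patient in sorted(cohort.ird_patients(), key=lambda p: p.participant_id):
        plp_calls = [
            c
            for c in cohort.calls_of_participant(patient.participant_id)
            if c.variant_key in classifications
            and is_disease_causing(classifications[c.variant_key])
        ]
        if not plp_calls:
            continue
        distinct = {c.variant_key for c in plp_calls}
        homozygous = [c for c in plp_calls if c.zygosity == "hom"]
        if len(distinct) >= 2:
            configuration = "compound_het"
        elif homozygous:
            configuration = "homozygous"
        else:
            continue  # single heterozygous allele: carrier, not solved

        trio = trios_by_proband.get(patient.participant_id)
        de_novo = {
            c.variant_key
            for c in plp_calls
            if trio and detect_de_novo(cohort, trio, c.variant_key, min_depth)
        }
        if configuration == "homozygous":
            phase = "trio_phased" if trio else "inferred"
        elif trio:
            phase = _phase_from_trio(cohort, trio, plp_calls, de_novo)
        else:
            phase = "unknown"
        if phase == "unknown":
            log.debug(
                "%s: compound heterozygote without parental data; the two "
                "alleles could lie on the same haplotype",
                patient.participant_id,
            )
        cases.append(
            ResolvedCase(
                participant_id=patient.participant_id,
                phenotype=patient.phenotype,
                variants=tuple(sorted(plp_calls, key=lambda c: c.variant_key)),
                configuration=configuration,
                phase_status=phase,
                combination_class=combination_class(plp_calls, cohort),
                de_novo_variants=tuple(sorted(de_novo)),
            )
        )
    n_unknown = sum(1 for c in cases if c.phase_status == "unknown")
    if n_unknown:
        log.warning(
            "%d compound heterozygotes lack parental data; their two alleles "
            "could lie on the same haplotype (phase_status=unknown)",
            n_unknown,
        )
    return cases


def find_carriers(
    cohort: Cohort,
    classifications: Mapping[str, ClassifiedVariant],
    resolved: list[ResolvedCase],
) -> list[Carrier]:
    """Participants carrying >=1 P/LP allele without being resolved.

    Includes control-cohort carriers and unsolved single-allele patients.
    """
    solved_ids = {c.participant_id for c in resolved}
    carriers = []
    for p in sorted(cohort.participants.values(), key=lambda p: p.participant_id):
        if p.participant_id in solved_ids:
            continue
        keys = tuple(
            sorted(
                c.variant_key
                for c in cohort.calls_of_participant(p.participant_id)
                if c.variant_key in classifications
                and is_disease_causing(classifications[c.variant_key])
            )
        )
        if keys:
            carriers.append(Carrier(p.participant_id, p.cohort, keys))
    return carriers
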
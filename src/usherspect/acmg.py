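"""ACMG/AMP evidence assignment and five-class combination.

Two layers are kept deliberately separate:

* :func:`combine` is a faithful transcription of the published ACMG/AMP
  combining rules (Richards et al. 2015): evidence items carry a strength
  (very strong / strong / moderate / supporting on the pathogenic side,
  stand-alone / strong / supporting on the benign side) and the rule table
  maps strength counts to one of P, LP, VUS, LB, B.  Co-occurrence of
  pathogenic-side and benign-side evidence is treated as contradictory and
  yields VUS.

* :func:`assign_evidence` derives evidence codes from what a cohort of this
  kind actually measures: consequence class (PVS1), reference-database
  rarity (PM2, BA1), an in-silico predictor panel (PP3), trio-confirmed
  de-novo status (PS2), observation in trans with another disease-causing
  allele (PM3), family co-segregation (PP1), literature/ClinVar status
  (PP5) and synonymous impact (BP7).  PM3 follows the ClinGen practice of
  upgrading to strong when a variant is seen in trans with a pathogenic
  partner in several unrelated patients.

Because PM3 refers to the classification of partner alleles, cohort-wide
classification is a monotone fixed-point iteration: truncating and
otherwise self-sufficient alleles classify first, and alleles whose case
rests on the biallelic context join in subsequent passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .model import (
    GLOBAL_FREQ_KEYS,
    PREDICTORS,
    Cohort,
    VariantRecord,
)
from .qc import is_truncating

__all__ = [
    "PATHOGENIC_STRENGTHS",
    "DEFAULT_STRENGTHS",
    "Evidence",
    "EvidenceSet",
    "ClassifiedVariant",
    "AcmgParams",
    "CohortContext",
    "assign_evidence",
    "combine",
    "classify_cohort",
    "reclassify",
    "is_disease_causing",
]

log = logging.getLogger(__name__)

_PS = [f"PS{i}" for i in range(1, 5)]
_PM = [f"PM{i}" for i in range(1, 7)]
_PP = [f"PP{i}" for i in range(1, 6)]
_BS = [f"BS{i}" for i in range(1, 5)]
_BP = [f"BP{i}" for i in range(1, 8)]

#: Default strength of every ACMG evidence code.
DEFAULT_STRENGTHS: dict[str, str] = {
    "PVS1": "very_strong",
    **{c: "strong" for c in _PS},
    **{c: "moderate" for c in _PM},
    **{c: "supporting" for c in _PP},
    "BA1": "stand_alone",
    **{c: "strong" for c in _BS},
    **{c: "supporting" for c in _BP},
}
PATHOGENIC_CODES = frozenset({"PVS1", *_PS, *_PM, *_PP})
BENIGN_CODES = frozenset({"BA1", *_BS, *_BP})
PATHOGENIC_STRENGTHS = ("very_strong", "strong", "moderate", "supporting")


@dataclass(frozen=True)
class Evidence:
    code: str
    strength: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.code not in DEFAULT_STRENGTHS:
            raise ValueError(f"unknown ACMG code {self.code!r}")
        valid = (
            PATHOGENIC_STRENGTHS
            if self.code in PATHOGENIC_CODES
            else ("stand_alone", "strong", "supporting")
        )
        if self.strength not in valid:
            raise ValueError(f"{self.code}: invalid strength {self.strength!r}")
        if self.strength != DEFAULT_STRENGTHS[self.code] and not self.note:
            raise ValueError(
                f"{self.code}: strength override to {self.strength} requires a note"
            )


class EvidenceSet:
    """At most one occurrence of each ACMG code, each with a strength."""

    def __init__(self, items: Iterable[Evidence | str] = ()) -> None:
        self._items: dict[str, Evidence] = {}
        for it in items:
            if isinstance(it, str):
                it = Evidence(it, DEFAULT_STRENGTHS[it])
            self.add(it)

    def add(self, item: Evidence | str, strength: str | None = None, note: str = "") -> None:
        if isinstance(item, str):
            item = Evidence(item, strength or DEFAULT_STRENGTHS[item], note)
        if item.code in self._items:
            raise ValueError(f"duplicate evidence code {item.code}")
        self._items[item.code] = item

    def __contains__(self, code: str) -> bool:
        return code in self._items

    def __iter__(self):
        return iter(sorted(self._items.values(), key=lambda e: e.code))

    def __len__(self) -> int:
        return len(self._items)

    def codes(self) -> list[str]:
        return sorted(self._items)

    def __getitem__(self, code: str) -> Evidence:
        return self._items[code]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvidenceSet):
            return NotImplemented
        return self._items == other._items

    def __repr__(self) -> str:
        parts = []
        for e in self:
            suffix = "" if e.strength == DEFAULT_STRENGTHS[e.code] else f"_{e.strength}"
            parts.append(e.code + suffix)
        return "{" + ", ".join(parts) + "}"

    def strength_counts(self) -> dict[str, int]:
        counts = {
            "very_strong": 0,
            "strong": 0,
            "moderate": 0,
            "supporting": 0,
            "stand_alone": 0,
            "benign_strong": 0,
            "benign_supporting": 0,
        }
        for e in self._items.values():
            if e.code in PATHOGENIC_CODES:
                counts[e.strength] += 1
            elif e.strength == "stand_alone":
                counts["stand_alone"] += 1
            elif e.strength == "strong":
                counts["benign_strong"] += 1
            else:
                counts["benign_supporting"] += 1
        return counts


def combine(evidence: EvidenceSet) -> str:
    """Combine an evidence set into one of P, LP, VUS, LB, B.

    Pathogenic rows: very-strong plus (one strong | two moderate | one
    moderate and one supporting | two supporting); two strong; one strong
    plus (three moderate | two moderate and two supporting | one moderate
    and four supporting).  Likely-pathogenic rows: very-strong plus one
    moderate; one strong plus one or two moderate; one strong plus two
    supporting; three moderate; two moderate plus two supporting; one
    moderate plus four supporting.  Benign: stand-alone, or two strong.
    Likely benign: one strong plus one supporting, or two supporting.
    Anything else — including simultaneous pathogenic- and benign-side
    evidence — is of uncertain significance.
    """
    n = evidence.strength_counts()
    has_path = n["very_strong"] + n["strong"] + n["moderate"] + n["supporting"] > 0
    has_benign = n["stand_alone"] + n["benign_strong"] + n["benign_supporting"] > 0
    if has_path and has_benign:
        return "VUS"

    vs, s, m, p = n["very_strong"], n["strong"], n["moderate"], n["supporting"]
    if vs >= 2:
        return "P"
    if vs == 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2):
        return "P"
    if s >= 2:
        return "P"
    if s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)):
        return "P"
    if vs == 1 and m == 1:
        return "LP"
    if s == 1 and (1 <= m <= 2 or p >= 2):
        return "LP"
    if m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4):
        return "LP"

    if n["stand_alone"] >= 1 or n["benign_strong"] >= 2:
        return "B"
    if (n["benign_strong"] == 1 and n["benign_supporting"] >= 1) or n[
        "benign_supporting"
    ] >= 2:
        return "LB"
    return "VUS"


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: VariantRecord
    evidence: EvidenceSet
    acmg_class: str
    reclassified: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.acmg_class not in ("P", "LP", "VUS", "LB", "B"):
            raise ValueError(f"unknown ACMG class {self.acmg_class!r}")
        if not self.reclassified and self.acmg_class != combine(self.evidence):
            raise ValueError(
                f"{self.variant.key}: class {self.acmg_class} does not follow from "
                f"evidence {self.evidence} and no reclassification note is present"
            )


def is_disease_causing(classified: ClassifiedVariant) -> bool:
    """Pathogenic or likely pathogenic alleles count toward a diagnosis."""
    return classified.acmg_class in ("P", "LP")


def reclassify(
    classified: ClassifiedVariant, new_class: str, note: str
) -> ClassifiedVariant:
    """Expert override of an automated class; the note is mandatory."""
    if not note or not note.strip():
        raise ValueError("reclassification requires a non-empty note")
    prior = classified.acmg_class
    full_note = f"reclassified {prior} -> {new_class}: {note}"
    if new_class == prior:
        full_note = f"confirmed {prior}: {note}"
    return replace(classified, acmg_class=new_class, reclassified=True, note=full_note)


@dataclass
class AcmgParams:
    """Thresholds of the automated evidence rules, each independently togglable."""

    pm2_max_af: float = 1e-4
    pp3_min_deleterious: int = 3
    pm3_strong_min_patients: int = 4
    ba1_min_af: float = 0.05
    enabled: frozenset[str] = frozenset(
        {"PVS1", "PM2", "PP3", "PS2", "PM3", "PP1", "PP5", "BA1", "BP7"}
    )


@dataclass
class CohortContext:
    """Cohort-level facts feeding the evidence rules.

    ``in_trans_patients`` maps a variant key to the number of distinct
    patients in which the variant co-occurs with a different P/LP allele
    (assumed or proven in trans).  ``de_novo_keys`` holds trio-confirmed
    de-novo variants and ``cosegregating_keys`` variants transmitted from an
    unaffected carrier parent to an affected proband.
    """

    de_novo_keys: frozenset[str] = frozenset()
    cosegregating_keys: frozenset[str] = frozenset()
    in_trans_patients: Mapping[str, int] = field(default_factory=dict)


def assign_evidence(
    variant: VariantRecord,
    context: CohortContext | None = None,
    params: AcmgParams | None = None,
) -> EvidenceSet:
    """Derive the evidence codes computable from this cohort's annotations."""
    context = context or CohortContext()
    params = params or AcmgParams()
    on = params.enabled
    ev = EvidenceSet()

    if "PVS1" in on and is_truncating(variant):
        ev.add("PVS1", note="truncating consequence")
    # rarity of a silent change with no predicted splice impact is not
    # pathogenic evidence, so PM2 is never raised for synonymous variants
    if (
        "PM2" in on
        and variant.consequence != "synonymous"
        and all(af <= params.pm2_max_af for af in variant.db_freqs.values())
    ):
        ev.add("PM2", note="absent or ultra-rare in all reference databases")
    preds = variant.predictor_verdicts
    if not preds:
        log.debug("%s: no predictor panel, treating all as unavailable", variant.key)
    if "PP3" in on:
        n_del = sum(1 for v in preds.values() if v == "deleterious")
        if n_del >= params.pp3_min_deleterious:
            ev.add("PP3", note=f"{n_del}/{len(PREDICTORS)} predictors deleterious")
    if "PS2" in on and variant.key in context.de_novo_keys:
        ev.add("PS2", note="trio-confirmed de novo")
    if "PM3" in on:
        n_trans = context.in_trans_patients.get(variant.key, 0)
        if n_trans >= params.pm3_strong_min_patients:
            ev.add(
                "PM3",
                strength="strong",
                note=f"in trans with a P/LP allele in {n_trans} patients",
            )
        elif n_trans >= 1:
            ev.add("PM3", note=f"in trans with a P/LP allele in {n_trans} patient(s)")
    if "PP1" in on and variant.key in context.cosegregating_keys:
        ev.add("PP1", note="co-segregates with disease in >=1 family")
    if "PP5" in on and variant.reported_status == "reported_pathogenic":
        ev.add("PP5", note="reported pathogenic in ClinVar/HGMD/literature")
    if "BA1" in on and any(
        variant.db_freqs.get(k, 0.0) > params.ba1_min_af for k in GLOBAL_FREQ_KEYS
    ):
        ev.add("BA1", note=f"global allele frequency > {params.ba1_min_af}")
    if "BP7" in on and variant.consequence == "synonymous":
        ev.add("BP7", note="synonymous, no predicted splice impact")
    return ev


def _trio_facts(
    cohort: Cohort, min_depth: int = 30
) -> tuple[frozenset[str], frozenset[str]]:
    """De-novo and co-segregating variant keys from enrolled trios."""
    from .resolution import detect_de_novo  # local import to avoid a cycle

    de_novo: set[str] = set()
    coseg: set[str] = set()
    for trio in cohort.trios():
        proband = cohort.participants[trio.proband_id]
        if proband.cohort != "ird":
            continue
        parent_keys = {
            c.variant_key
            for pid in (trio.father_id, trio.mother_id)
            for c in cohort.calls_of_participant(pid)
        }
        for call in cohort.calls_of_participant(trio.proband_id):
            if call.variant_key in parent_keys:
                coseg.add(call.variant_key)
            elif detect_de_novo(cohort, trio, call.variant_key, min_depth=min_depth):
                de_novo.add(call.variant_key)
    return frozenset(de_novo), frozenset(coseg)


def _in_trans_counts(cohort: Cohort, plp_keys: set[str]) -> dict[str, int]:
    """Patients in which each variant co-occurs with a distinct P/LP allele."""
    counts: dict[str, int] = {}
    for p in cohort.ird_patients():
        calls = cohort.calls_of_participant(p.participant_id)
        keys = {c.variant_key for c in calls}
        for k in keys:
            if any(other in plp_keys for other in keys - {k}):
                counts[k] = counts.get(k, 0) + 1
    return counts


def classify_cohort(
    cohort: Cohort,
    params: AcmgParams | None = None,
    min_depth: int = 30,
    max_passes: int = 10,
) -> dict[str, ClassifiedVariant]:
    """Classify every variant of a QC-passed cohort.

    Runs :func:`assign_evidence` / :func:`combine` iteratively: the in-trans
    context (PM3) is recomputed from the previous pass's P/LP set until the
    classification reaches a fixed point.  Convergence is guaranteed because
    the P/LP set grows monotonically.
    """
    params = params or AcmgParams()
    de_novo, coseg = _trio_facts(cohort, min_depth=min_depth)
    plp: set[str] = set()
    result: dict[str, ClassifiedVariant] = {}
    for _ in range(max_passes):
        context = CohortContext(
            de_novo_keys=de_novo,
            cosegregating_keys=coseg,
            in_trans_patients=_in_trans_counts(cohort, plp),
        )
        result = {}
        for key, variant in cohort.variants.items():
            ev = assign_evidence(variant, context, params)
            result[key] = ClassifiedVariant(variant, ev, combine(ev))
        new_plp = {k for k, cv in result.items() if is_disease_causing(cv)}
        if new_plp == plp:
            break
        plp = new_plp
    return result
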
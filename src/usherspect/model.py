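"""Core domain types for the USH2A cohort pipeline.

The in-memory model mirrors what a multi-sample VCF, a PED file, a phenotype
table and a per-variant population-frequency table jointly describe:

* :class:`VariantRecord` — one alternate allele at a genomic position, with
  HGVS names, a consequence class, a region class, reference-database allele
  frequencies and in-silico predictor verdicts.
* :class:`GenotypeCall` — one participant's non-reference genotype (het/hom)
  at one variant, with sequencing depth.
* :class:`Participant` — phenotype group (RP / USH / other inherited eye
  disease / healthy relative), cohort membership and pedigree links.
* :class:`Cohort` — the assembled collection, with lookup indexes and the
  reference-homozygous depths needed for de-novo evaluation in trios.

A heterozygote contributes one alternate allele and a homozygote two, so the
allele count of a variant is ``n_het + 2 * n_hom`` and the cohort-wide allele
frequency is ``AC / (2 * n_participants)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "CONSEQUENCES",
    "REGIONS",
    "TRUNCATING_CONSEQUENCES",
    "GLOBAL_FREQ_KEYS",
    "EAS_FREQ_KEYS",
    "NON_EAS_FREQ_KEYS",
    "FREQ_KEYS",
    "PREDICTORS",
    "REPORTED_STATUSES",
    "CohortError",
    "VariantRecord",
    "GenotypeCall",
    "Participant",
    "Trio",
    "Cohort",
    "variant_key",
]

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice_intronic",
    "inframe",
    "synonymous",
)
REGIONS = ("coding", "intronic_splice", "utr")

#: Consequences expected to truncate the protein product.
TRUNCATING_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice_intronic"})

#: Whole-database (global) allele-frequency keys used by the MAF filter.
GLOBAL_FREQ_KEYS = (
    "g1000_global",
    "exac_global",
    "gnomad_global",
    "esp6500",
    "dbsnp",
)
#: East-Asian subpopulation keys (never trigger the MAF filter).
EAS_FREQ_KEYS = ("g1000_eas", "exac_eas", "gnomad_eas")
#: Non-East-Asian subpopulation keys; a positive value under any of them
#: marks a recurrent allele as a hot spot rather than a founder allele.
NON_EAS_FREQ_KEYS = (
    "gnomad_asj",
    "exac_amr",
    "exac_nfe",
    "gnomad_afr",
    "exac_afr",
    "exac_sas",
    "gnomad_nfe",
)
FREQ_KEYS = GLOBAL_FREQ_KEYS + EAS_FREQ_KEYS + NON_EAS_FREQ_KEYS

PREDICTORS = ("SIFT", "LRT", "MutationTaster", "FATHMM")
PREDICTOR_VERDICTS = ("deleterious", "tolerated", "unavailable")
REPORTED_STATUSES = ("reported_pathogenic", "reported_conflicting", "novel")

PHENOTYPES = ("RP", "USH", "other_ied", "healthy")
COHORTS = ("ird", "control")

# Coding-DNA HGVS: "c." followed by a position token and a change description,
# e.g. c.2802T>G, c.8559-2A>G, c.99_100insT, c.11526_11528del, c.6325+1G>A.
_HGVS_C_RE = re.compile(r"^c\.[\d*+-][\dA-Za-z_+*>=-]*$")


class CohortError(ValueError):
    """Raised when an input violates the cohort model's invariants."""


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Unique variant identifier in ``chrom:pos:ref>alt`` notation."""
    return f"{chrom}:{pos}:{ref}>{alt}"


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_c: str
    hgvs_p: str = ""
    consequence: str = "missense"
    region: str = "coding"
    db_freqs: dict[str, float] = field(default_factory=dict)
    predictor_verdicts: dict[str, str] = field(default_factory=dict)
    reported_status: str = "novel"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortError(f"{self.hgvs_c or self.pos}: position must be >= 1")
        if self.ref == self.alt:
            raise CohortError(f"{self.key}: ref and alt alleles are identical")
        if self.consequence not in CONSEQUENCES:
            raise CohortError(f"{self.key}: unknown consequence {self.consequence!r}")
        if self.region not in REGIONS:
            raise CohortError(f"{self.key}: unknown region {self.region!r}")
        if self.consequence == "synonymous" and self.region != "coding":
            raise CohortError(f"{self.key}: synonymous variants must be coding")
        if self.hgvs_c and not _HGVS_C_RE.match(self.hgvs_c):
            raise CohortError(f"{self.key}: malformed HGVS cDNA name {self.hgvs_c!r}")
        for key, af in self.db_freqs.items():
            if not (0.0 <= af <= 1.0):
                raise CohortError(f"{self.key}: frequency {key}={af} outside [0, 1]")
        for pred, verdict in self.predictor_verdicts.items():
            if pred not in PREDICTORS:
                raise CohortError(f"{self.key}: unknown predictor {pred!r}")
            if verdict not in PREDICTOR_VERDICTS:
                raise CohortError(f"{self.key}: unknown verdict {verdict!r}")
        if self.reported_status not in REPORTED_STATUSES:
            raise CohortError(
                f"{self.key}: unknown reported status {self.reported_status!r}"
            )

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeCall:
    participant_id: str
    variant_key: str
    zygosity: str  # "het" or "hom"
    depth: int

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom"):
            raise CohortError(
                f"{self.participant_id}@{self.variant_key}: "
                f"zygosity must be het or hom, got {self.zygosity!r}"
            )
        if self.depth < 0:
            raise CohortError(
                f"{self.participant_id}@{self.variant_key}: negative depth"
            )

    @property
    def allele_count(self) -> int:
        return 2 if self.zygosity == "hom" else 1


@dataclass(frozen=True)
class Participant:
    participant_id: str
    cohort: str  # "ird" or "control"
    phenotype: str  # RP | USH | other_ied | healthy
    family_id: str = ""
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    age_years: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise CohortError(f"{self.participant_id}: unknown cohort {self.cohort!r}")
        if self.phenotype not in PHENOTYPES:
            raise CohortError(
                f"{self.participant_id}: unknown phenotype {self.phenotype!r}"
            )
        is_patient = self.phenotype in ("RP", "USH")
        if is_patient != (self.cohort == "ird"):
            raise CohortError(
                f"{self.participant_id}: phenotype {self.phenotype} inconsistent "
                f"with cohort {self.cohort}"
            )
        if self.age_years is not None and self.age_years < 0:
            raise CohortError(f"{self.participant_id}: negative age")


@dataclass(frozen=True)
class Trio:
    proband_id: str
    father_id: str
    mother_id: str


class Cohort:
    """Participants, variants and genotype calls with lookup indexes.

    ``ref_depths`` holds sequencing depth for reference-homozygous genotypes
    of pedigree parents, keyed ``(participant_id, variant_key)``.  Those
    genotypes produce no :class:`GenotypeCall`, but their depth is required
    to distinguish a true de-novo event from parental dropout.
    """

    def __init__(
        self,
        participants: Iterable[Participant] = (),
        variants: Iterable[VariantRecord] = (),
        calls: Iterable[GenotypeCall] = (),
        ref_depths: Optional[dict[tuple[str, str], int]] = None,
    ) -> None:
        self.participants: dict[str, Participant] = {}
        for p in participants:
            if p.participant_id in self.participants:
                raise CohortError(f"duplicate participant {p.participant_id}")
            self.participants[p.participant_id] = p
        self.variants: dict[str, VariantRecord] = {}
        for v in variants:
            if v.key in self.variants:
                raise CohortError(f"duplicate variant {v.key}")
            self.variants[v.key] = v
        self.calls: list[GenotypeCall] = []
        self._calls_by_participant: dict[str, list[GenotypeCall]] = {}
        self._calls_by_variant: dict[str, list[GenotypeCall]] = {}
        seen: set[tuple[str, str]] = set()
        for c in calls:
            if c.participant_id not in self.participants:
                raise CohortError(
                    f"call references unknown participant {c.participant_id}"
                )
            if c.variant_key not in self.variants:
                raise CohortError(f"call references unknown variant {c.variant_key}")
            pair = (c.participant_id, c.variant_key)
            if pair in seen:
                raise CohortError(f"duplicate genotype call {pair}")
            seen.add(pair)
            self.calls.append(c)
            self._calls_by_participant.setdefault(c.participant_id, []).append(c)
            self._calls_by_variant.setdefault(c.variant_key, []).append(c)
        self.ref_depths: dict[tuple[str, str], int] = dict(ref_depths or {})

    # -- lookups ---------------------------------------------------------

    def calls_of_participant(self, participant_id: str) -> list[GenotypeCall]:
        return self._calls_by_participant.get(participant_id, [])

    def calls_of_variant(self, key: str) -> list[GenotypeCall]:
        return self._calls_by_variant.get(key, [])

    def allele_count(self, key: str) -> int:
        return sum(c.allele_count for c in self.calls_of_variant(key))

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_chromosomes(self) -> int:
        """Diploid allele total: two chromosomes per participant."""
        return 2 * self.n_participants

    def ird_patients(self) -> list[Participant]:
        return [p for p in self.participants.values() if p.cohort == "ird"]

    def trios(self) -> list[Trio]:
        """Proband-parent trios in which both parents are enrolled."""
        out = []
        for p in self.participants.values():
            if (
                p.father_id
                and p.mother_id
                and p.father_id in self.participants
                and p.mother_id in self.participants
            ):
                out.append(Trio(p.participant_id, p.father_id, p.mother_id))
        return sorted(out, key=lambda t: t.proband_id)

    def subset_calls(self, keep: Iterable[GenotypeCall]) -> "Cohort":
        """New cohort with the same participants/variants but only ``keep`` calls."""
        return Cohort(
            self.participants.values(), self.variants.values(), keep, self.ref_depths
        )

    def subset_variants(self, keys: Iterable[str]) -> "Cohort":
        keyset = set(keys)
        return Cohort(
            self.participants.values(),
            [v for k, v in self.variants.items() if k in keyset],
            [c for c in self.calls if c.variant_key in keyset],
            self.ref_depths,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.participants == other.participants
            and self.variants == other.variants
            and sorted(self.calls, key=lambda c: (c.participant_id, c.variant_key))
            == sorted(other.calls, key=lambda c: (c.participant_id, c.variant_key))
        )

    def __repr__(self) -> str:
        return (
            f"Cohort({self.n_participants} participants, "
            f"{len(self.variants)} variants, {len(self.calls)} calls)"
        )
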
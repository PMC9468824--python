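"""Seeded synthetic cohort generator.

Real per-sample genotypes for a hospital IRD cohort cannot be redistributed,
so every downstream stage of this package is exercised on synthetic cohorts
whose *statistical structure* matches the study conditions: 1,278 retinitis
pigmentosa and 56 Usher-syndrome patients, 7,376 control participants
(other inherited-eye-disease patients and healthy relatives), 373
proband-parent trios, eleven recurrent founder/hot-spot alleles planted at
their target cohort allele counts, 218 biallelic (genetically solved)
patients with a 23 : 195 homozygous : compound-heterozygous split, exactly
one trio-confirmed de-novo event, and a background of rare VUS-like and
benign-leaning filler variants, three of which deliberately violate one QC
rule each (common allele, low depth, UTR location).

Planting is by exact count, not by sampling, so pipeline outputs on the
default fixture are deterministic; a stochastic mode (per-individual
carrier sampling at the target allele frequency) is available for
statistical recovery tests.  The seed controls who carries what, ages and
depths — never the planted counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    Cohort,
    GenotypeCall,
    Participant,
    TRUNCATING_CONSEQUENCES,
    VariantRecord,
)

__all__ = [
    "SimulationError",
    "FounderSpec",
    "SimConfig",
    "generate",
    "fixture_reference",
    "DEFAULT_FOUNDERS",
]


class SimulationError(ValueError):
    """Raised when a requested cohort structure is infeasible."""


@dataclass(frozen=True)
class FounderSpec:
    """A recurrent allele template with its planted carrier structure.

    ``cohort_het``/``cohort_hom`` are whole-cohort targets (solved patients,
    single-allele carriers and trio parents together); ``solved`` gives the
    (het, hom) share planted inside solved RP and USH patients.
    """

    variant: VariantRecord
    cohort_het: int
    cohort_hom: int
    solved: Mapping[str, tuple[int, int]]  # phenotype -> (n_het, n_hom)

    @property
    def target_ac(self) -> int:
        return self.cohort_het + 2 * self.cohort_hom

    def validate(self) -> None:
        if self.cohort_het < 0 or self.cohort_hom < 0:
            raise SimulationError(f"{self.variant.key}: negative carrier target")
        s_het = sum(h for h, _ in self.solved.values())
        s_hom = sum(m for _, m in self.solved.values())
        if s_het > self.cohort_het or s_hom > self.cohort_hom:
            raise SimulationError(
                f"{self.variant.key}: solved share exceeds cohort target"
            )


def _v(
    pos: int,
    ref: str,
    alt: str,
    hgvs_c: str,
    hgvs_p: str,
    consequence: str,
    region: str,
    freqs: dict[str, float],
) -> VariantRecord:
    preds = (
        {"SIFT": "deleterious", "LRT": "deleterious", "MutationTaster": "deleterious",
         "FATHMM": "tolerated"}
        if consequence in ("missense", "inframe")
        else {p: "unavailable" for p in ("SIFT", "LRT", "MutationTaster", "FATHMM")}
    )
    return VariantRecord(
        chrom="chr1", pos=pos, ref=ref, alt=alt, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
        consequence=consequence, region=region, db_freqs=freqs,
        predictor_verdicts=preds, reported_status="reported_pathogenic",
    )


#: The eleven recurrent alleles, with reference-database frequencies as
#: curated for this locus and their planted cohort/solved carrier structure.
DEFAULT_FOUNDERS: tuple[FounderSpec, ...] = (
    FounderSpec(
        _v(216246592, "A", "C", "c.2802T>G", "p.Cys934Trp", "missense", "coding",
           {"g1000_eas": 0.004, "gnomad_eas": 3.27e-3, "exac_eas": 2.79e-3,
            "exac_amr": 8.66e-5, "exac_nfe": 1.50e-5, "gnomad_asj": 2.89e-4}),
        120, 1, {"RP": (46, 1), "USH": (3, 0)},
    ),
    FounderSpec(
        _v(215877882, "T", "C", "c.8559-2A>G", "", "splice_intronic",
           "intronic_splice",
           {"g1000_eas": 0.001, "gnomad_eas": 1.93e-4, "exac_eas": 3.48e-4}),
        83, 8, {"RP": (33, 7), "USH": (6, 1)},
    ),
    FounderSpec(
        _v(216422237, "G", "GA", "c.99_100insT", "p.Arg34Serfs*41", "frameshift",
           "coding",
           {"g1000_eas": 0.0, "gnomad_eas": 3.86e-4, "exac_eas": 0.0}),
        23, 2, {"RP": (9, 2), "USH": (1, 0)},
    ),
    FounderSpec(
        _v(215759735, "C", "T", "c.11156G>A", "p.Arg3719His", "missense", "coding",
           {"g1000_eas": 0.0, "gnomad_eas": 1.93e-4, "exac_eas": 1.16e-4,
            "gnomad_afr": 1.69e-4, "gnomad_nfe": 1.47e-5, "exac_amr": 2.60e-4,
            "exac_afr": 1.92e-4, "exac_sas": 6.06e-5}),
        23, 2, {"RP": (8, 2), "USH": (0, 0)},
    ),
    FounderSpec(
        _v(215879090, "C", "G", "c.8232G>C", "p.Trp2744Cys", "missense", "coding",
           {"g1000_eas": 0.0, "gnomad_eas": 1.93e-4, "exac_eas": 0.0}),
        16, 2, {"RP": (3, 2), "USH": (2, 0)},
    ),
    FounderSpec(
        _v(215674446, "C", "T", "c.13465G>A", "p.Gly4489Ser", "missense", "coding",
           {"g1000_eas": 0.0, "gnomad_eas": 0.0, "exac_eas": 0.0}),
        16, 1, {"RP": (8, 1), "USH": (0, 0)},
    ),
    FounderSpec(
        _v(215879038, "G", "C", "c.8284C>G", "p.Pro2762Ala", "missense", "coding",
           {"g1000_eas": 0.0, "gnomad_eas": 0.0, "exac_eas": 0.0}),
        12, 2, {"RP": (4, 2), "USH": (0, 0)},
    ),
    FounderSpec(
        _v(215798907, "C", "A", "c.9958G>T", "p.Gly3320Cys", "missense", "coding",
           {"g1000_eas": 0.0, "gnomad_eas": 0.0, "exac_eas": 0.0}),
        12, 2, {"RP": (4, 2), "USH": (0, 0)},
    ),
    FounderSpec(
        _v(215786726, "C", "T", "c.10331G>A", "p.Cys3444Tyr", "missense", "coding",
           {"g1000_eas": 0.0, "gnomad_eas": 5.44e-5, "exac_eas": 0.0}),
        14, 0, {"RP": (3, 0), "USH": (0, 0)},
    ),
    FounderSpec(
        _v(215817098, "G", "A", "c.9469C>T", "p.Gln3157*", "nonsense", "coding",
           {"g1000_eas": 0.0, "gnomad_eas": 1.94e-4, "exac_eas": 3.48e-4}),
        14, 0, {"RP": (4, 0), "USH": (3, 0)},
    ),
    FounderSpec(
        _v(216046430, "C", "T", "c.6325+1G>A", "", "splice_intronic",
           "intronic_splice",
           {"g1000_eas": 0.0, "gnomad_eas": 0.0, "exac_eas": 0.0}),
        11, 0, {"RP": (4, 0), "USH": (3, 0)},
    ),
)

#: Mean/SD of age at first visit per genotype-combination group, years.
AGE_MODEL = {
    "missense_missense": (43.73, 17.00),
    "missense_truncating": (40.75, 16.18),
    "truncating_truncating": (36.04, 12.30),
}
AGE_RANGE = (2.0, 78.0)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 42
    n_rp: int = 1278
    n_ush: int = 56
    n_control: int = 7376
    n_trios_rp: int = 350
    n_trios_ush: int = 23
    founder_alleles: tuple[FounderSpec, ...] = DEFAULT_FOUNDERS
    n_solved_rp: int = 190
    n_solved_ush: int = 28
    homozygous_fraction: float = 23 / 218
    #: distinct additional (non-recurrent) disease-causing variants to plant,
    #: by consequence class
    extra_pathogenic_mix: Mapping[str, int] = field(
        default_factory=lambda: {
            "missense": 28, "nonsense": 28, "splice_intronic": 25,
            "frameshift": 43, "inframe": 1,
        }
    )
    #: target total alternate-allele count over all disease-causing variants
    total_plp_alleles: int = 665
    #: target number of novel (unreported) disease-causing variants; drawn
    #: from the truncating extras, which classify without literature support
    n_novel_plp: int = 43
    #: per-phenotype (missense/missense, missense/truncating,
    #: truncating/truncating) counts among solved patients; None lets the
    #: generator choose a feasible split
    combination_targets: Optional[Mapping[str, tuple[int, int, int]]] = field(
        default_factory=lambda: {"RP": (75, 89, 26), "USH": (1, 15, 12)}
    )
    #: distinct background (non-causal) variants, by profile
    background_vus_mix: Mapping[str, int] = field(
        default_factory=lambda: {"missense": 328, "synonymous": 180}
    )
    background_benign_mix: Mapping[str, int] = field(
        default_factory=lambda: {"missense": 115, "splice_intronic": 5, "inframe": 4}
    )
    #: target total alternate-allele count over all QC-passing variants
    total_alleles: int = 5636
    de_novo_count: int = 1
    planted_third_allele_patients: int = 3
    #: plant one violator of each QC rule (common allele, low depth, UTR)
    qc_violators: bool = True
    #: sample carrier padding per-individual instead of planting exact counts
    stochastic: bool = False
    recurrence_ac_threshold: int = 10

    @property
    def n_background_vus(self) -> int:
        return sum(self.background_vus_mix.values())

    @property
    def n_background_benign(self) -> int:
        return sum(self.background_benign_mix.values())

    @property
    def n_participants(self) -> int:
        return self.n_rp + self.n_ush + self.n_control

    @property
    def n_solved(self) -> int:
        return self.n_solved_rp + self.n_solved_ush

    def validate(self) -> None:
        counts = [
            self.n_rp, self.n_ush, self.n_control, self.n_trios_rp,
            self.n_trios_ush, self.n_solved_rp, self.n_solved_ush,
            self.de_novo_count, self.planted_third_allele_patients,
        ]
        if any(c < 0 for c in counts):
            raise SimulationError("all cohort counts must be non-negative")
        if not (0.0 <= self.homozygous_fraction <= 1.0):
            raise SimulationError("homozygous_fraction must lie in [0, 1]")
        if self.n_solved_rp > self.n_rp or self.n_solved_ush > self.n_ush:
            raise SimulationError("solved counts exceed phenotype group sizes")
        if self.n_trios_rp > self.n_rp or self.n_trios_ush > self.n_ush:
            raise SimulationError("trio counts exceed phenotype group sizes")
        if 2 * (self.n_trios_rp + self.n_trios_ush) > self.n_control:
            raise SimulationError("not enough control participants for trio parents")
        if self.de_novo_count not in (0, 1):
            raise SimulationError("de_novo_count must be 0 or 1")
        for spec in self.founder_alleles:
            spec.validate()
            if spec.target_ac > 2 * self.n_participants:
                raise SimulationError(
                    f"{spec.variant.key}: target AC {spec.target_ac} exceeds "
                    f"2 x {self.n_participants} chromosomes"
                )


# ---------------------------------------------------------------------------
# internal planting machinery


def _truncating(variant: VariantRecord) -> bool:
    return variant.consequence in TRUNCATING_CONSEQUENCES


class _Pool:
    """Het-allele pool for one impact class, with coverage-first dealing."""

    def __init__(self, counts: "Counter[str]") -> None:
        self.counts = Counter({k: v for k, v in counts.items() if v > 0})

    def total(self) -> int:
        return sum(self.counts.values())

    def pop_max(self, exclude: set[str] = frozenset()) -> str:
        best = None
        for key, n in self.counts.items():
            if n > 0 and key not in exclude and (best is None or n > self.counts[best]):
                best = key
        if best is None:
            raise SimulationError("allele pool exhausted during planting")
        self.counts[best] -= 1
        if self.counts[best] == 0:
            del self.counts[best]
        return best

    def deal(self) -> list[str]:
        """All remaining alleles: one copy of each distinct variant first
        (coverage), then the rest in descending-abundance order."""
        out = []
        remaining = Counter(self.counts)
        for key in sorted(remaining, key=lambda k: -remaining[k]):
            out.append(key)
            remaining[key] -= 1
        for key in sorted(remaining, key=lambda k: -remaining[k]):
            out.extend([key] * remaining[key])
        self.counts.clear()
        return out


def _spread(total: int, n_bins: int) -> list[int]:
    """Split ``total`` alleles over ``n_bins`` variants as evenly as possible."""
    if n_bins == 0:
        if total:
            raise SimulationError("alleles to plant but no variants to carry them")
        return []
    base, rem = divmod(total, n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


def _make_extra_pathogenic(config: SimConfig) -> list[VariantRecord]:
    """Distinct non-recurrent disease-causing variants (synthetic templates)."""
    taken = {f.variant.pos for f in config.founder_alleles}
    variants: list[VariantRecord] = []
    pos = 215630001
    idx = 0
    refs = "ACGT"
    n_truncating = sum(
        n for c, n in config.extra_pathogenic_mix.items()
        if c in TRUNCATING_CONSEQUENCES
    )
    novel_left = min(config.n_novel_plp, n_truncating)
    for consequence, n in sorted(config.extra_pathogenic_mix.items()):
        for _ in range(n):
            while pos in taken:
                pos += 1
            ref = refs[idx % 4]
            alt = refs[(idx + 1) % 4]
            cdna = 15000 + idx
            if consequence == "frameshift":
                hgvs_c, hgvs_p, alt_allele = f"c.{cdna}del", "p.?", ref + alt
                ref_allele, alt_allele = ref + alt, ref
            elif consequence == "inframe":
                hgvs_c, hgvs_p = f"c.{cdna}_{cdna + 2}del", "p.?"
                ref_allele, alt_allele = ref + "CAT", ref
            else:
                hgvs_c, hgvs_p = f"c.{cdna}{ref}>{alt}", (
                    "" if consequence == "splice_intronic" else "p.?"
                )
                ref_allele, alt_allele = ref, alt
            region = (
                "intronic_splice" if consequence == "splice_intronic" else "coding"
            )
            novel = consequence in TRUNCATING_CONSEQUENCES and novel_left > 0
            if novel:
                novel_left -= 1
            preds = (
                {"SIFT": "deleterious", "LRT": "deleterious",
                 "MutationTaster": "deleterious", "FATHMM": "deleterious"}
                if consequence in ("missense", "inframe")
                else {p: "unavailable"
                      for p in ("SIFT", "LRT", "MutationTaster", "FATHMM")}
            )
            variants.append(
                VariantRecord(
                    chrom="chr1", pos=pos, ref=ref_allele, alt=alt_allele,
                    hgvs_c=hgvs_c, hgvs_p=hgvs_p, consequence=consequence,
                    region=region,
                    db_freqs={"gnomad_eas": 0.0, "g1000_eas": 0.0},
                    predictor_verdicts=preds,
                    reported_status="novel" if novel else "reported_pathogenic",
                )
            )
            taken.add(pos)
            pos += 7
            idx += 1
    return variants


def _make_background(config: SimConfig, rng: np.random.Generator) -> list[VariantRecord]:
    variants: list[VariantRecord] = []
    pos = 215900001
    idx = 0
    refs = "GTAC"
    for profile, mix in (("vus", config.background_vus_mix),
                         ("benign", config.background_benign_mix)):
        for consequence, n in sorted(mix.items()):
            for _ in range(n):
                ref = refs[idx % 4]
                alt = refs[(idx + 2) % 4]
                cdna = 2000 + idx
                if profile == "benign":
                    freqs = {
                        "gnomad_global": round(float(rng.uniform(1e-3, 9e-3)), 6),
                        "gnomad_eas": round(float(rng.uniform(1e-3, 9e-3)), 6),
                    }
                    preds = {p: "tolerated"
                             for p in ("SIFT", "LRT", "MutationTaster", "FATHMM")}
                else:
                    freqs = (
                        {"gnomad_global": round(float(rng.uniform(0, 5e-4)), 7)}
                        if rng.random() < 0.5
                        else {}
                    )
                    preds = {
                        "SIFT": "deleterious" if rng.random() < 0.3 else "tolerated",
                        "LRT": "tolerated",
                        "MutationTaster": "deleterious" if rng.random() < 0.3
                        else "tolerated",
                        "FATHMM": "tolerated",
                    }
                region = (
                    "intronic_splice" if consequence == "splice_intronic" else "coding"
                )
                variants.append(
                    VariantRecord(
                        chrom="chr1", pos=pos, ref=ref, alt=alt,
                        hgvs_c=f"c.{cdna}{ref}>{alt}",
                        hgvs_p="" if consequence in ("splice_intronic", "synonymous")
                        else "p.?",
                        consequence=consequence, region=region, db_freqs=freqs,
                        predictor_verdicts=preds,
                        reported_status="reported_conflicting"
                        if profile == "vus" and rng.random() < 0.2 else "novel",
                    )
                )
                pos += 3
                idx += 1
    return variants


def _qc_violators() -> list[VariantRecord]:
    """One deliberate violator of each QC rule."""
    tolerated = {p: "tolerated" for p in ("SIFT", "LRT", "MutationTaster", "FATHMM")}
    return [
        VariantRecord(  # common polymorphism: global MAF above the ceiling
            chrom="chr1", pos=216040111, ref="A", alt="G", hgvs_c="c.6506A>G",
            hgvs_p="p.?", consequence="missense", region="coding",
            db_freqs={"gnomad_global": 0.05, "g1000_global": 0.04,
                      "gnomad_eas": 0.08},
            predictor_verdicts=tolerated, reported_status="novel",
        ),
        VariantRecord(  # every call below the 30x depth floor
            chrom="chr1", pos=216040222, ref="C", alt="T", hgvs_c="c.6400C>T",
            hgvs_p="p.?", consequence="missense", region="coding",
            db_freqs={}, predictor_verdicts=tolerated, reported_status="novel",
        ),
        VariantRecord(  # untranslated-region change
            chrom="chr1", pos=215622950, ref="G", alt="A", hgvs_c="c.*58C>T",
            hgvs_p="", consequence="missense", region="utr",
            db_freqs={"gnomad_eas": 1e-4}, predictor_verdicts=tolerated,
            reported_status="novel",
        ),
    ]


class _Plant:
    """Accumulates genotype calls while enforcing per-participant uniqueness."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.calls: dict[tuple[str, str], GenotypeCall] = {}
        self.by_participant: dict[str, set[str]] = {}

    def add(self, participant: str, key: str, zygosity: str, depth: int | None = None) -> None:
        if key in self.by_participant.get(participant, ()):
            raise SimulationError(
                f"planting would give {participant} two calls at {key}"
            )
        if depth is None:
            depth = int(self.rng.integers(30, 200))
        self.calls[(participant, key)] = GenotypeCall(participant, key, zygosity, depth)
        self.by_participant.setdefault(participant, set()).add(key)

    def keys_of(self, participant: str) -> set[str]:
        return self.by_participant.get(participant, set())


def _solve_combination_split(
    n_patients: int, n_mis: int, n_trunc: int
) -> tuple[int, int, int]:
    """Feasible (mm, mt, tt) patient split for given het-allele pools."""
    if n_mis + n_trunc != 2 * n_patients:
        raise SimulationError("allele pools do not match chet patient count")
    if n_trunc <= n_patients:
        mt = n_trunc
        mm = (n_mis - mt) // 2
        tt = 0
    else:
        mt = n_mis
        mm = 0
        tt = (n_trunc - mt) // 2
    if mm + mt + tt != n_patients:
        raise SimulationError("no feasible combination split for allele pools")
    return mm, mt, tt


def generate(config: SimConfig | None = None) -> Cohort:
    """Generate a synthetic cohort with the configured planted structure.

    Deterministic given ``config.seed``.  Raises :class:`SimulationError`
    when the requested structure is arithmetically infeasible.
    """
    config = config or SimConfig()
    config.validate()
    if config.n_participants == 0:
        return Cohort()
    rng = np.random.default_rng(config.seed)

    # -- participants -----------------------------------------------------
    rp_ids = [f"RP{i:04d}" for i in range(1, config.n_rp + 1)]
    ush_ids = [f"USH{i:04d}" for i in range(1, config.n_ush + 1)]
    ctrl_ids = [f"CT{i:05d}" for i in range(1, config.n_control + 1)]

    trio_probands = {
        "RP": rp_ids[len(rp_ids) - config.n_trios_rp:],
        "USH": ush_ids[len(ush_ids) - config.n_trios_ush:],
    }
    parents: dict[str, tuple[str, str]] = {}
    parent_pool = list(ctrl_ids)
    for ph in ("RP", "USH"):
        for proband in trio_probands[ph]:
            father = parent_pool.pop()
            mother = parent_pool.pop()
            parents[proband] = (father, mother)
    all_parents = {pid for pair in parents.values() for pid in pair}

    # -- solved roster ----------------------------------------------------
    n_hom_total = round(config.homozygous_fraction * config.n_solved)
    founders = config.founder_alleles
    founder_hom = {
        ph: sum(spec.solved.get(ph, (0, 0))[1] for spec in founders)
        for ph in ("RP", "USH")
    }
    n_filler_hom = n_hom_total - founder_hom["RP"] - founder_hom["USH"]
    if n_filler_hom < 0:
        raise SimulationError(
            "founder homozygote shares exceed the homozygous_fraction target"
        )
    filler_hom_ph = {"RP": 0, "USH": 0}
    cap = {"RP": config.n_solved_rp - founder_hom["RP"],
           "USH": config.n_solved_ush - founder_hom["USH"]}
    for i in range(n_filler_hom):
        for ph in (("RP", "USH") if i % 2 == 0 else ("USH", "RP")):
            if filler_hom_ph[ph] < cap[ph]:
                filler_hom_ph[ph] += 1
                break
        else:
            raise SimulationError("cannot place the requested homozygous patients")
    n_hom = {ph: founder_hom[ph] + filler_hom_ph[ph] for ph in ("RP", "USH")}
    n_chet = {"RP": config.n_solved_rp - n_hom["RP"],
              "USH": config.n_solved_ush - n_hom["USH"]}
    if min(n_chet.values()) < 0:
        raise SimulationError("more homozygous patients than solved patients")

    # special compound-het patients are trio probands or singletons with a
    # third allele; all belong to the RP group, as in the emulated cohort
    n_trio_specials = 0
    if config.de_novo_count:
        n_trio_specials += 1  # de-novo proband
    want_demo = config.n_trios_rp >= n_trio_specials + 1 and n_chet["RP"] >= 2
    if want_demo:
        n_trio_specials += 1  # fully trio-phased proband
    n_third = config.planted_third_allele_patients
    third_in_trio = 1 if (n_third and config.n_trios_rp > n_trio_specials) else 0
    n_trio_specials += third_in_trio
    if n_trio_specials > config.n_trios_rp:
        raise SimulationError("not enough RP trios for the requested special cases")
    n_specials = n_trio_specials + (n_third - third_in_trio)
    if n_specials > n_chet["RP"]:
        raise SimulationError("special compound-het patients exceed solved RP chets")

    non_trio_rp = rp_ids[: len(rp_ids) - config.n_trios_rp]
    non_trio_ush = ush_ids[: len(ush_ids) - config.n_trios_ush]
    n_plain_rp = config.n_solved_rp - n_trio_specials
    if n_plain_rp > len(non_trio_rp) or config.n_solved_ush > len(non_trio_ush):
        raise SimulationError("solved patients exceed available non-trio patients")

    special_trio_ids = trio_probands["RP"][:n_trio_specials]
    de_novo_id = special_trio_ids[0] if config.de_novo_count else None
    demo_id = special_trio_ids[1] if want_demo else None
    third_ids = (special_trio_ids[-1:] if third_in_trio else []) + [
        pid for pid in non_trio_rp[:n_third - third_in_trio]
    ]
    offset = n_third - third_in_trio
    hom_ids = {
        "RP": non_trio_rp[offset: offset + n_hom["RP"]],
        "USH": non_trio_ush[: n_hom["USH"]],
    }
    general_ids = {
        "RP": non_trio_rp[offset + n_hom["RP"]: offset + n_hom["RP"]
                          + (n_chet["RP"] - n_specials)],
        "USH": non_trio_ush[n_hom["USH"]: n_hom["USH"] + n_chet["USH"]],
    }
    solved_ids = {
        "RP": set(special_trio_ids) | set(third_ids) | set(hom_ids["RP"])
        | set(general_ids["RP"]),
        "USH": set(hom_ids["USH"]) | set(general_ids["USH"]),
    }
    if (len(solved_ids["RP"]), len(solved_ids["USH"])) != (
        config.n_solved_rp, config.n_solved_ush
    ):
        raise SimulationError("internal error: solved roster size mismatch")

    # -- extra pathogenic variants and their allele budgets ----------------
    extra = _make_extra_pathogenic(config)
    extra_tr = [v for v in extra if _truncating(v)]
    extra_mis = [v for v in extra if not _truncating(v)]
    founder_ac = sum(spec.target_ac for spec in founders)
    filler_ac = config.total_plp_alleles - founder_ac
    hom_fs = [v for v in extra_tr if v.consequence == "frameshift"][: n_filler_hom]
    if len(hom_fs) < n_filler_hom:
        raise SimulationError("not enough frameshift extras to host homozygotes")

    founder_het_solved = {
        ph: sum(spec.solved.get(ph, (0, 0))[0] for spec in founders)
        for ph in ("RP", "USH")
    }
    slots = {
        "RP": 2 * n_chet["RP"] + len(third_ids),
        "USH": 2 * n_chet["USH"],
    }
    filler_het = {ph: slots[ph] - founder_het_solved[ph] for ph in ("RP", "USH")}
    if min(filler_het.values()) < 0:
        raise SimulationError("founder solved shares exceed compound-het slots")

    # truncating/missense split of the filler het alleles, from the
    # combination targets when given
    founder_tr_het = {
        ph: sum(spec.solved.get(ph, (0, 0))[0] for spec in founders
                if _truncating(spec.variant))
        for ph in ("RP", "USH")
    }
    founder_tr_hom_ac = {
        ph: 2 * sum(spec.solved.get(ph, (0, 0))[1] for spec in founders
                    if _truncating(spec.variant))
        for ph in ("RP", "USH")
    }
    filler_tr_het = {}
    for ph in ("RP", "USH"):
        if config.combination_targets and ph in config.combination_targets:
            mm_t, mt_t, tt_t = config.combination_targets[ph]
            if mm_t + mt_t + tt_t != (config.n_solved_rp if ph == "RP"
                                      else config.n_solved_ush):
                raise SimulationError(
                    f"{ph}: combination targets do not sum to the solved count"
                )
            target_tr_ac = mt_t + 2 * tt_t
            have = (founder_tr_het[ph] + founder_tr_hom_ac[ph]
                    + 2 * filler_hom_ph[ph])
            filler_tr_het[ph] = target_tr_ac - have
        else:
            share = len(extra_tr) / max(1, len(extra))
            filler_tr_het[ph] = min(filler_het[ph], round(filler_het[ph] * share))
        if not (0 <= filler_tr_het[ph] <= filler_het[ph]):
            raise SimulationError(
                f"{ph}: combination targets incompatible with planted alleles"
            )
    filler_mis_het = {ph: filler_het[ph] - filler_tr_het[ph] for ph in ("RP", "USH")}

    # per-variant allele budgets for the extras
    demand_tr = filler_tr_het["RP"] + filler_tr_het["USH"]
    demand_mis = filler_mis_het["RP"] + filler_mis_het["USH"]
    carriers_filler = filler_ac - (demand_tr + demand_mis + 2 * n_filler_hom)
    if carriers_filler < 0:
        raise SimulationError(
            "total_plp_alleles too small for the planted solved genotypes"
        )
    het_tr_variants = [v for v in extra_tr if v not in hom_fs]
    tr_counts = _spread(demand_tr, len(het_tr_variants))
    carrier_tr_keys = [
        v.key for v, n in zip(het_tr_variants, tr_counts) if n == 0
    ]
    if len(carrier_tr_keys) > carriers_filler:
        raise SimulationError(
            "not enough filler alleles to give every extra variant one carrier"
        )
    carriers_mis = carriers_filler - len(carrier_tr_keys)
    mis_total = demand_mis + carriers_mis
    if extra_mis and mis_total < len(extra_mis):
        raise SimulationError(
            "not enough filler alleles to give every extra variant one carrier"
        )
    mis_counts = _spread(mis_total, len(extra_mis))
    max_filler = max(mis_counts + tr_counts + [2] if (mis_counts or tr_counts) else [0])
    if max_filler >= config.recurrence_ac_threshold:
        raise SimulationError(
            "filler allele budgets would create additional recurrent alleles"
        )

    # split per-variant budgets into phenotype pools (coverage: every
    # missense extra appears in the larger phenotype pool when possible)
    def split_counts(
        variants: Sequence[VariantRecord], counts: Sequence[int],
        demand: Mapping[str, int],
    ) -> tuple[dict[str, Counter], Counter]:
        order: list[str] = []
        remaining = {v.key: c for v, c in zip(variants, counts)}
        while any(remaining.values()):
            for v in variants:
                if remaining[v.key] > 0:
                    order.append(v.key)
                    remaining[v.key] -= 1
        pools = {"RP": Counter(), "USH": Counter()}
        i = 0
        for ph in ("RP", "USH"):
            for key in order[i: i + demand[ph]]:
                pools[ph][key] += 1
            i += demand[ph]
        leftovers = Counter(order[i:])
        return pools, leftovers

    tr_pools, tr_leftover = split_counts(
        het_tr_variants, tr_counts,
        {"RP": filler_tr_het["RP"], "USH": filler_tr_het["USH"]},
    )
    mis_pools, mis_leftover = split_counts(
        extra_mis, mis_counts,
        {"RP": filler_mis_het["RP"], "USH": filler_mis_het["USH"]},
    )
    filler_carrier_budget = Counter(
        {k: 1 for k in carrier_tr_keys}
    ) + mis_leftover + tr_leftover

    # -- plant genotypes ---------------------------------------------------
    plant = _Plant(rng)
    founder_by_key = {spec.variant.key: spec for spec in founders}
    founder_het_used: Counter = Counter()
    founder_hom_used: Counter = Counter()

    pools = {}
    for ph in ("RP", "USH"):
        tr_counter = Counter(
            {spec.variant.key: spec.solved.get(ph, (0, 0))[0]
             for spec in founders if _truncating(spec.variant)}
        ) + tr_pools[ph]
        mis_counter = Counter(
            {spec.variant.key: spec.solved.get(ph, (0, 0))[0]
             for spec in founders if not _truncating(spec.variant)}
        ) + mis_pools[ph]
        pools[ph] = {"tr": _Pool(tr_counter), "mis": _Pool(mis_counter)}

    def plant_het(pid: str, key: str) -> None:
        plant.add(pid, key, "het")
        if key in founder_by_key:
            founder_het_used[key] += 1

    def plant_parent_het(pid: str, key: str) -> None:
        plant.add(pid, key, "het")
        if key in founder_by_key:
            founder_het_used[key] += 1
            if founder_het_used[key] > founder_by_key[key].cohort_het:
                raise SimulationError(
                    f"{key}: trio parents exceed the cohort het target"
                )
        else:
            filler_carrier_budget[key] -= 1  # may go negative; rebalanced below

    # special trio probands
    special_class: dict[str, str] = {}
    if de_novo_id:
        mis_key = pools["RP"]["mis"].pop_max()
        tr_key = pools["RP"]["tr"].pop_max()
        plant_het(de_novo_id, mis_key)  # de novo: in neither parent
        plant_het(de_novo_id, tr_key)
        _, mother = parents[de_novo_id]
        plant_parent_het(mother, tr_key)
        special_class[de_novo_id] = "missense_truncating"
    if demo_id:
        k1 = pools["RP"]["mis"].pop_max()
        k2 = pools["RP"]["mis"].pop_max(exclude={k1})
        plant_het(demo_id, k1)
        plant_het(demo_id, k2)
        father, mother = parents[demo_id]
        plant_parent_het(father, k1)
        plant_parent_het(mother, k2)
        special_class[demo_id] = "missense_missense"
    for i, pid in enumerate(third_ids):
        tr_key = pools["RP"]["tr"].pop_max()
        m1 = pools["RP"]["mis"].pop_max()
        m2 = pools["RP"]["mis"].pop_max(exclude={m1})
        for key in (tr_key, m1, m2):
            plant_het(pid, key)
        if pid in parents:  # trio: paternal truncating, maternal missense pair
            father, mother = parents[pid]
            plant_parent_het(father, tr_key)
            plant_parent_het(mother, m1)
            plant_parent_het(mother, m2)
        special_class[pid] = "missense_truncating"

    # homozygous patients
    hom_alleles = {"RP": [], "USH": []}
    for spec in founders:
        for ph in ("RP", "USH"):
            hom_alleles[ph].extend([spec.variant.key] * spec.solved.get(ph, (0, 0))[1])
    fs_iter = iter(hom_fs)
    for ph in ("RP", "USH"):
        hom_alleles[ph].extend(v.key for v in
                               [next(fs_iter) for _ in range(filler_hom_ph[ph])])
        if len(hom_alleles[ph]) != len(hom_ids[ph]):
            raise SimulationError("internal error: homozygote allocation mismatch")
        for pid, key in zip(hom_ids[ph], hom_alleles[ph]):
            plant.add(pid, key, "hom")
            if key in founder_by_key:
                founder_hom_used[key] += 1

    # general compound-het patients
    for ph in ("RP", "USH"):
        ids = general_ids[ph]
        mis_n = pools[ph]["mis"].total()
        tr_n = pools[ph]["tr"].total()
        if config.combination_targets and ph in config.combination_targets:
            mm_t, mt_t, tt_t = config.combination_targets[ph]
            hom_tt = sum(1 for k in hom_alleles[ph]
                         if k not in founder_by_key or
                         _truncating(founder_by_key[k].variant))
            hom_mm = len(hom_alleles[ph]) - hom_tt
            sp = [special_class[p] for p in special_class
                  if (p in solved_ids[ph])]
            mm = mm_t - hom_mm - sp.count("missense_missense")
            mt = mt_t - sp.count("missense_truncating")
            tt = tt_t - hom_tt - sp.count("truncating_truncating")
            if (mm < 0 or mt < 0 or tt < 0 or mm + mt + tt != len(ids)
                    or 2 * mm + mt != mis_n or mt + 2 * tt != tr_n):
                raise SimulationError(
                    f"{ph}: combination targets infeasible with planted alleles"
                )
        else:
            mm, mt, tt = _solve_combination_split(len(ids), mis_n, tr_n)
        mis_list = pools[ph]["mis"].deal()
        tr_list = pools[ph]["tr"].deal()
        # patient allele pairs: mt pairs first (coverage of every missense
        # extra by a truncating partner), then mm, then tt
        pairs: list[tuple[str, str]] = []
        for i in range(mt):
            pairs.append((mis_list[i], tr_list[i]))
        mis_rest = mis_list[mt:]
        for i in range(mm):
            a, b = mis_rest[i], mis_rest[mm + i]
            pairs.append((a, b))
        tr_rest = tr_list[mt:]
        for i in range(tt):
            pairs.append((tr_rest[i], tr_rest[tt + i]))
        for pid, (a, b) in zip(ids, pairs):
            if a == b:  # repair: swap with another pair sharing no allele
                for j, (c, d) in enumerate(pairs):
                    if c not in (a, b) and d not in (a, b):
                        pairs[j] = (c, a)
                        b = d
                        break
                else:
                    raise SimulationError("cannot pair alleles without duplicates")
            plant_het(pid, a)
            plant_het(pid, b)

    # -- carrier padding to the cohort targets -----------------------------
    trio_members = set(all_parents)
    for ph in ("RP", "USH"):
        trio_members.update(trio_probands[ph])
    host_pool = [
        pid for pid in ctrl_ids + rp_ids + ush_ids
        if pid not in trio_members
        and pid not in solved_ids["RP"] and pid not in solved_ids["USH"]
    ]
    rng.shuffle(host_pool)
    host_iter = iter(host_pool)

    def next_host(key: str) -> str:
        for pid in host_iter:
            if key not in plant.keys_of(pid):
                return pid
        raise SimulationError("ran out of carrier hosts")

    ird_carrier_hosts: set[str] = set()
    pad_jobs: list[tuple[str, int, int]] = []
    for spec in founders:
        pad_het = spec.cohort_het - founder_het_used[spec.variant.key]
        pad_hom = spec.cohort_hom - founder_hom_used[spec.variant.key]
        if pad_het < 0 or pad_hom < 0:
            raise SimulationError(
                f"{spec.variant.key}: planted carriers exceed the cohort target"
            )
        pad_jobs.append((spec.variant.key, pad_het, pad_hom))
    # rebalance filler carrier budgets driven negative by trio parents
    deficit = [k for k, n in filler_carrier_budget.items() if n < 0]
    for key in deficit:
        need = -filler_carrier_budget[key]
        filler_carrier_budget[key] = 0
        donors = sorted(
            (k for k, n in filler_carrier_budget.items() if n > 0),
            key=lambda k: -filler_carrier_budget[k],
        )
        for donor in donors:
            take = min(need, filler_carrier_budget[donor])
            filler_carrier_budget[donor] -= take
            need -= take
            if need == 0:
                break
        if need:
            raise SimulationError("filler carrier budget exhausted by trio parents")
    for key, n in sorted(filler_carrier_budget.items()):
        if n > 0:
            pad_jobs.append((key, n, 0))

    for key, pad_het, pad_hom in pad_jobs:
        if config.stochastic and key in founder_by_key:
            n_hosts = len(host_pool)
            p = min(1.0, pad_het / max(1, n_hosts))
            pad_het = int(rng.binomial(n_hosts, p))
        for _ in range(pad_het):
            pid = next_host(key)
            plant.add(pid, key, "het")
            if pid.startswith(("RP", "USH")):
                ird_carrier_hosts.add(pid)
        for _ in range(pad_hom):
            pid = next_host(key)
            plant.add(pid, key, "hom")
            if pid.startswith(("RP", "USH")):
                ird_carrier_hosts.add(pid)

    # -- background and QC-violator variants -------------------------------
    background = _make_background(config, rng)
    violators = _qc_violators() if config.qc_violators else []
    background_ac = config.total_alleles - config.total_plp_alleles
    if background_ac < len(background):
        if background:
            raise SimulationError("total_alleles too small for background variants")
        background_ac = 0
    # background hosts: never trio members (a proband's every allele must have
    # a parental origin or be the planted de-novo event) and never patients
    # already carrying a disease-causing allele (background must not inflate
    # the in-trans evidence of causal alleles)
    bg_eligible = np.array(
        [
            pid for pid in ctrl_ids + rp_ids + ush_ids
            if pid not in trio_members
            and pid not in ird_carrier_hosts
            and pid not in solved_ids["RP"]
            and pid not in solved_ids["USH"]
        ]
    )
    if background:
        counts = np.ones(len(background), dtype=int)
        extra_alleles = background_ac - len(background)
        weights = rng.pareto(2.0, size=len(background)) + 0.2
        counts += rng.multinomial(extra_alleles, weights / weights.sum())
        cap = max(1, int(0.009 * 2 * config.n_participants))
        while counts.max() > cap:
            i = int(counts.argmax())
            counts[int(counts.argmin())] += counts[i] - cap
            counts[i] = cap
        for v, n in zip(background, counts):
            hosts = rng.choice(bg_eligible, size=int(n), replace=False)
            for pid in hosts:
                plant.add(str(pid), v.key, "het")
    if violators:
        common, lowdepth, utr = violators
        for pid in rng.choice(bg_eligible, size=min(300, len(bg_eligible)),
                              replace=False):
            plant.add(str(pid), common.key, "het")
        for pid in rng.choice(bg_eligible, size=min(5, len(bg_eligible)),
                              replace=False):
            plant.add(str(pid), lowdepth.key, "het", depth=10)
        for pid in rng.choice(bg_eligible, size=min(5, len(bg_eligible)),
                              replace=False):
            plant.add(str(pid), utr.key, "het")

    # -- ages and participant records --------------------------------------
    combo_of: dict[str, str] = dict(special_class)
    variant_index = {
        v.key: v for v in
        [s.variant for s in founders] + extra + background + violators
    }
    for ph in ("RP", "USH"):
        for pid, key in zip(hom_ids[ph], hom_alleles[ph]):
            combo_of[pid] = (
                "truncating_truncating" if _truncating(variant_index[key])
                else "missense_missense"
            )
        for pid in general_ids[ph]:
            flags = sorted(
                (_truncating(variant_index[k]) for k in plant.keys_of(pid)),
                reverse=True,
            )[:2]
            combo_of[pid] = (
                "truncating_truncating" if sum(flags) == 2
                else "missense_truncating" if sum(flags) == 1
                else "missense_missense"
            )

    def draw_age(pid: str) -> float:
        if pid in combo_of:
            mean, sd = AGE_MODEL[combo_of[pid]]
        else:
            mean, sd = 45.0, 18.0
        return round(float(np.clip(rng.normal(mean, sd), *AGE_RANGE)), 1)

    participants: list[Participant] = []
    child_of = {pid: proband for proband, pair in parents.items() for pid in pair}
    for pid in rp_ids + ush_ids + ctrl_ids:
        if pid.startswith("RP"):
            cohort_label, phenotype = "ird", "RP"
        elif pid.startswith("USH"):
            cohort_label, phenotype = "ird", "USH"
        else:
            cohort_label = "control"
            phenotype = "healthy" if pid in child_of else (
                "other_ied" if rng.random() < 0.5 else "healthy"
            )
        if pid in parents:
            family = f"FAM_{pid}"
            father, mother = parents[pid]
        elif pid in child_of:
            family = f"FAM_{child_of[pid]}"
            father = mother = None
        else:
            family = f"FAM_{pid}"
            father = mother = None
        age = draw_age(pid)
        if pid in child_of:
            age = round(min(AGE_RANGE[1], age + 27.0), 1)
        participants.append(
            Participant(
                participant_id=pid, cohort=cohort_label, phenotype=phenotype,
                family_id=family, father_id=father, mother_id=mother,
                age_years=age,
            )
        )

    variants = [s.variant for s in founders] + extra + background + violators
    cohort = Cohort(participants, variants, plant.calls.values())

    # reference-homozygous parental depths at sites their proband carries,
    # needed to separate de-novo events from parental dropout
    for proband, (father, mother) in parents.items():
        for key in plant.keys_of(proband):
            for parent in (father, mother):
                if key not in plant.keys_of(parent):
                    cohort.ref_depths[(parent, key)] = int(rng.integers(60, 150))
    return cohort


def config_from_dict(raw: Mapping, seed: int | None = None) -> SimConfig:
    """Build a :class:`SimConfig` from a plain mapping (e.g. parsed YAML).

    ``founder_alleles`` entries are mappings with ``cohort_het``,
    ``cohort_hom`` and ``solved`` (phenotype -> [het, hom]); the variant
    itself is either ``template: <index>`` into the default recurrent-allele
    templates or a full ``variant`` field mapping.
    """
    raw = dict(raw)
    if seed is not None:
        raw["seed"] = seed
    if "founder_alleles" in raw and raw["founder_alleles"] is not None:
        specs = []
        for entry in raw["founder_alleles"]:
            if "template" in entry:
                variant = DEFAULT_FOUNDERS[int(entry["template"])].variant
            else:
                variant = VariantRecord(**entry["variant"])
            solved = {
                ph: (int(h), int(m))
                for ph, (h, m) in (entry.get("solved") or {}).items()
            }
            specs.append(
                FounderSpec(
                    variant, int(entry["cohort_het"]), int(entry["cohort_hom"]),
                    solved,
                )
            )
        raw["founder_alleles"] = tuple(specs)
    if raw.get("combination_targets"):
        raw["combination_targets"] = {
            ph: tuple(v) for ph, v in raw["combination_targets"].items()
        }
    return SimConfig(**raw)


_FIXTURE_CACHE: dict[int, Cohort] = {}


def fixture_reference() -> Cohort:
    """The packaged default-parameter, seed-42 reference cohort (cached)."""
    if 42 not in _FIXTURE_CACHE:
        _FIXTURE_CACHE[42] = generate(SimConfig())
    return _FIXTURE_CACHE[42]
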
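"""Allele-count spectra, founder/hot-spot labelling and RP-vs-USH statistics.

The spectrum is built over the disease-causing (P/LP) alleles only.  A row
counts heterozygous and homozygous carriers within a scope — the whole
cohort, all solved patients, or the solved RP / USH subgroups — so that
``AC = n_het + 2 * n_hom`` and ``alt_freq = AC / (2 * n_scope)``.

Recurrent alleles (AC at or above a recurrence threshold, 10 by default)
are labelled from their reference-database footprint: an allele observed at
a positive frequency in any non-East-Asian subpopulation recurs across
populations and is called a *hot-spot* mutation; one confined to East Asia
(all non-East-Asian keys absent or zero) is called a *founder* mutation.

Phenotype contrasts use a Pearson chi-square on the RP x USH contingency
table of genotype-combination classes, falling back to an exact
(Freeman-Halton) test when any expected cell drops below five.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .acmg import ClassifiedVariant, is_disease_causing
from .model import NON_EAS_FREQ_KEYS, Cohort, VariantRecord
from .qc import is_truncating
from .resolution import COMBINATION_CLASSES, ResolvedCase

__all__ = [
    "SCOPES",
    "SpectrumRow",
    "EnrichmentResult",
    "build_spectrum",
    "classify_recurrent",
    "allele_type_breakdown",
    "truncating_fraction",
    "combination_contingency",
    "variant_enrichment",
    "summary_metrics",
]

SCOPES = ("all_participants", "solved_patients", "solved_rp", "solved_ush")

CONSEQUENCE_ORDER = ("missense", "splice_intronic", "frameshift", "nonsense", "inframe")


@dataclass(frozen=True)
class SpectrumRow:
    variant_key: str
    n_het: int
    n_hom: int
    ac: int
    alt_freq: float
    scope: str
    label: str = "none"  # founder | hot_spot | none

    def __post_init__(self) -> None:
        if self.ac != self.n_het + 2 * self.n_hom:
            raise ValueError(
                f"{self.variant_key}: AC {self.ac} != n_het + 2*n_hom "
                f"({self.n_het} + 2*{self.n_hom})"
            )
        if not (0.0 <= self.alt_freq <= 1.0):
            raise ValueError(f"{self.variant_key}: alt_freq outside [0, 1]")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.label != "none" and self.scope != "all_participants":
            raise ValueError("recurrence labels only apply to the full-cohort scope")


def _scope_participants(
    cohort: Cohort, resolved: Sequence[ResolvedCase], scope: str
) -> list[str]:
    if scope == "all_participants":
        return list(cohort.participants)
    solved = {c.participant_id: c.phenotype for c in resolved}
    if scope == "solved_patients":
        return list(solved)
    want = "RP" if scope == "solved_rp" else "USH"
    return [pid for pid, ph in solved.items() if ph == want]


def build_spectrum(
    cohort: Cohort,
    classifications: Mapping[str, ClassifiedVariant],
    scope: str = "all_participants",
    resolved: Sequence[ResolvedCase] = (),
    ac_threshold: int = 10,
) -> list[SpectrumRow]:
    """One row per P/LP variant with surviving calls in the scope.

    Rows are sorted by descending allele count, ties by genomic position.
    In the full-cohort scope each recurrent row also carries its
    founder/hot-spot label.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    members = set(_scope_participants(cohort, resolved, scope))
    if not members:
        return []
    denominator = 2 * len(members)
    rows = []
    for key, cv in classifications.items():
        if not is_disease_causing(cv) or key not in cohort.variants:
            continue
        calls = [c for c in cohort.calls_of_variant(key) if c.participant_id in members]
        if not calls:
            continue
        n_het = sum(1 for c in calls if c.zygosity == "het")
        n_hom = len(calls) - n_het
        ac = n_het + 2 * n_hom
        row = SpectrumRow(
            variant_key=key,
            n_het=n_het,
            n_hom=n_hom,
            ac=ac,
            alt_freq=ac / denominator,
            scope=scope,
        )
        if scope == "all_participants":
            label = classify_recurrent(row, cohort.variants[key], ac_threshold)
            row = SpectrumRow(**{**row.__dict__, "label": label})
        rows.append(row)
    def _pos(row: SpectrumRow) -> int:
        return cohort.variants[row.variant_key].pos
    return sorted(rows, key=lambda r: (-r.ac, _pos(r)))


def classify_recurrent(
    row: SpectrumRow, variant: VariantRecord, ac_threshold: int = 10
) -> str:
    """Label a full-cohort spectrum row as founder, hot_spot or none.

    Below the recurrence threshold the label is "none".  At or above it,
    presence (strictly positive frequency) under any non-East-Asian
    subpopulation key marks a hot spot; zero entries count as absent, so an
    allele printed as 0 everywhere outside East Asia is still a founder.
    """
    if row.ac < ac_threshold:
        return "none"
    for key in NON_EAS_FREQ_KEYS:
        if variant.db_freqs.get(key, 0.0) > 0.0:
            return "hot_spot"
    return "founder"


def allele_type_breakdown(
    cases: Sequence[ResolvedCase], cohort: Cohort, phenotype: str | None = None
) -> dict[str, int]:
    """Causal-allele counts per consequence class for a case set.

    A homozygote contributes two alleles.  Restricting to a phenotype
    ("RP"/"USH") mirrors the per-subgroup breakdowns; ``None`` pools all
    cases.
    """
    counts = {c: 0 for c in CONSEQUENCE_ORDER}
    for case in cases:
        if phenotype is not None and case.phenotype != phenotype:
            continue
        for call in case.variants:
            cons = cohort.variants[call.variant_key].consequence
            counts[cons] = counts.get(cons, 0) + call.allele_count
    return counts


def truncating_fraction(counts: Mapping[str, int]) -> float:
    """Fraction of causal alleles that are truncating (splice + frameshift +
    nonsense) in a per-consequence allele-count map."""
    total = sum(counts.values())
    if total == 0:
        return 0.0
    truncating = sum(
        n for cons, n in counts.items() if cons in ("splice_intronic", "frameshift", "nonsense")
    )
    return truncating / total


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[tuple[int, ...], ...]
    test: str  # "chi_square" | "fisher_exact"
    statistic: float | None
    p_value: float
    tier: str  # "", "*", "**", "***"


def _significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _fisher_exact_2xc(table: np.ndarray) -> float:
    """Freeman-Halton exact test for a 2 x C table.

    Enumerates all tables with the observed margins and sums, in log space,
    the conditional hypergeometric probabilities not exceeding that of the
    observed table.
    """
    table = np.asarray(table, dtype=int)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()

    def log_prob(first_row: np.ndarray) -> float:
        second = col - first_row
        logp = (
            gammaln(row + 1).sum()
            + gammaln(col + 1).sum()
            - gammaln(n + 1)
            - gammaln(first_row + 1).sum()
            - gammaln(second + 1).sum()
        )
        return float(logp)

    observed = log_prob(table[0])
    total = 0.0
    ncols = table.shape[1]

    def recurse(idx: int, remaining: int, prefix: list[int]) -> None:
        nonlocal total
        if idx == ncols - 1:
            cells = np.array(prefix + [remaining])
            if np.all(cells <= col[: len(cells)]) and remaining <= col[-1]:
                lp = log_prob(cells)
                if lp <= observed + 1e-9:
                    total += float(np.exp(lp))
            return
        for k in range(min(remaining, col[idx]) + 1):
            recurse(idx + 1, remaining - k, prefix + [k])

    recurse(0, int(row[0]), [])
    return min(total, 1.0)


def combination_contingency(
    cases: Sequence[ResolvedCase], method: str = "auto"
) -> EnrichmentResult:
    """RP-vs-USH contrast of genotype-combination classes (2 x 3 table).

    Pearson chi-square without continuity correction; when any expected
    cell is below five (or ``method="fisher"``), the Freeman-Halton exact
    test is used instead.
    """
    table = np.zeros((2, len(COMBINATION_CLASSES)), dtype=int)
    for case in cases:
        row = {"RP": 0, "USH": 1}[case.phenotype]
        col = COMBINATION_CLASSES.index(case.combination_class)
        table[row, col] += 1
    return contingency_test(table, method=method)


def contingency_test(table, method: str = "auto") -> EnrichmentResult:
    table = np.asarray(table, dtype=int)
    if np.any(table < 0):
        raise ValueError("contingency counts must be non-negative")
    for name, row in zip(("RP", "USH"), table):
        if row.sum() == 0:
            raise ValueError(f"phenotype {name} has no cases")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    use_fisher = method == "fisher" or (method == "auto" and (expected < 5).any())
    if use_fisher:
        p = _fisher_exact_2xc(table)
        result = EnrichmentResult(
            tuple(tuple(int(x) for x in r) for r in table),
            "fisher_exact", None, p, _significance_tier(p),
        )
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        result = EnrichmentResult(
            tuple(tuple(int(x) for x in r) for r in table),
            "chi_square", float(chi2), float(p), _significance_tier(float(p)),
        )
    return result


def variant_enrichment(
    spectrum_rp: Sequence[SpectrumRow],
    spectrum_ush: Sequence[SpectrumRow],
    freq_threshold: float = 0.01,
) -> dict[str, dict[str, bool | float]]:
    """Per-variant subgroup enrichment flags at an allele-frequency threshold.

    Mirrors the convention of calling a causal allele "enriched" in a solved
    subgroup when its within-subgroup alternate-allele frequency exceeds the
    threshold (a frequency rule, not a hypothesis test).
    """
    rp = {r.variant_key: r.alt_freq for r in spectrum_rp}
    ush = {r.variant_key: r.alt_freq for r in spectrum_ush}
    out: dict[str, dict[str, bool | float]] = {}
    for key in sorted(set(rp) | set(ush)):
        f_rp = rp.get(key, 0.0)
        f_ush = ush.get(key, 0.0)
        out[key] = {
            "alt_freq_rp": f_rp,
            "alt_freq_ush": f_ush,
            "enriched_rp": f_rp > freq_threshold,
            "enriched_ush": f_ush > freq_threshold,
            "ush_over_rp": f_ush > f_rp,
        }
    return out


def summary_metrics(
    cohort: Cohort,
    classifications: Mapping[str, ClassifiedVariant],
    resolved: Sequence[ResolvedCase],
    carriers: Sequence,
    top_k: int = 11,
) -> dict:
    """Headline cohort metrics, keyed stably for downstream reporting."""
    patients = cohort.ird_patients()
    n_rp = sum(1 for p in patients if p.phenotype == "RP")
    n_ush = sum(1 for p in patients if p.phenotype == "USH")
    solved_rp = [c for c in resolved if c.phenotype == "RP"]
    solved_ush = [c for c in resolved if c.phenotype == "USH"]
    n_hom = sum(1 for c in resolved if c.configuration == "homozygous")
    n_chet = len(resolved) - n_hom

    spectrum = build_spectrum(cohort, classifications, "all_participants", resolved)
    total_ac = sum(r.ac for r in spectrum)
    top_rows = spectrum[:top_k]
    top_ac = sum(r.ac for r in top_rows)

    plp = [cv for cv in classifications.values() if is_disease_causing(cv)]
    n_truncating = sum(1 for cv in plp if is_truncating(cv.variant))

    union_fraction = 0.0
    top2_keys = [r.variant_key for r in spectrum[:2]]
    if resolved and top2_keys:
        carriers_of_top2 = sum(
            1 for c in resolved if any(k in c.variant_keys for k in top2_keys)
        )
        union_fraction = carriers_of_top2 / len(resolved)

    ages: dict[str, dict[str, float | int]] = {}
    for cls in COMBINATION_CLASSES:
        vals = [
            cohort.participants[c.participant_id].age_years
            for c in resolved
            if c.combination_class == cls
            and cohort.participants[c.participant_id].age_years is not None
        ]
        ages[cls] = {
            "n": len(vals),
            "mean": float(np.mean(vals)) if vals else float("nan"),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
        }

    def frac(a: int, b: int) -> float:
        return a / b if b else 0.0

    return {
        "n_participants": cohort.n_participants,
        "n_ird": len(patients),
        "n_rp": n_rp,
        "n_ush": n_ush,
        "n_trios": len([t for t in cohort.trios()
                        if cohort.participants[t.proband_id].cohort == "ird"]),
        "solved_total": len(resolved),
        "solved_rp": len(solved_rp),
        "solved_ush": len(solved_ush),
        "solved_fraction_overall": frac(len(resolved), len(patients)),
        "solved_fraction_rp": frac(len(solved_rp), n_rp),
        "solved_fraction_ush": frac(len(solved_ush), n_ush),
        "n_homozygous": n_hom,
        "n_compound_het": n_chet,
        "homozygous_fraction": frac(n_hom, len(resolved)),
        "n_distinct_plp": len(plp),
        "n_distinct_variants": len(cohort.variants),
        "total_plp_ac": total_ac,
        "total_alleles": sum(c.allele_count for c in cohort.calls),
        "truncating_share_distinct": frac(n_truncating, len(plp)),
        "top_k": top_k,
        "top_k_ac": top_ac,
        "top_k_allele_share": frac(top_ac, total_ac),
        "union_top2_fraction": union_fraction,
        "n_carriers": len(carriers),
        "carrier_fraction": frac(
            len(carriers) + len(resolved), cohort.n_participants
        ),
        "n_de_novo": sum(len(c.de_novo_variants) for c in resolved),
        "age_by_combination": ages,
    }
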
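"""Variant quality control.

Three filters are applied before any classification:

1. **Population frequency** — a variant is excluded when any *global*
   reference-database allele frequency (1000 Genomes, ExAC, gnomAD, ESP6500,
   dbSNP) exceeds the MAF ceiling (default 0.01).  Subpopulation keys, East
   Asian ones in particular, never trigger exclusion: recurrent founder
   alleles legitimately reach East-Asian frequencies of a few per-mille while
   remaining globally rare.  An absent key is treated as frequency zero.
2. **Sequencing depth** — a genotype call is excluded when the site is
   covered by fewer than 30 reads (a call at exactly 30x survives).
3. **Region** — variants in untranslated regions are excluded.

The three filters commute and each partitions its input, which the test
suite asserts as properties.  Synonymous variants deliberately pass QC; they
are set aside later, by classification, not here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .model import (
    GLOBAL_FREQ_KEYS,
    REGIONS,
    TRUNCATING_CONSEQUENCES,
    Cohort,
    CohortError,
    GenotypeCall,
    VariantRecord,
)

__all__ = [
    "QcConfig",
    "QcLog",
    "filter_by_frequency",
    "filter_by_depth",
    "filter_by_region",
    "is_truncating",
    "apply_qc",
]

log = logging.getLogger(__name__)


@dataclass
class QcConfig:
    maf_threshold: float = 0.01
    min_depth: int = 30
    excluded_regions: frozenset[str] = frozenset({"utr"})
    #: "per_call" drops individual low-depth calls; "per_variant" drops the
    #: whole variant as soon as one of its calls fails the depth rule.
    depth_mode: str = "per_call"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold < 1.0):
            raise ValueError("maf_threshold must lie in (0, 1)")
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")
        if self.depth_mode not in ("per_call", "per_variant"):
            raise ValueError(f"unknown depth_mode {self.depth_mode!r}")
        self.excluded_regions = frozenset(self.excluded_regions)
        unknown = self.excluded_regions - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels {sorted(unknown)}")


def filter_by_frequency(
    variants: Iterable[VariantRecord], config: QcConfig | None = None
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split variants into (kept, removed) by the global-MAF rule."""
    config = config or QcConfig()
    kept, removed = [], []
    for v in variants:
        for key, af in v.db_freqs.items():
            if not (0.0 <= af <= 1.0):
                raise CohortError(f"{v.key}: frequency {key}={af} outside [0, 1]")
        if any(v.db_freqs.get(k, 0.0) > config.maf_threshold for k in GLOBAL_FREQ_KEYS):
            removed.append(v)
        else:
            kept.append(v)
    return kept, removed


def filter_by_depth(
    calls: Iterable[GenotypeCall], config: QcConfig | None = None
) -> tuple[list[GenotypeCall], list[GenotypeCall]]:
    """Split genotype calls into (kept, removed) by the depth rule."""
    config = config or QcConfig()
    kept, removed = [], []
    for c in calls:
        if c.depth < 0:
            raise CohortError(f"{c.participant_id}@{c.variant_key}: negative depth")
        (removed if c.depth < config.min_depth else kept).append(c)
    return kept, removed


def filter_by_region(
    variants: Iterable[VariantRecord], config: QcConfig | None = None
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split variants into (kept, removed) by the region rule."""
    config = config or QcConfig()
    kept, removed = [], []
    for v in variants:
        if v.region not in REGIONS:
            raise CohortError(f"{v.key}: unknown region {v.region!r}")
        (removed if v.region in config.excluded_regions else kept).append(v)
    return kept, removed


def is_truncating(variant: VariantRecord) -> bool:
    """True for nonsense, frameshift and intronic splice-site changes."""
    return variant.consequence in TRUNCATING_CONSEQUENCES


@dataclass
class QcLog:
    """Audit trail of everything a QC run removed."""

    removed_variants: list[tuple[str, str, str]] = field(default_factory=list)
    removed_calls: list[tuple[str, str, str]] = field(default_factory=list)

    def record_variant(self, key: str, rule: str, detail: str) -> None:
        self.removed_variants.append((key, rule, detail))
        log.info("QC removed variant %s (%s: %s)", key, rule, detail)

    def record_call(self, participant: str, key: str, detail: str) -> None:
        self.removed_calls.append((participant, key, detail))
        log.info("QC removed call %s@%s (%s)", participant, key, detail)

    @property
    def n_removed_variants(self) -> int:
        return len(self.removed_variants)


def apply_qc(cohort: Cohort, config: QcConfig | None = None) -> tuple[Cohort, QcLog]:
    """Run all three filters and return the surviving cohort plus a log.

    Variants removed by the frequency or region rule lose all their calls.
    Depth filtering acts on the remaining calls; a variant whose calls are
    all removed is dropped from the output entirely (it contributes an
    allele count of zero and can never appear in a spectrum).
    """
    config = config or QcConfig()
    qclog = QcLog()

    kept, removed = filter_by_frequency(cohort.variants.values(), config)
    for v in removed:
        worst = max(v.db_freqs.get(k, 0.0) for k in GLOBAL_FREQ_KEYS)
        qclog.record_variant(v.key, "maf", f"global frequency {worst:g} > {config.maf_threshold}")
    kept, removed = filter_by_region(kept, config)
    for v in removed:
        qclog.record_variant(v.key, "region", f"region {v.region} excluded")

    keys = {v.key for v in kept}
    surviving_calls = []
    failed_variants: set[str] = set()
    for c in cohort.calls:
        if c.variant_key not in keys:
            continue
        if c.depth < config.min_depth:
            qclog.record_call(
                c.participant_id, c.variant_key, f"depth {c.depth} < {config.min_depth}"
            )
            failed_variants.add(c.variant_key)
        else:
            surviving_calls.append(c)
    if config.depth_mode == "per_variant":
        surviving_calls = [
            c for c in surviving_calls if c.variant_key not in failed_variants
        ]
        for k in sorted(failed_variants & keys):
            qclog.record_variant(k, "depth", "low-depth call under per-variant mode")
        keys -= failed_variants

    covered = {c.variant_key for c in surviving_calls}
    final_variants = [v for v in kept if v.key in keys and v.key in covered]
    for v in kept:
        if v.key in keys and v.key not in covered:
            qclog.record_variant(v.key, "depth", "no surviving calls")
    qc_cohort = Cohort(
        cohort.participants.values(), final_variants, surviving_calls, cohort.ref_depths
    )
    return qc_cohort, qclog
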
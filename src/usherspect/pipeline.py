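"""End-to-end orchestration: QC -> classification -> resolution -> spectra.

:func:`run_pipeline` sequences the stages on an in-memory cohort or on the
four input files, writes all tabular artifacts plus a JSON summary into an
output directory, and is fully deterministic for identical inputs and
configuration.  :func:`render_report` turns the artifacts into a compact
markdown report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from . import io as cohort_io
from .acmg import AcmgParams, classify_cohort
from .model import Cohort
from .qc import QcConfig, apply_qc
from .resolution import find_carriers, resolve_patients
from .spectrum import (
    allele_type_breakdown,
    build_spectrum,
    combination_contingency,
    summary_metrics,
    truncating_fraction,
    variant_enrichment,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "render_report"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    qc: QcConfig = field(default_factory=QcConfig)
    acmg: AcmgParams = field(default_factory=AcmgParams)
    ac_threshold: int = 10
    freq_threshold: float = 0.01
    top_k: int = 11

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc_raw = raw.get("qc", {})
        if "excluded_regions" in qc_raw:
            qc_raw["excluded_regions"] = frozenset(qc_raw["excluded_regions"])
        acmg_raw = raw.get("acmg", {})
        if "enabled" in acmg_raw:
            acmg_raw["enabled"] = frozenset(acmg_raw["enabled"])
        return cls(
            qc=QcConfig(**qc_raw),
            acmg=AcmgParams(**acmg_raw),
            ac_threshold=int(raw.get("ac_threshold", 10)),
            freq_threshold=float(raw.get("freq_threshold", 0.01)),
            top_k=int(raw.get("top_k", 11)),
        )


@dataclass
class PipelineResult:
    cohort: Cohort  # post-QC
    qc_log: object
    classifications: dict
    resolved: list
    carriers: list
    spectra: dict
    enrichment: dict
    summary: dict
    artifacts: dict[str, Path] = field(default_factory=dict)


def run_pipeline(
    cohort: Cohort | None = None,
    *,
    vcf: str | Path | None = None,
    ped: str | Path | None = None,
    phenotypes: str | Path | None = None,
    freqs: str | Path | None = None,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis and optionally write artifacts to ``outdir``."""
    config = config or RunConfig()
    if cohort is None:
        if not all((vcf, ped, phenotypes, freqs)):
            raise ValueError("provide either a cohort or all four input paths")
        log.info("reading cohort from %s", vcf)
        cohort = cohort_io.read_cohort(vcf, ped, phenotypes, freqs)
    log.info("input: %r", cohort)

    qc_cohort, qc_log = apply_qc(cohort, config.qc)
    log.info(
        "QC removed %d variants and %d calls",
        len(qc_log.removed_variants),
        len(qc_log.removed_calls),
    )
    classifications = classify_cohort(
        qc_cohort, config.acmg, min_depth=config.qc.min_depth
    )
    resolved = resolve_patients(qc_cohort, classifications, config.qc.min_depth)
    carriers = find_carriers(qc_cohort, classifications, resolved)

    spectra = {
        scope: build_spectrum(
            qc_cohort, classifications, scope, resolved, config.ac_threshold
        )
        for scope in ("all_participants", "solved_patients", "solved_rp", "solved_ush")
    }
    enrichment = variant_enrichment(
        spectra["solved_rp"], spectra["solved_ush"], config.freq_threshold
    )
    summary = summary_metrics(
        qc_cohort, classifications, resolved, carriers, config.top_k
    )
    summary["qc_removed_variants"] = len(qc_log.removed_variants)
    summary["qc_removed_calls"] = len(qc_log.removed_calls)
    for phenotype in ("RP", "USH"):
        counts = allele_type_breakdown(resolved, qc_cohort, phenotype)
        summary[f"allele_counts_{phenotype.lower()}"] = counts
        summary[f"truncating_allele_fraction_{phenotype.lower()}"] = (
            truncating_fraction(counts)
        )
    try:
        contingency = combination_contingency(resolved)
        summary["combination_test"] = {
            "table": [list(r) for r in contingency.table],
            "test": contingency.test,
            "statistic": contingency.statistic,
            "p_value": contingency.p_value,
            "tier": contingency.tier,
        }
    except ValueError as exc:
        summary["combination_test"] = {"error": str(exc)}

    result = PipelineResult(
        cohort=qc_cohort,
        qc_log=qc_log,
        classifications=classifications,
        resolved=resolved,
        carriers=carriers,
        spectra=spectra,
        enrichment=enrichment,
        summary=summary,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        arts = result.artifacts
        arts["classifications"] = cohort_io.write_classifications(
            classifications, outdir / "classifications.tsv"
        )
        arts["solved_cases"] = cohort_io.write_solved_cases(
            resolved, outdir / "solved_cases.tsv"
        )
        for scope, rows in spectra.items():
            arts[f"spectrum_{scope}"] = cohort_io.write_spectrum_table(
                rows, qc_cohort.variants, outdir / f"spectrum_{scope}.tsv"
            )
        arts["enrichment"] = cohort_io.write_enrichment(
            enrichment, outdir / "enrichment.tsv"
        )
        arts["summary"] = cohort_io.write_summary(summary, outdir / "summary.json")
        with open(outdir / "qc_log.tsv", "w") as fh:
            fh.write("kind\tid\trule\tdetail\n")
            for key, rule, detail in qc_log.removed_variants:
                fh.write(f"variant\t{key}\t{rule}\t{detail}\n")
            for pid, key, detail in qc_log.removed_calls:
                fh.write(f"call\t{pid}@{key}\tdepth\t{detail}\n")
        arts["qc_log"] = outdir / "qc_log.tsv"
        arts["report"] = outdir / "report.md"
        arts["report"].write_text(render_report(result))
    return result


def _fmt_pct(x: float) -> str:
    return f"{100 * x:.2f}%"


def render_report(result: PipelineResult) -> str:
    """Markdown report of the headline tables and metrics."""
    s = result.summary
    lines = [
        "# USH2A cohort variant-spectrum report",
        "",
        "## Cohort",
        "",
        f"- participants: {s['n_participants']} "
        f"({s['n_ird']} IRD patients: {s['n_rp']} RP + {s['n_ush']} USH; "
        f"{s['n_participants'] - s['n_ird']} controls)",
        f"- proband-parent trios: {s['n_trios']}",
        f"- distinct QC-passing variants: {s['n_distinct_variants']} "
        f"({s['n_distinct_plp']} P/LP in {s['total_plp_ac']} alleles)",
        "",
        "## Diagnostic yield",
        "",
        f"- genetically solved patients: {s['solved_total']} "
        f"({_fmt_pct(s['solved_fraction_overall'])} of IRD patients; "
        f"RP {_fmt_pct(s['solved_fraction_rp'])}, "
        f"USH {_fmt_pct(s['solved_fraction_ush'])})",
        f"- configuration: {s['n_homozygous']} homozygous / "
        f"{s['n_compound_het']} compound heterozygous",
        f"- de-novo events detected in trios: {s['n_de_novo']}",
        "",
        "## Recurrent alleles (full cohort)",
        "",
        "| variant | HGVS | n_het | n_hom | AC | ALT freq | label |",
        "|---|---|---|---|---|---|---|",
    ]
    spectrum = result.spectra.get("all_participants", [])
    for row in spectrum[: s.get("top_k", 11)]:
        v = result.cohort.variants.get(row.variant_key)
        lines.append(
            f"| {row.variant_key} | {v.hgvs_c if v else '.'} | {row.n_het} "
            f"| {row.n_hom} | {row.ac} | {row.alt_freq:.4f} | {row.label} |"
        )
    lines += [
        "",
        f"- top-{s.get('top_k', 11)} allele share: "
        f"{_fmt_pct(s['top_k_allele_share'])}",
        f"- truncating share of distinct P/LP variants: "
        f"{_fmt_pct(s['truncating_share_distinct'])}",
        "",
        "## RP vs USH",
        "",
        f"- truncating causal-allele fraction: RP "
        f"{_fmt_pct(s.get('truncating_allele_fraction_rp', 0.0))}, USH "
        f"{_fmt_pct(s.get('truncating_allele_fraction_ush', 0.0))}",
    ]
    test = s.get("combination_test", {})
    if "p_value" in test:
        stat = (
            f"chi2={test['statistic']:.3f}, " if test["statistic"] is not None else ""
        )
        lines.append(
            f"- genotype-combination contrast ({test['test']}): {stat}"
            f"p={test['p_value']:.3g} {test['tier']}"
        )
    lines.append("")
    return "\n".join(lines)
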
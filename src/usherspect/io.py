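"""Reading and writing the pipeline's standard-format inputs and outputs.

Inputs are a multi-sample VCF 4.2 (FORMAT ``GT:DP``), a six-column PED
file, a phenotype TSV (``participant_id  cohort  phenotype  age_years``)
and a per-variant frequency TSV keyed by ``(chrom, pos, ref, alt)`` whose
columns are reference-database allele frequencies plus the four in-silico
predictor verdicts.  An empty frequency cell (``.``) means the allele was
*not observed* in that database, which is distinct from an observed
frequency of zero; both round-trip.

Variant-level annotations that belong to the call set rather than to
population databases (HGVS names, consequence and region class, reported
status) travel in the VCF INFO column.  Multi-allelic records are
decomposed into one :class:`~usherspect.model.VariantRecord` per alternate
allele.  Genotypes ``0/1`` map to het, ``1/1`` to hom, and ``0/0``/``./.``
produce no genotype call — except that reference-homozygous depths of
pedigree parents are retained at the sites their proband carries, because
de-novo detection must be able to rule out parental dropout.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .acmg import DEFAULT_STRENGTHS
from .model import (
    FREQ_KEYS,
    Cohort,
    CohortError,
    GenotypeCall,
    Participant,
    VariantRecord,
    variant_key,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_spectrum_table",
    "write_solved_cases",
    "write_classifications",
    "write_enrichment",
    "write_summary",
]

_PREDICTOR_COLUMNS = {
    "sift": "SIFT",
    "lrt": "LRT",
    "mutation_taster": "MutationTaster",
    "fathmm": "FATHMM",
}
_VERDICT_CODES = {"deleterious": "D", "tolerated": "T", "unavailable": "."}
_CODE_VERDICTS = {v: k for k, v in _VERDICT_CODES.items()}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=248956422>
##INFO=<ID=HGVSC,Number=A,Type=String,Description="Coding-DNA HGVS name">
##INFO=<ID=HGVSP,Number=A,Type=String,Description="Protein HGVS name">
##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence class">
##INFO=<ID=REGION,Number=A,Type=String,Description="Region class">
##INFO=<ID=REPORTED,Number=A,Type=String,Description="Literature/ClinVar status">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


# ---------------------------------------------------------------------------
# writing


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write VCF + PED + phenotype TSV + frequency TSV for a cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "cohort.ped",
        "phenotypes": outdir / "phenotypes.tsv",
        "freqs": outdir / "frequencies.tsv",
    }
    samples = list(cohort.participants)
    sample_index = {s: i for i, s in enumerate(samples)}
    variants = sorted(
        cohort.variants.values(), key=lambda v: (v.chrom, v.pos, v.ref, v.alt)
    )

    ref_depth_by_variant: dict[str, list[tuple[int, int]]] = {}
    for (pid, key), depth in cohort.ref_depths.items():
        if pid in sample_index:
            ref_depth_by_variant.setdefault(key, []).append((sample_index[pid], depth))

    with open(paths["vcf"], "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in variants:
            info = (
                f"HGVSC={v.hgvs_c or '.'};HGVSP={v.hgvs_p or '.'};"
                f"CSQ={v.consequence};REGION={v.region};REPORTED={v.reported_status}"
            )
            fields = ["0/0:100"] * len(samples)
            for idx, depth in ref_depth_by_variant.get(v.key, ()):
                fields[idx] = f"0/0:{depth}"
            for call in cohort.calls_of_variant(v.key):
                gt = "1/1" if call.zygosity == "hom" else "0/1"
                fields[sample_index[call.participant_id]] = f"{gt}:{call.depth}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT:DP\t"
                + "\t".join(fields)
                + "\n"
            )

    with open(paths["ped"], "w") as fh:
        mothers = {p.mother_id for p in cohort.participants.values() if p.mother_id}
        fathers = {p.father_id for p in cohort.participants.values() if p.father_id}
        for p in cohort.participants.values():
            sex = "1" if p.participant_id in fathers else (
                "2" if p.participant_id in mothers else "0"
            )
            phen = "2" if p.cohort == "ird" else "1"
            fh.write(
                f"{p.family_id or p.participant_id}\t{p.participant_id}\t"
                f"{p.father_id or '0'}\t{p.mother_id or '0'}\t{sex}\t{phen}\n"
            )

    with open(paths["phenotypes"], "w") as fh:
        fh.write("participant_id\tcohort\tphenotype\tage_years\n")
        for p in cohort.participants.values():
            age = "" if p.age_years is None else repr(float(p.age_years))
            fh.write(f"{p.participant_id}\t{p.cohort}\t{p.phenotype}\t{age}\n")

    with open(paths["freqs"], "w") as fh:
        cols = list(FREQ_KEYS) + list(_PREDICTOR_COLUMNS)
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(cols) + "\n")
        for v in variants:
            cells = []
            for key in FREQ_KEYS:
                cells.append(
                    repr(float(v.db_freqs[key])) if key in v.db_freqs else "."
                )
            for col, pred in _PREDICTOR_COLUMNS.items():
                cells.append(
                    _VERDICT_CODES[v.predictor_verdicts.get(pred, "unavailable")]
                )
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t" + "\t".join(cells) + "\n")
    return paths


# ---------------------------------------------------------------------------
# reading


def _read_ped(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family_id", "participant_id", "father_id", "mother_id", "sex", "phen"],
        dtype=str,
    )
    return ped.set_index("participant_id", drop=False)


def _read_frequency_table(path: str | Path) -> dict[str, dict]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise CohortError(
            f"frequency table must contain columns {sorted(required)}"
        )
    table: dict[str, dict] = {}
    freq_cols = [c for c in df.columns if c in FREQ_KEYS]
    for row in df.itertuples(index=False):
        rowd = row._asdict()
        key = variant_key(rowd["chrom"], int(rowd["pos"]), rowd["ref"], rowd["alt"])
        freqs = {}
        for col in freq_cols:
            cell = rowd[col]
            if isinstance(cell, str) and cell.strip() not in (".", "", "-"):
                freqs[col] = float(cell)
        preds = {}
        for col, pred in _PREDICTOR_COLUMNS.items():
            cell = rowd.get(col)
            if isinstance(cell, str):
                preds[pred] = _CODE_VERDICTS.get(cell.strip(), "unavailable")
            else:
                preds[pred] = "unavailable"
        table[key] = {"db_freqs": freqs, "predictor_verdicts": preds}
    return table


def read_cohort(
    vcf_path: str | Path,
    ped_path: str | Path,
    phenotype_path: str | Path,
    freq_path: str | Path,
) -> Cohort:
    """Assemble a :class:`Cohort` from its four input files.

    Raises :class:`CohortError` when a VCF sample is missing from the
    phenotype table or the PED file; a variant absent from the frequency
    table only triggers a warning (its databases are treated as unobserved).
    """
    ped = _read_ped(ped_path)
    phen = pd.read_csv(phenotype_path, sep="\t", dtype={"participant_id": str})
    phen = phen.set_index("participant_id", drop=False)
    freq_table = _read_frequency_table(freq_path)

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    for s in samples:
        if s not in phen.index:
            raise CohortError(f"VCF sample {s!r} missing from the phenotype table")
        if s not in ped.index:
            raise CohortError(f"VCF sample {s!r} missing from the PED file")

    enrolled = set(phen.index)
    participants = []
    for pid, row in phen.iterrows():
        father = mother = None
        family = pid
        if pid in ped.index:
            prow = ped.loc[pid]
            family = prow["family_id"]
            father = prow["father_id"] if prow["father_id"] != "0" else None
            mother = prow["mother_id"] if prow["mother_id"] != "0" else None
            if father is not None and father not in enrolled:
                father = None
            if mother is not None and mother not in enrolled:
                mother = None
        age = row.get("age_years")
        participants.append(
            Participant(
                participant_id=pid,
                cohort=row["cohort"],
                phenotype=row["phenotype"],
                family_id=str(family),
                father_id=father,
                mother_id=mother,
                age_years=None if pd.isna(age) else float(age),
            )
        )

    # parents of enrolled probands, for reference-depth retention
    parent_pairs = {
        p.participant_id: (p.father_id, p.mother_id)
        for p in participants
        if p.father_id and p.mother_id
    }
    sample_index = {s: i for i, s in enumerate(samples)}

    variants: list[VariantRecord] = []
    calls: list[GenotypeCall] = []
    ref_depths: dict[tuple[str, str], int] = {}
    for record in vcf:
        alts = record.ALT
        dp = record.format("DP")
        dp = (
            np.clip(dp.reshape(-1), 0, None).astype(int)
            if dp is not None
            else np.zeros(len(samples), dtype=int)
        )
        info = {k: record.INFO.get(k) for k in ("HGVSC", "HGVSP", "CSQ", "REGION", "REPORTED")}

        def per_alt(value, i, default=""):
            if value is None:
                return default
            parts = str(value).split(",")
            cell = parts[i] if i < len(parts) else parts[0]
            return "" if cell == "." else cell

        if len(alts) == 1:
            gt = record.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            alt_counts = {1: np.flatnonzero(gt == 1), 2: np.flatnonzero(gt == 2)}
            carrier_sets = [alt_counts]
        else:
            genos = record.genotypes
            carrier_sets = []
            for k in range(1, len(alts) + 1):
                hets, homs = [], []
                for i, g in enumerate(genos):
                    n = sum(1 for a in g[:-1] if a == k)
                    if n == 1:
                        hets.append(i)
                    elif n >= 2:
                        homs.append(i)
                carrier_sets.append({1: np.array(hets, int), 2: np.array(homs, int)})

        for i, alt in enumerate(alts):
            key = variant_key(record.CHROM, record.POS, record.REF, alt)
            ann = freq_table.get(key)
            if ann is None:
                warnings.warn(
                    f"variant {key} absent from the frequency table; "
                    "treating all databases as unobserved"
                )
                ann = {"db_freqs": {}, "predictor_verdicts": {}}
            variants.append(
                VariantRecord(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    hgvs_c=per_alt(info["HGVSC"], i),
                    hgvs_p=per_alt(info["HGVSP"], i),
                    consequence=per_alt(info["CSQ"], i, "missense"),
                    region=per_alt(info["REGION"], i, "coding"),
                    reported_status=per_alt(info["REPORTED"], i, "novel"),
                    db_freqs=ann["db_freqs"],
                    predictor_verdicts=ann["predictor_verdicts"],
                )
            )
            carriers = carrier_sets[i]
            carrier_idx = set(carriers[1].tolist()) | set(carriers[2].tolist())
            for zygosity, idx_array in (("het", carriers[1]), ("hom", carriers[2])):
                for idx in idx_array:
                    calls.append(
                        GenotypeCall(samples[idx], key, zygosity, int(dp[idx]))
                    )
            for proband, (father, mother) in parent_pairs.items():
                p_idx = sample_index.get(proband)
                if p_idx is None or p_idx not in carrier_idx:
                    continue
                for parent in (father, mother):
                    q_idx = sample_index.get(parent)
                    if q_idx is not None and q_idx not in carrier_idx:
                        ref_depths[(parent, key)] = int(dp[q_idx])
    return Cohort(participants, variants, calls, ref_depths)


# ---------------------------------------------------------------------------
# result tables


def write_spectrum_table(rows, variants: Mapping[str, VariantRecord], path) -> Path:
    """Spectrum TSV with a fixed column order; frequencies at 4 decimals."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("variant_key\thgvs_c\thgvs_p\tn_het\tn_hom\tac\talt_freq\tlabel\n")
        for r in rows:
            v = variants.get(r.variant_key)
            fh.write(
                f"{r.variant_key}\t{v.hgvs_c if v else '.'}\t"
                f"{(v.hgvs_p or '.') if v else '.'}\t{r.n_het}\t{r.n_hom}\t{r.ac}\t"
                f"{r.alt_freq:.4f}\t{r.label}\n"
            )
    return path


def write_solved_cases(cases, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "participant_id\tphenotype\tvariants\tconfiguration\tphase_status\t"
            "combination_class\tn_causal_alleles\tde_novo_variants\n"
        )
        for c in cases:
            alleles = ";".join(f"{v.variant_key}:{v.zygosity}" for v in c.variants)
            dn = ";".join(c.de_novo_variants) or "."
            fh.write(
                f"{c.participant_id}\t{c.phenotype}\t{alleles}\t{c.configuration}\t"
                f"{c.phase_status}\t{c.combination_class}\t{c.n_causal_alleles}\t{dn}\n"
            )
    return path


def write_classifications(classified: Mapping[str, "object"], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("variant_key\thgvs_c\tconsequence\tevidence\tacmg_class\t"
                 "reclassified\tnote\n")
        for key in sorted(classified):
            cv = classified[key]
            codes = ",".join(
                e.code
                if e.strength == DEFAULT_STRENGTHS[e.code]
                else f"{e.code}({e.strength})"
                for e in cv.evidence
            ) or "."
            fh.write(
                f"{key}\t{cv.variant.hgvs_c}\t{cv.variant.consequence}\t{codes}\t"
                f"{cv.acmg_class}\t{int(cv.reclassified)}\t{cv.note or '.'}\n"
            )
    return path


def write_enrichment(flags: Mapping[str, Mapping], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "variant_key\talt_freq_rp\talt_freq_ush\tenriched_rp\tenriched_ush\t"
            "ush_over_rp\n"
        )
        for key, f in flags.items():
            fh.write(
                f"{key}\t{f['alt_freq_rp']:.4f}\t{f['alt_freq_ush']:.4f}\t"
                f"{int(f['enriched_rp'])}\t{int(f['enriched_ush'])}\t"
                f"{int(f['ush_over_rp'])}\n"
            )
    return path


def write_summary(summary: Mapping, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return path
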
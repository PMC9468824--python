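# usherspect

Cohort-scale analysis of the *USH2A* variant spectrum in inherited retinal
disease (IRD).  Biallelic *USH2A* mutations are the most common cause of
autosomal-recessive retinitis pigmentosa (RP) and of Usher syndrome type II
(USH), and in East-Asian cohorts a handful of recurrent founder and hot-spot
alleles carry most of the diagnostic yield.  `usherspect` takes a
multi-sample VCF, a pedigree (PED), a phenotype table and a per-variant
population-frequency table, and produces:

* **QC-filtered variants** — three filters: any *global* reference-database
  minor allele frequency (1000 Genomes, ExAC, gnomAD, ESP6500, dbSNP) above
  0.01 excludes the variant; genotype calls under 30× depth are dropped;
  untranslated-region variants are excluded.
* **ACMG/AMP classifications** — evidence codes computable from cohort data
  (PVS1, PM2, PM3 with ClinGen-style strength upgrading, PS2, PP1, PP3, PP5,
  BA1, BP7) combined by the published rule table into P / LP / VUS / LB / B,
  with support for documented expert reclassification.
* **Genetically solved patients** — IRD patients carrying a homozygous or
  compound-heterozygous P/LP genotype, with phase provenance from trios,
  genotype-combination class (missense/missense, missense/truncating,
  truncating/truncating) and de-novo flags.
* **Allele-count spectra** — per-variant heterozygous/homozygous carrier
  counts with `AC = n_het + 2·n_hom` and `ALT freq = AC / 2N`, in
  whole-cohort and solved-patient scopes; recurrent alleles (AC ≥ 10) are
  labelled *founder* (confined to East-Asian databases) or *hot spot*
  (present at positive frequency in any non-East-Asian subpopulation).
* **RP-vs-USH statistics** — truncating-allele fractions, per-variant
  subgroup enrichment at an allele-frequency threshold, and a χ²
  (or exact Freeman–Halton, when expected cells are sparse) contrast of
  genotype-combination classes.

Because per-patient hospital genotypes cannot be redistributed, the package
includes a first-class **synthetic cohort generator** (`usherspect.simulate`)
that plants, by exact count, a cohort with the emulated study's structure:
1,278 RP + 56 USH patients, 7,376 controls, 373 proband-parent trios, eleven
recurrent alleles at their target allele counts, 218 solved patients
(23 homozygous / 195 compound-heterozygous), exactly one de-novo event, and
one deliberate violator of each QC rule.  Every pipeline stage is tested
end-to-end against this generator.

## Worked example

Generate the default reference cohort, run the pipeline, and render the
report:

```sh
usherspect simulate --seed 42 --out sim/
usherspect run --vcf sim/cohort.vcf --ped sim/cohort.ped \
    --phenotypes sim/phenotypes.tsv --freqs sim/frequencies.tsv --out results/
usherspect report --artifacts results/
```

The report printed for the seed-42 default cohort:

```
- participants: 8710 (1334 IRD patients: 1278 RP + 56 USH; 7376 controls)
- proband-parent trios: 373
- distinct QC-passing variants: 768 (136 P/LP in 665 alleles)

- genetically solved patients: 218 (16.34% of IRD patients; RP 14.87%, USH 50.00%)
- configuration: 23 homozygous / 195 compound heterozygous
- de-novo events detected in trios: 1

| variant             | HGVS         | n_het | n_hom | AC  | ALT freq | label    |
| chr1:216246592:A>C  | c.2802T>G    | 120   | 1     | 122 | 0.0070   | hot_spot |
| chr1:215877882:T>C  | c.8559-2A>G  | 83    | 8     | 99  | 0.0057   | founder  |
| ...                 |              |       |       |     |          |          |

- top-11 allele share: 57.74%
- truncating share of distinct P/LP variants: 73.53%
- truncating causal-allele fraction: RP 36.81%, USH 69.64%
- genotype-combination contrast (fisher_exact): p=1.01e-05 ***
```

Reading the output: 16.34% of IRD patients are genetically solved
(218/1,334 — 14.87% of RP, 50% of USH patients); the eleven recurrent
alleles (AC ≥ 10) account for 57.74% of all 665 disease-causing alleles;
c.2802T>G is the most frequent allele (AC 122, cohort frequency 0.0070) and
is labelled a hot spot because it also appears in non-East-Asian gnomAD/ExAC
subpopulations, whereas c.8559-2A>G (AC 99) is East-Asian-confined and
labelled a founder allele.  Truncating alleles dominate in USH (69.6%)
far more than in RP (36.8%), and the genotype-combination distribution
differs significantly between the two phenotypes.

The same analysis is available as a library:

```python
from usherspect import SimConfig, generate, run_pipeline

result = run_pipeline(generate(SimConfig(seed=42)))
print(result.summary["solved_fraction_overall"])   # 0.1634...
```

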
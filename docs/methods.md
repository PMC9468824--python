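# Methods

## Problem setting

*USH2A* is a large (73-exon) gene whose biallelic loss-of-function and
missense alleles cause autosomal-recessive retinitis pigmentosa (RP) and
Usher syndrome type II (USH: RP plus sensorineural hearing loss).  Given
genotypes for a mixed cohort — IRD patients, other inherited-eye-disease
patients, and healthy relatives — the analysis asks: which variants survive
quality control; which are disease-causing under ACMG/AMP rules; which
patients are genetically solved by a biallelic P/LP genotype; how the
allele-count spectrum is structured (and which recurrent alleles are founder
vs hot-spot mutations); and how RP and USH differ in allele composition.

## Quality control

Three filters, each config-exposed (`qc.*`):

* **MAF** (`maf_threshold`, default 0.01): a variant is removed when any
  *global* database frequency (`g1000_global`, `exac_global`,
  `gnomad_global`, `esp6500`, `dbsnp`) exceeds the ceiling.  Subpopulation
  keys never trigger removal: recurrent East-Asian founder alleles
  legitimately reach a few per-mille in EAS panels while remaining globally
  rare, and using subpopulation frequencies would delete exactly the alleles
  the analysis is about.  A missing key counts as zero (unobserved = rare).
* **Depth** (`min_depth`, default 30): calls under 30× are removed; a call
  at exactly 30× survives.  Filtering is per-call by default; a
  `per_variant` mode (drop the variant when any call fails) is provided
  since either reading of a cohort-level depth rule is defensible.
  A variant left with no surviving calls is dropped entirely.
* **Region** (`excluded_regions`, default `{utr}`): untranslated-region
  variants are excluded.

The filters commute and partition their input (property-tested).
Synonymous variants pass QC by design and are set aside at classification.

## ACMG/AMP classification

The **combiner** is a direct transcription of the published combining table
over evidence strengths (very strong / strong / moderate / supporting;
stand-alone / strong / supporting on the benign side).  Simultaneous
pathogenic- and benign-side evidence is contradictory and yields VUS.  The
test suite checks the combiner against an independently transcribed
brute-force copy of the table over every evidence multiset of size ≤ 6.

The **evidence rules** are restricted to what this kind of cohort actually
measures, each independently togglable (`acmg.enabled`):

| code | rule | default parameter |
|---|---|---|
| PVS1 | truncating consequence (nonsense, frameshift, intronic splice) | — |
| PM2 | every populated database frequency ≤ `pm2_max_af`; never raised for synonymous changes (rarity of a silent variant is not pathogenic evidence) | 1 × 10⁻⁴ |
| PP3 | ≥ `pp3_min_deleterious` of the four predictors (SIFT, LRT, MutationTaster, FATHMM) deleterious; unavailable verdicts never count | 3 of 4 |
| PS2 | trio-confirmed de novo | — |
| PM3 | observed in trans with a P/LP allele in ≥ 1 patient; upgraded to strong at ≥ `pm3_strong_min_patients` patients (ClinGen SVI practice) | 4 |
| PP1 | transmitted from an unaffected carrier parent to an affected proband in ≥ 1 trio | — |
| PP5 | reported pathogenic in ClinVar/HGMD/literature (an input field) | — |
| BA1 | any global frequency > `ba1_min_af` | 0.05 |
| BP7 | synonymous with no splice prediction available | — |

The PM3 strength upgrade matters: a recurrent missense allele whose
East-Asian panel frequency exceeds the PM2 ceiling can otherwise never
exceed VUS from computable evidence (PM3 + PP3 + PP5 = 1 moderate + 2
supporting), even when it is observed in trans with pathogenic partners in
ten unrelated patients.  With the upgrade such alleles reach LP through
1 strong + ≥ 2 supporting, which reproduces the expected composition of the
recurrent-allele set.  Homozygous observations are *not* counted toward
PM3 (consanguinity caveat).

Because PM3 depends on partner classifications, cohort classification
iterates to a fixed point: pass 1 classifies self-sufficient alleles
(e.g. PVS1 + PM2), later passes add PM3 where partners are now P/LP.  The
P/LP set grows monotonically, so convergence is guaranteed (≤ 10 passes;
two to three in practice).

Expert reclassification (`reclassify`) overrides the automated class,
requires a non-empty note, and preserves the prior class in provenance.

## Genotype resolution

An IRD patient is *solved* when carrying one homozygous P/LP allele or ≥ 2
distinct heterozygous P/LP alleles.  Control participants are never
resolved; they and single-allele patients are emitted as carriers.
Compound heterozygotes without parental data still count as solved —
mirroring how such patients are counted in practice — but carry
`phase_status=unknown` in every output, since the two alleles could lie in
cis.  Trio phase is proven when two causal alleles have distinct origins
(different parents, or one parental and one de novo).  Homozygotes need no
phasing (`inferred`).

De-novo detection requires the proband to carry the allele, neither parent
to have any genotype call for it, and **both parents to show reference
coverage ≥ the QC depth threshold at the site** — otherwise parental
dropout cannot be excluded and the event is unevaluable (false, with a
warning).  Since reference-homozygous genotypes produce no call record, the
cohort model retains parents' reference depths at the sites their proband
carries (`Cohort.ref_depths`), and the VCF reader collects exactly those.

Genotype-combination class: inframe changes count with missense
(non-truncating); homozygotes use their variant twice; patients with more
than two causal alleles are classed by their two truncating-first alleles
(a convention — the class of a three-allele patient is not otherwise
defined).

## Spectrum statistics

A spectrum row counts het/hom carriers of one P/LP variant within a scope;
`AC = n_het + 2·n_hom` is asserted on every emitted row, and the frequency
denominator is 2 × participants *in scope* (2 × 8,710 for the full cohort;
2 × 218 = 436 for solved patients, even though three solved patients carry a
third allele — patient-based denominators match how such tables are
printed).  Recurrent alleles (AC ≥ `ac_threshold`, default 10) are labelled
**hot spot** when any non-East-Asian subpopulation key (`gnomad_asj`,
`exac_amr`, `exac_nfe`, `gnomad_afr`, `exac_afr`, `exac_sas`, `gnomad_nfe`)
is present with a strictly positive value, else **founder**; an explicit
zero counts as absent.  Subgroup "enrichment" at `freq_threshold` (default
0.01) is a frequency rule, not a hypothesis test.

The RP × USH genotype-combination contrast uses Pearson's χ² without
continuity correction, replaced by a Freeman–Halton exact test (2 × C
margin enumeration with log-space hypergeometric probabilities) when any
expected cell is below five.  The χ² path is cross-checked against both a
from-scratch computation and scipy; the exact path reduces to scipy's
`fisher_exact` on 2 × 2 tables.  Significance tiers: `*` p < 0.05,
`**` p < 0.01, `***` p < 0.001.

## Synthetic cohort generator

The generator emulates the study conditions by **planting exact counts**,
not sampling: 1,278 RP + 56 USH + 7,376 controls; 350 RP and 23 USH
proband-parent trios (parents drawn from the control pool); eleven
recurrent-allele templates with real locus coordinates, HGVS names and
curated database frequencies, planted at their target cohort het/hom counts
with a fixed solved-patient share; 190 + 28 solved patients with 23
homozygous; 125 additional rare P/LP variants (consequence mix chosen so
the distinct P/LP set is 136 with 100 truncating) filling the remaining
compound-het slots so that total P/LP AC is exactly 665; 632 background
variants (VUS-profile and benign-leaning profiles) bringing the QC-passing
allele total to 5,636; one violator of each QC rule; exactly one de-novo
event inside an RP trio; three third-allele patients (one in a trio whose
mother carries the two missense alleles in cis); and per-phenotype
genotype-combination targets (RP 75/89/26, USH 1/15/12) that drive the
truncating/missense split of the planted pairs.

Design points worth knowing:

* **Feasibility is checked, not assumed** — any arithmetic inconsistency in
  a custom configuration (target AC beyond 2N, solved counts beyond group
  sizes, allele budgets that cannot cover every distinct variant, an
  infeasible combination-target split) raises `SimulationError`.
* **Pairing** deals alleles so that every missense extra is partnered with
  a truncating P/LP allele in at least one patient; this guarantees the
  PM3 fixed-point iteration can bootstrap every planted causal allele to
  LP, which in turn makes the planted solved count exactly recoverable.
* **Trio hygiene**: every allele of a trio proband has a planted parental
  origin except the single de-novo event, and background variants never
  touch trio members, so de-novo detection finds exactly one event.
* Background variants are also kept off patients who carry causal alleles,
  so they cannot inflate the in-trans (PM3) evidence; they classify as VUS.
* **Determinism**: the seed controls carrier placement, depths and ages,
  never the planted counts; two runs with one seed are byte-identical on
  disk.  A `stochastic` mode samples carrier padding per individual at the
  target frequency, for statistical recovery tests.
* **Ages** are drawn per genotype-combination group (means 43.73 / 40.75 /
  36.04 years, SDs 17.00 / 16.18 / 12.30, truncated to [2, 78]) to emulate
  the earlier onset of truncating genotypes; other participants draw from
  N(45, 18), parents offset +27 years.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no sequence-level simulation (reads, alignment,
caller artifacts); no linkage between neighbouring variants or real
haplotype structure; background allele frequencies follow a convention (a
Pareto-weighted multinomial), not an empirical site-frequency spectrum;
genotype calls are error-free apart from the planted low-depth violator;
and the generator's carriers each hold a single causal allele, so the
carrier *count* is a consequence of the allele-count targets rather than an
independently calibrated quantity.

## Numerical and degenerate-input choices

* Frequencies are compared with strict `>` at thresholds (a variant at
  exactly the MAF ceiling survives; a call at exactly 30× survives).
* The exact-test enumeration compares log-probabilities with a 10⁻⁹ slack
  to keep ties stable across platforms.
* Empty cohorts, empty scopes, empty evidence sets and zero-case breakdowns
  all return empty/zero results rather than erroring; a missing phenotype
  group in the contingency contrast errors naming the group.
* Spectrum ordering: descending AC, ties by genomic position.
* JSON summaries are written with sorted keys so identical runs are
  byte-identical.

## Problem sizes

The default cohort (8,710 participants × 771 variants) generates in ~0.2 s
in memory; writing and re-reading the ~54 MB VCF takes ~2 s; the full test
suite runs in a few seconds and the acceptance script end-to-end (generate →
write → read → pipeline) in under ten.  Structural property tests use a
222-participant configuration with the same special-case inventory.

## Known limitations

* The evidence rule set omits codes that need data this cohort model does
  not carry (PS1/PM5 against known amino-acid changes, PM1 domain
  annotations, PS3 functional assays, BS/BP codes beyond BP7); benign
  classifications are therefore rare by construction.
* PP1 uses single-trio transmission as minimal segregation evidence; true
  multi-generation LOD-based co-segregation is out of scope.
* Phase is pedigree-only; no statistical phasing from population
  haplotypes.
* The founder/hot-spot rule is a frequency-footprint heuristic; it does not
  date alleles or test haplotype sharing.
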
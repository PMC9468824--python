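"""Shared fixtures: the reference synthetic cohort, pipeline runs on it,
and a reduced-scale generator configuration for structural property tests."""

import pytest

from usherspect.model import Cohort, GenotypeCall, Participant, VariantRecord
from usherspect.pipeline import run_pipeline
from usherspect.simulate import (
    DEFAULT_FOUNDERS,
    FounderSpec,
    SimConfig,
    fixture_reference,
    generate,
)
from usherspect import io as cohort_io


@pytest.fixture(scope="session")
def fixture_cohort() -> Cohort:
    """Default-parameter, seed-42 reference cohort (in memory)."""
    return fixture_reference()


@pytest.fixture(scope="session")
def pipeline_result(fixture_cohort):
    """Full pipeline run on the in-memory reference cohort."""
    return run_pipeline(fixture_cohort)


@pytest.fixture(scope="session")
def file_pipeline_result(fixture_cohort, tmp_path_factory):
    """Pipeline run from written VCF/PED/phenotype/frequency files."""
    indir = tmp_path_factory.mktemp("fixture_inputs")
    outdir = tmp_path_factory.mktemp("fixture_outputs")
    paths = cohort_io.write_cohort(fixture_cohort, indir)
    result = run_pipeline(
        vcf=paths["vcf"],
        ped=paths["ped"],
        phenotypes=paths["phenotypes"],
        freqs=paths["freqs"],
        outdir=outdir,
    )
    return result


def small_sim_config(seed: int = 7, **overrides) -> SimConfig:
    """A reduced-scale but structurally complete generator configuration.

    Two recurrent-allele templates, ten extra causal variants, one de-novo
    event and one third-allele patient; all counts chosen to be exactly
    feasible so parameter recovery can be asserted equality-exact.
    """
    founders = (
        FounderSpec(
            DEFAULT_FOUNDERS[0].variant, 10, 1, {"RP": (4, 1), "USH": (1, 0)}
        ),
        FounderSpec(
            DEFAULT_FOUNDERS[1].variant, 8, 1, {"RP": (3, 1), "USH": (1, 0)}
        ),
    )
    defaults = dict(
        seed=seed,
        n_rp=60,
        n_ush=12,
        n_control=150,
        n_trios_rp=8,
        n_trios_ush=2,
        founder_alleles=founders,
        n_solved_rp=10,
        n_solved_ush=3,
        homozygous_fraction=2 / 13,
        extra_pathogenic_mix={"missense": 4, "nonsense": 3, "frameshift": 3},
        total_plp_alleles=38,
        n_novel_plp=3,
        combination_targets=None,
        background_vus_mix={"missense": 6, "synonymous": 4},
        background_benign_mix={"missense": 2},
        total_alleles=68,
        de_novo_count=1,
        planted_third_allele_patients=1,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate(small_sim_config())


# -- hand-built micro-cohort helpers ---------------------------------------


def make_variant(pos=100, ref="A", alt="G", consequence="missense",
                 region="coding", **kw) -> VariantRecord:
    kw.setdefault("hgvs_c", f"c.{pos}{ref}>{alt}")
    return VariantRecord(
        chrom="chr1", pos=pos, ref=ref, alt=alt, consequence=consequence,
        region=region, **kw,
    )


def make_patient(pid="P1", phenotype="RP", **kw) -> Participant:
    cohort = "ird" if phenotype in ("RP", "USH") else "control"
    kw.setdefault("family_id", f"F_{pid}")
    return Participant(participant_id=pid, cohort=cohort, phenotype=phenotype, **kw)


def make_call(pid, variant, zygosity="het", depth=60) -> GenotypeCall:
    key = variant.key if isinstance(variant, VariantRecord) else variant
    return GenotypeCall(pid, key, zygosity, depth)
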
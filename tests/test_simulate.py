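"""Synthetic cohort generator: planted structure, determinism, recovery."""

import numpy as np
import pytest

from usherspect.model import Cohort
from usherspect.pipeline import run_pipeline
from usherspect.simulate import (
    DEFAULT_FOUNDERS,
    FounderSpec,
    SimConfig,
    SimulationError,
    fixture_reference,
    generate,
)

from conftest import small_sim_config


def test_reference_fixture_composition(fixture_cohort):
    c = fixture_cohort
    assert c.n_participants == 8710
    phenos = {}
    for p in c.participants.values():
        phenos[p.phenotype] = phenos.get(p.phenotype, 0) + 1
    assert phenos["RP"] == 1278 and phenos["USH"] == 56
    assert sum(1 for p in c.participants.values() if p.cohort == "control") == 7376
    trios = c.trios()
    assert len(trios) == 373
    rp_trios = sum(1 for t in trios if t.proband_id.startswith("RP"))
    assert rp_trios == 350 and len(trios) - rp_trios == 23
    assert len(c.variants) == 771  # 768 QC-passing + 3 planted violators


def test_planted_founder_allele_counts(fixture_cohort):
    """Every recurrent-allele template reaches its target het-hom counts."""
    for spec in DEFAULT_FOUNDERS:
        calls = fixture_cohort.calls_of_variant(spec.variant.key)
        n_het = sum(1 for c in calls if c.zygosity == "het")
        n_hom = len(calls) - n_het
        assert (n_het, n_hom) == (spec.cohort_het, spec.cohort_hom), spec.variant.hgvs_c
    top = DEFAULT_FOUNDERS[0]
    assert fixture_cohort.allele_count(top.variant.key) == 122


def test_planted_frequency_is_exact_by_count(fixture_cohort):
    """Planting is by count: empirical ALT freq == target AC / (2N) exactly."""
    for spec in DEFAULT_FOUNDERS:
        ac = fixture_cohort.allele_count(spec.variant.key)
        assert ac / fixture_cohort.n_chromosomes == spec.target_ac / (2 * 8710)


def test_exactly_one_de_novo_event(fixture_cohort):
    from usherspect.resolution import detect_de_novo

    events = []
    for trio in fixture_cohort.trios():
        for call in fixture_cohort.calls_of_participant(trio.proband_id):
            if detect_de_novo(fixture_cohort, trio, call.variant_key):
                events.append((trio.proband_id, call.variant_key))
    assert len(events) == 1
    assert events[0][1] == DEFAULT_FOUNDERS[0].variant.key


def test_each_qc_violator_is_planted_and_filtered(fixture_cohort):
    from usherspect.qc import apply_qc

    qc_cohort, _ = apply_qc(fixture_cohort)
    by_region = [v for v in fixture_cohort.variants.values() if v.region == "utr"]
    by_freq = [
        v for v in fixture_cohort.variants.values()
        if v.db_freqs.get("gnomad_global", 0) > 0.01
    ]
    low_depth_keys = {
        c.variant_key for c in fixture_cohort.calls if c.depth < 30
    }
    assert by_region and by_freq and low_depth_keys
    for v in by_region + by_freq:
        assert v.key not in qc_cohort.variants
    for key in low_depth_keys:
        assert key not in qc_cohort.variants


def test_determinism_same_seed_same_cohort():
    a = generate(small_sim_config(seed=11))
    b = generate(small_sim_config(seed=11))
    assert a == b and a.ref_depths == b.ref_depths
    c = generate(small_sim_config(seed=12))
    assert a != c  # carrier placement is seed-dependent


def test_fixture_reference_equals_default_seed42():
    assert fixture_reference() == fixture_reference()
    assert fixture_reference().n_participants == SimConfig().n_participants


def test_zero_config_yields_empty_cohort():
    empty = generate(SimConfig(
        seed=1, n_rp=0, n_ush=0, n_control=0, n_trios_rp=0, n_trios_ush=0,
        founder_alleles=(), n_solved_rp=0, n_solved_ush=0,
        extra_pathogenic_mix={}, total_plp_alleles=0, combination_targets=None,
        background_vus_mix={}, background_benign_mix={}, total_alleles=0,
        de_novo_count=0, planted_third_allele_patients=0, qc_violators=False,
    ))
    assert isinstance(empty, Cohort)
    assert empty.n_participants == 0 and not empty.variants and not empty.calls


@pytest.mark.parametrize(
    "overrides, message",
    [
        (dict(n_solved_rp=100), "solved"),
        (dict(n_trios_rp=70), "trio"),
        (dict(n_control=10), "parents"),
        (dict(homozygous_fraction=1.5), "homozygous_fraction"),
        (dict(total_plp_alleles=20), "total_plp_alleles"),
    ],
)
def test_infeasible_configs_raise(overrides, message):
    with pytest.raises(SimulationError, match=message):
        generate(small_sim_config(**overrides))


def test_target_ac_beyond_cohort_capacity_raises():
    tiny = FounderSpec(DEFAULT_FOUNDERS[0].variant, 100, 0, {"RP": (1, 0)})
    with pytest.raises(SimulationError, match="exceeds"):
        generate(small_sim_config(n_rp=4, n_ush=2, n_control=8, n_trios_rp=1,
                                  n_trios_ush=0, founder_alleles=(tiny,),
                                  n_solved_rp=1, n_solved_ush=0,
                                  homozygous_fraction=0.0,
                                  planted_third_allele_patients=0))


def test_parameter_recovery_small_scale(small_cohort):
    """The full pipeline recovers the planted solved counts, founder ACs and
    the single de-novo event from a reduced-scale cohort, exactly."""
    config = small_sim_config()
    result = run_pipeline(small_cohort)
    s = result.summary
    assert s["solved_rp"] == config.n_solved_rp
    assert s["solved_ush"] == config.n_solved_ush
    assert s["n_de_novo"] == config.de_novo_count
    assert s["n_homozygous"] == round(
        config.homozygous_fraction * config.n_solved
    )
    for spec in config.founder_alleles:
        assert result.cohort.allele_count(spec.variant.key) == spec.target_ac
    assert s["total_plp_ac"] == config.total_plp_alleles


def test_stochastic_mode_frequency_recovery_over_seeds():
    """In stochastic mode carrier padding is sampled per individual; the
    pooled allele count over 50 seeds lies within the binomial 95% CI."""
    base = small_sim_config(stochastic=True)
    spec = base.founder_alleles[0]
    fixed = generate(small_sim_config(seed=1)).allele_count(spec.variant.key)
    assert fixed == spec.target_ac  # deterministic mode plants exactly
    total = 0
    n_seeds = 50
    for seed in range(1, n_seeds + 1):
        cohort = generate(small_sim_config(seed=seed, stochastic=True))
        total += cohort.allele_count(spec.variant.key)
    expectation = n_seeds * spec.target_ac
    # padded part is Binomial(n_hosts, pad/n_hosts) per seed; bound its sd
    pad = 3  # target het minus solved/parental planted copies
    sd = np.sqrt(n_seeds * pad)  # variance <= n p (1-p) * seeds <= pad * seeds
    assert abs(total - expectation) <= 1.96 * sd


def test_solved_patients_receive_group_specific_ages(fixture_cohort):
    ages = [
        p.age_years for p in fixture_cohort.participants.values()
        if p.age_years is not None
    ]
    assert len(ages) == fixture_cohort.n_participants
    assert min(ages) >= 2.0 and max(ages) <= 78.0
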
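"""Synthetic-study generator: determinism, truth parameters, recovery."""

import math

import numpy as np
import pytest

from snpmeta.association_stats import hwe_test, odds_ratio
from snpmeta.genetic_models import GeneticModel, build_contrast
from snpmeta.io_studies import read_study_table, write_study_table
from snpmeta.meta_pool import pool_mantel_haenszel
from snpmeta.synthetic import (
    ScenarioError,
    SyntheticScenario,
    case_probs,
    generate_scenario_table,
    generate_study,
    hwe_probs,
    true_contrast_or,
)


def test_null_scenario_case_equals_control_probs():
    assert case_probs(0.3, 1.0) == pytest.approx(hwe_probs(0.3, 0.0))


def test_hwe_probs_at_half():
    assert hwe_probs(0.5, 0.0) == pytest.approx((0.25, 0.5, 0.25))


def test_distortion_moves_mass_from_heterozygotes():
    aa, ag, gg = hwe_probs(0.3, 0.3)
    aa0, ag0, gg0 = hwe_probs(0.3, 0.0)
    assert ag < ag0 and aa > aa0 and gg > gg0
    assert aa + ag + gg == pytest.approx(1.0)


def test_invalid_scenarios_rejected():
    with pytest.raises(ScenarioError):
        SyntheticScenario(k=3, p_control=1.5)
    with pytest.raises(ScenarioError):
        SyntheticScenario(k=3, or_allele=-1)
    with pytest.raises(ScenarioError):
        SyntheticScenario(k=3, hwe_f=-2.0)  # probabilities leave [0, 1]


def test_determinism_under_fixed_seed():
    sc = SyntheticScenario(k=4, seed=42, or_allele=1.3, tau=0.1)
    assert generate_scenario_table(sc) == generate_scenario_table(sc)


def test_per_study_streams_independent_of_k():
    a = generate_study(SyntheticScenario(k=5, seed=7), 2)
    b = generate_study(SyntheticScenario(k=3, seed=7), 2)
    assert a.case_counts == b.case_counts
    assert a.control_counts == b.control_counts


def test_counts_sum_to_arm_sizes():
    sc = SyntheticScenario(k=3, n_case=123, n_control=456, seed=1)
    for r in generate_scenario_table(sc):
        assert sum(r.case_counts) == 123
        assert sum(r.control_counts) == 456


def test_empty_scenario():
    assert generate_scenario_table(SyntheticScenario(k=0)) == []


def test_table_mimicking_fixture_shape_round_trips(tmp_path):
    sc = SyntheticScenario(
        k=9, seed=3, or_allele=1.2,
        subgroups=("Asian",) * 5 + ("non-Asian",) * 4,
        effect_only=frozenset({2}),
    )
    records = generate_scenario_table(sc)
    assert records[2].has_effect and not records[2].has_counts
    out = tmp_path / "sim.tsv"
    write_study_table(records, out)
    assert read_study_table(out) == records


def test_control_allele_frequency_converges():
    sc = SyntheticScenario(k=1, n_case=100, n_control=100_000,
                           p_control=0.3, seed=11)
    [r] = generate_scenario_table(sc)
    aa, ag, gg = r.control_counts
    freq = (2 * aa + ag) / (2 * sum(r.control_counts))
    assert freq == pytest.approx(0.3, abs=0.01)


def test_true_contrast_ors_derive_from_genotype_probs():
    sc = SyntheticScenario(k=1, p_control=0.3, or_allele=1.5)
    assert true_contrast_or(sc, GeneticModel.ALLELE) == pytest.approx(1.5)
    # under the allelic model the AA-vs-GG contrast has OR = or_allele^2
    assert true_contrast_or(sc, GeneticModel.ADDITIVE) == \
        pytest.approx(1.5**2)
    rec = true_contrast_or(sc, GeneticModel.RECESSIVE)
    dom = true_contrast_or(sc, GeneticModel.DOMINANT)
    assert 1 < rec < 1.5**2 and 1 < dom < 1.5**2


def test_hwe_distortion_detected_with_high_power():
    rejections = 0
    for rep in range(100):
        sc = SyntheticScenario(k=1, n_control=1000, p_control=0.3,
                               hwe_f=0.3, seed=1000 + rep)
        [r] = generate_scenario_table(sc)
        if hwe_test(r.control_counts).p < 0.05 :
            rejections += 1
    assert rejections >= 95


def test_mh_recovers_true_allele_or():
    # fixed-seed Monte Carlo: pooled allele OR near the generative truth
    pooled_ors = []
    for rep in range(30):
        sc = SyntheticScenario(k=10, n_case=1000, n_control=1000,
                               p_control=0.3, or_allele=1.5, seed=500 + rep)
        tables = [build_contrast(r, GeneticModel.ALLELE)
                  for r in generate_scenario_table(sc)]
        pooled_ors.append(pool_mantel_haenszel(tables).or_point)
    assert np.mean(pooled_ors) == pytest.approx(1.5, rel=0.02)


def test_null_pipeline_ci_covers_one():
    covered = 0
    for rep in range(100):
        sc = SyntheticScenario(k=8, n_case=500, n_control=500,
                               p_control=0.3, or_allele=1.0, seed=9000 + rep)
        tables = [build_contrast(r, GeneticModel.ALLELE)
                  for r in generate_scenario_table(sc)]
        pooled = pool_mantel_haenszel(tables)
        covered += pooled.ci_low <= 1.0 <= pooled.ci_high
    assert covered >= 89  # ~95% nominal, binomial noise at 100 replicates
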
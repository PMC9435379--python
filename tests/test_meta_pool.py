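"""Heterogeneity, MH/DL pooling, method selection and subgroup runs."""

import math
import random

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.meta_analysis import combine_effects

from snpmeta.association_stats import EffectEstimate, odds_ratio
from snpmeta.genetic_models import ContrastTable, GeneticModel, build_contrast
from snpmeta.meta_pool import (
    EmptySubgroupError,
    HeterogeneityResult,
    HeterogeneityRule,
    InsufficientStudiesError,
    PoolingMethod,
    cochran_q,
    pool_dersimonian_laird,
    pool_mantel_haenszel,
    run_meta,
    select_method,
)

from .oracles import oracle_dl, oracle_mh, oracle_q


def effect(log_or, se, study="s", snp="rs1"):
    return EffectEstimate(
        study_id=study, snp_id=snp, model=GeneticModel.ALLELE,
        log_or=log_or, se=se, or_point=math.exp(log_or),
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se))


def table(a, b, c, d, study="s", model=GeneticModel.ADDITIVE):
    return ContrastTable(model=model, a=a, b=b, c=c, d=d,
                         study_id=study, snp_id="rs1")


class TestCochranQ:
    def test_identical_effects_give_zero_q(self):
        het = cochran_q([effect(0.3, 0.1, "a"), effect(0.3, 0.1, "b")])
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0

    def test_i2_formula_q10_k6(self):
        # I2 = (Q - df)/Q * 100 = (10 - 5)/10 * 100 = 50
        het = HeterogeneityResult(q=10, k=6, df=5, p=0.07, i2=50.0)
        assert het.i2 == (het.q - het.df) / het.q * 100

    def test_i2_clamped_when_q_below_df(self):
        effects = [effect(0.30 + 0.001 * i, 0.5, f"s{i}") for i in range(6)]
        het = cochran_q(effects)
        assert het.q < het.df
        assert het.i2 == 0.0

    def test_fewer_than_two_studies_rejected(self):
        with pytest.raises(InsufficientStudiesError):
            cochran_q([effect(0.1, 0.2)])

    def test_agrees_with_direct_sum_oracle(self):
        rng = random.Random(11)
        thetas = [rng.gauss(0.2, 0.4) for _ in range(8)]
        ses = [rng.uniform(0.05, 0.5) for _ in range(8)]
        effects = [effect(t, s, f"s{i}")
                   for i, (t, s) in enumerate(zip(thetas, ses))]
        assert cochran_q(effects).q == pytest.approx(
            oracle_q(thetas, ses), abs=1e-10)


class TestSelectMethod:
    @pytest.mark.parametrize("p, i2, expected", [
        (0.8, 0.0, PoolingMethod.MH_FIXED),
        (0.01, 20.0, PoolingMethod.DL_RANDOM),
        (0.5, 75.0, PoolingMethod.DL_RANDOM),
    ])
    def test_default_rule(self, p, i2, expected):
        het = HeterogeneityResult(q=1, k=3, df=2, p=p, i2=i2)
        assert select_method(het) is expected

    def test_conjunctive_variant_requires_both(self):
        rule = HeterogeneityRule(p_threshold=0.1, i2_threshold=50,
                                 combine="all")
        only_p = HeterogeneityResult(q=1, k=3, df=2, p=0.01, i2=20.0)
        both = HeterogeneityResult(q=1, k=3, df=2, p=0.01, i2=80.0)
        assert select_method(only_p, rule) is PoolingMethod.MH_FIXED
        assert select_method(both, rule) is PoolingMethod.DL_RANDOM

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            HeterogeneityRule(p_threshold=1.5)


class TestMantelHaenszel:
    def test_single_study_equals_crude_or(self):
        t = table(30, 20, 25, 25)
        pooled = pool_mantel_haenszel([t])
        assert pooled.or_point == pytest.approx((30 * 25) / (20 * 25))

    def test_identical_tables_preserve_common_or(self):
        t = table(30, 20, 25, 25)
        pooled = pool_mantel_haenszel([t, table(30, 20, 25, 25, "s2")])
        assert pooled.or_point == pytest.approx((30 * 25) / (20 * 25))

    def test_two_study_additive_example(self):
        # direct MH sums over the Gretarsdottir and B7 additive tables
        tables = [table(514, 22206, 71, 4962, "g"),
                  table(128, 17, 140, 25, "b7")]
        pooled = pool_mantel_haenszel(tables)
        expected = ((514 * 4962 / 27753 + 128 * 25 / 310)
                    / (22206 * 71 / 27753 + 17 * 140 / 310))
        assert pooled.or_point == pytest.approx(expected, abs=1e-12)
        assert pooled.or_point == pytest.approx(1.59, abs=0.01)

    def test_agrees_with_statsmodels_stratified_table(self):
        cells = [(514, 22206, 71, 4962), (128, 17, 140, 25), (49, 767, 60, 756)]
        pooled = pool_mantel_haenszel(
            [table(*t, study=f"s{i}") for i, t in enumerate(cells)])
        st_tables = [np.array([[a, b], [c, d]], float)
                     for a, b, c, d in cells]
        ref = StratifiedTable(st_tables)
        assert pooled.or_point == pytest.approx(ref.oddsratio_pooled,
                                                rel=1e-12)
        se = math.log(pooled.ci_high / pooled.or_point) / 1.96
        assert se == pytest.approx(ref.logodds_pooled_se, rel=1e-12)

    def test_weights_sum_to_one(self):
        pooled = pool_mantel_haenszel(
            [table(30, 20, 25, 25, "a"), table(10, 5, 8, 9, "b")])
        assert sum(pooled.weights.values()) == pytest.approx(1.0)

    def test_agrees_with_spreadsheet_oracle(self):
        rng = random.Random(3)
        cells = [tuple(rng.randint(1, 80) for _ in range(4)) for _ in range(6)]
        pooled = pool_mantel_haenszel(
            [table(*t, study=f"s{i}") for i, t in enumerate(cells)])
        log_or, se = oracle_mh(cells)
        assert math.log(pooled.or_point) == pytest.approx(log_or, abs=1e-10)
        assert math.log(pooled.ci_high / pooled.or_point) / 1.96 == \
            pytest.approx(se, abs=1e-10)


class TestDerSimonianLaird:
    def test_identical_effects_reduce_to_fixed_effect(self):
        effects = [effect(0.3, 0.1, f"s{i}") for i in range(4)]
        pooled = pool_dersimonian_laird(effects)
        assert pooled.tau2 == 0.0
        assert math.log(pooled.or_point) == pytest.approx(0.3, abs=1e-12)
        # equals inverse-variance pooling exactly when tau2 = 0
        w = [1 / 0.1**2] * 4
        assert math.log(pooled.or_point) == pytest.approx(
            sum(wi * 0.3 for wi in w) / sum(w), abs=1e-12)

    def test_large_tau2_equalises_weights(self):
        effects = [effect(th, se, f"s{i}") for i, (th, se) in
                   enumerate([(-3.0, 0.05), (0.0, 0.2), (3.0, 0.4)])]
        pooled = pool_dersimonian_laird(effects)
        assert pooled.tau2 > 1
        w = list(pooled.weights.values())
        assert max(w) / min(w) < 1.6  # far closer than the 64x IV ratio

    def test_agrees_with_direct_formula_oracle(self):
        rng = random.Random(5)
        thetas = [rng.gauss(0.3, 0.3) for _ in range(10)]
        ses = [rng.uniform(0.1, 0.4) for _ in range(10)]
        effects = [effect(t, s, f"s{i}")
                   for i, (t, s) in enumerate(zip(thetas, ses))]
        pooled = pool_dersimonian_laird(effects)
        tau2, mu, se = oracle_dl(thetas, ses)
        assert pooled.tau2 == pytest.approx(tau2, abs=1e-10)
        assert math.log(pooled.or_point) == pytest.approx(mu, abs=1e-10)

    def test_agrees_with_statsmodels_combine_effects(self):
        rng = random.Random(9)
        thetas = np.array([rng.gauss(0.3, 0.3) for _ in range(8)])
        var = np.array([rng.uniform(0.01, 0.2) for _ in range(8)])
        effects = [effect(t, math.sqrt(v), f"s{i}")
                   for i, (t, v) in enumerate(zip(thetas, var))]
        pooled = pool_dersimonian_laird(effects)
        ref = combine_effects(thetas, var, method_re="dl")
        assert pooled.tau2 == pytest.approx(ref.tau2, abs=1e-10)
        assert math.log(pooled.or_point) == pytest.approx(
            ref.mean_effect_re, abs=1e-10)


class TestRunMeta:
    def test_asian_additive_includes_six_count_rows(self, fixture_records):
        res = run_meta(fixture_records, GeneticModel.ADDITIVE, "Asian")
        assert res.k == 6
        assert res.excluded_studies == ()

    def test_bevan_excluded_from_dominant_with_reason(self, fixture_records):
        res = run_meta(fixture_records, GeneticModel.DOMINANT, "pooled")
        excluded = dict(res.excluded_studies)
        assert "Bevan" in excluded
        assert "no genotype counts" in excluded["Bevan"]

    def test_single_study_subgroup_returns_crude_estimate(self, fixture_records):
        one = [r for r in fixture_records if r.study_id == "Shi"]
        res = run_meta(one, GeneticModel.ALLELE, "Asian")
        crude = odds_ratio(build_contrast(one[0], GeneticModel.ALLELE))
        assert res.k == 1
        assert res.het is None
        assert res.or_point == pytest.approx(crude.or_point)

    def test_empty_subgroup_rejected(self, fixture_records):
        with pytest.raises(EmptySubgroupError):
            run_meta(fixture_records, GeneticModel.ALLELE, "Martian")

    def test_effect_only_row_joins_allele_pool_under_random_effects(self):
        from snpmeta.io_studies import StudyRecord

        counts = [
            StudyRecord(study_id=f"s{i}", snp_id="rs1", population="x",
                        subgroup="g", cohort_id=f"s{i}", n_case=100,
                        n_control=100, case_counts=c, control_counts=t)
            for i, (c, t) in enumerate([
                ((60, 30, 10), (20, 40, 40)),
                ((15, 45, 40), (45, 40, 15)),
                ((35, 40, 25), (30, 45, 25)),
            ])
        ]
        reported = StudyRecord(
            study_id="rep", snp_id="rs1", population="x", subgroup="g",
            cohort_id="rep", n_case=500, n_control=500,
            effect_only=(1.32, 1.18, 1.48))
        res = run_meta(counts + [reported], GeneticModel.ALLELE)
        assert res.method is PoolingMethod.DL_RANDOM  # wildly heterogeneous
        assert "rep:rs1" in res.included_studies
        # under a non-allele model the same row is excluded instead
        res2 = run_meta(counts + [reported], GeneticModel.DOMINANT)
        assert ("rep", "no genotype counts") in res2.excluded_studies

    def test_order_invariance(self, fixture_records):
        shuffled = list(fixture_records)
        random.Random(2).shuffle(shuffled)
        for model in GeneticModel:
            a = run_meta(fixture_records, model, "pooled")
            b = run_meta(shuffled, model, "pooled")
            assert a.or_point == pytest.approx(b.or_point, abs=1e-12)
            assert a.het.q == pytest.approx(b.het.q, abs=1e-12)
            assert a.weights == pytest.approx(b.weights)
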
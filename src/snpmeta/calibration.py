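"""Monte-Carlo calibration experiments on synthetic scenarios.

These drivers quantify the statistical behaviour of the pipeline under
known truth: type-I error of the heterogeneity and Hardy-Weinberg tests,
confidence-interval coverage of Mantel-Haenszel pooling, and recovery of
the DerSimonian-Laird between-study variance.  They are used by the test
suite and the reproduction script; each is deterministic in its ``seed``.
"""

from __future__ import annotations

import math

import numpy as np

from .association_stats import EffectEstimate, hwe_test, odds_ratio
from .genetic_models import GeneticModel, build_contrast
from .meta_pool import cochran_q, dl_tau2, pool_mantel_haenszel
from .synthetic import SyntheticScenario, generate_scenario_table


def _rep_seeds(seed: int, n_reps: int) -> np.ndarray:
    """Independent per-replicate scenario seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n_reps) & 0x7FFFFFFF


def q_type1_rate(
    n_reps: int = 2000, k: int = 10, n: int = 1000,
    p_control: float = 0.3, or_allele: float = 1.2,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Rejection rate of Cochran's Q on homogeneous (tau = 0) scenarios.

    Effects are allele-model Woolf log-ORs; under homogeneity the rate
    should sit at the nominal ``alpha``.
    """
    rejections = 0
    for s in _rep_seeds(seed, n_reps):
        scenario = SyntheticScenario(
            k=k, n_case=n, n_control=n, p_control=p_control,
            or_allele=or_allele, tau=0.0, seed=int(s))
        effects = [odds_ratio(build_contrast(r, GeneticModel.ALLELE))
                   for r in generate_scenario_table(scenario)]
        rejections += cochran_q(effects).p < alpha
    return rejections / n_reps


def hwe_type1_rate(
    n_reps: int = 2000, n: int = 1000, p_control: float = 0.3,
    alpha: float = 0.05, seed: int = 0,
) -> float:
    """Rejection rate of the HWE chi-square test on samples drawn from
    exact Hardy-Weinberg proportions."""
    rejections = 0
    for s in _rep_seeds(seed, n_reps):
        scenario = SyntheticScenario(
            k=1, n_case=10, n_control=n, p_control=p_control,
            hwe_f=0.0, seed=int(s))
        [record] = generate_scenario_table(scenario)
        rejections += hwe_test(record.control_counts).p < alpha
    return rejections / n_reps


def mh_coverage(
    or_allele: float, n_reps: int = 2000, k: int = 10, n: int = 1000,
    p_control: float = 0.3, seed: int = 0,
) -> float:
    """Coverage of the MH pooled 95% CI for the true per-allele OR
    (allele model, homogeneous studies)."""
    covered = 0
    for s in _rep_seeds(seed, n_reps):
        scenario = SyntheticScenario(
            k=k, n_case=n, n_control=n, p_control=p_control,
            or_allele=or_allele, tau=0.0, seed=int(s))
        tables = [build_contrast(r, GeneticModel.ALLELE)
                  for r in generate_scenario_table(scenario)]
        pooled = pool_mantel_haenszel(tables)
        covered += pooled.ci_low <= or_allele <= pooled.ci_high
    return covered / n_reps


def dl_tau2_recovery(
    n_reps: int = 1000, k: int = 20, tau2: float = 0.04,
    mu: float = 0.3, seed: int = 0,
) -> float:
    """Mean DerSimonian-Laird tau^2 estimate over replicates of k studies
    with known within-study standard errors.

    Each replicate draws true study effects ``Normal(mu, tau2)`` and
    observed effects ``Normal(theta_i, se_i^2)`` with se_i spread over
    [0.1, 0.3]; the DL moment estimator should average close to ``tau2``.
    """
    rng = np.random.default_rng(seed)
    tau = math.sqrt(tau2)
    estimates = np.empty(n_reps)
    for i in range(n_reps):
        ses = rng.uniform(0.1, 0.3, size=k)
        thetas = rng.normal(mu, tau, size=k) + rng.normal(0.0, ses)
        effects = [
            EffectEstimate(
                study_id=f"s{j}", snp_id="rsSIM", model=GeneticModel.ALLELE,
                log_or=float(t), se=float(s),
                or_point=math.exp(t),
                ci_low=math.exp(t - 1.96 * s), ci_high=math.exp(t + 1.96 * s))
            for j, (t, s) in enumerate(zip(thetas, ses))
        ]
        estimates[i] = dl_tau2(effects)
    return float(estimates.mean())
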
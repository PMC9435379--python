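"""Synthetic case-control genotype studies with known truth.

The generator emulates the sampling structure the analysis assumes: controls
are drawn multinomially from population genotype frequencies, cases from the
genotype distribution implied by a per-allele (multiplicative) odds ratio.
Its parameters are the quantities the pipeline is supposed to recover, so
every stage can be validated against known truth without external data.

Model
-----
For a scenario with control allele frequency ``p``, per-allele odds ratio
``OR`` and between-study spread ``tau``:

* study j draws its own log odds ratio ``ln OR_j ~ Normal(ln OR, tau^2)``;
* control genotype probabilities follow Hardy-Weinberg proportions,
  optionally distorted by an inbreeding-style coefficient ``f``:
  ``(p^2 + f p q, 2 p q (1 - f), q^2 + f p q)``;
* case allele odds are ``OR_j`` times the control allele odds, and case
  genotypes follow Hardy-Weinberg at the implied case allele frequency
  (no distortion on the case side);
* genotype counts are multinomial draws of the requested arm sizes.

Because the disease model is allelic, the allele-model contrast has true
odds ratio exactly ``OR``; the recessive, dominant and additive contrasts
have derived true values computable from the genotype probabilities with
:func:`true_contrast_or`.

Each study's random stream is seeded by ``(seed, study_index)``, so removing
a study from a scenario does not shift the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .genetic_models import GeneticModel
from .io_studies import StudyRecord
from .association_stats import odds_ratio
from .genetic_models import build_contrast


class ScenarioError(ValueError):
    """Scenario parameters are outside their valid domain."""


def hwe_probs(p: float, f: float = 0.0) -> tuple[float, float, float]:
    """Genotype probabilities (AA, AG, GG) at allele frequency ``p`` with
    inbreeding-style distortion ``f`` (``f = 0`` is exact Hardy-Weinberg)."""
    q = 1.0 - p
    probs = (p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q)
    if any(x < 0 or x > 1 for x in probs):
        raise ScenarioError(
            f"distorted genotype probabilities outside [0, 1]: {probs}")
    return probs


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for a bank of k synthetic case-control studies.

    Parameters
    ----------
    k
        Number of studies.
    n_case, n_control
        Per-study arm sizes; a scalar applies to every study, a sequence
        gives per-study sizes (length k).
    p_control
        Control-population frequency of the coded allele, in (0, 1).
    or_allele
        True per-allele odds ratio (> 0).
    tau
        Between-study standard deviation of the log odds ratio; 0 gives a
        homogeneous bank.
    hwe_f
        Hardy-Weinberg distortion coefficient applied to controls.
    seed
        Master seed; study j uses the stream seeded by (seed, j).
    subgroups
        Optional per-study subgroup labels (length k); defaults to
        "synthetic" for every study.
    effect_only
        Indices of studies to emit as reported-effect rows: their genotype
        counts are drawn, converted to an allele-model OR with 95% CI, and
        the counts discarded — mimicking a study that published only a
        summary estimate.
    """

    k: int
    n_case: int | Sequence[int] = 1000
    n_control: int | Sequence[int] = 1000
    p_control: float = 0.3
    or_allele: float = 1.0
    tau: float = 0.0
    hwe_f: float = 0.0
    seed: int = 0
    subgroups: tuple[str, ...] | None = None
    effect_only: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ScenarioError("k must be non-negative")
        if not (0 < self.p_control < 1):
            raise ScenarioError("p_control must lie in (0, 1)")
        if self.or_allele <= 0:
            raise ScenarioError("or_allele must be positive")
        if self.tau < 0:
            raise ScenarioError("tau must be non-negative")
        hwe_probs(self.p_control, self.hwe_f)  # validate distortion
        if self.subgroups is not None and len(self.subgroups) != self.k:
            raise ScenarioError("subgroups must have one label per study")
        for label, sizes in (("n_case", self.n_case),
                             ("n_control", self.n_control)):
            if not isinstance(sizes, int) and len(sizes) != self.k:
                raise ScenarioError(f"{label} must be scalar or length k")

    def _size(self, sizes: int | Sequence[int], j: int) -> int:
        return sizes if isinstance(sizes, int) else int(sizes[j])


def case_probs(p_control: float, or_study: float) -> tuple[float, float, float]:
    """Case genotype probabilities under the allelic disease model.

    Case allele odds are the control allele odds multiplied by the study
    odds ratio; genotypes follow Hardy-Weinberg at that allele frequency.
    """
    odds = p_control / (1.0 - p_control) * or_study
    p_case = odds / (1.0 + odds)
    return hwe_probs(p_case)


def true_contrast_or(scenario: SyntheticScenario,
                     model: GeneticModel | str) -> float:
    """The true odds ratio of a genetic-model contrast implied by the
    scenario's genotype probabilities (at tau = 0)."""
    model = GeneticModel(model)
    ctrl = hwe_probs(scenario.p_control, scenario.hwe_f)
    case = case_probs(scenario.p_control, scenario.or_allele)

    def collapse(probs: tuple[float, float, float]) -> tuple[float, float]:
        aa, ag, gg = probs
        if model is GeneticModel.ALLELE:
            return (2 * aa + ag, 2 * gg + ag)
        if model is GeneticModel.RECESSIVE:
            return (aa, ag + gg)
        if model is GeneticModel.DOMINANT:
            return (aa + ag, gg)
        return (aa, gg)

    (a, b), (c, d) = collapse(case), collapse(ctrl)
    return (a * d) / (b * c)


def generate_study(scenario: SyntheticScenario, study_index: int) -> StudyRecord:
    """Draw one study's genotype counts; deterministic in (seed, study_index)."""
    if not (0 <= study_index < scenario.k):
        raise ScenarioError(f"study_index {study_index} outside [0, {scenario.k})")
    rng = np.random.default_rng((scenario.seed, study_index))
    log_or_j = rng.normal(math.log(scenario.or_allele), scenario.tau)
    ctrl_p = hwe_probs(scenario.p_control, scenario.hwe_f)
    case_p = case_probs(scenario.p_control, math.exp(log_or_j))
    n_case = scenario._size(scenario.n_case, study_index)
    n_control = scenario._size(scenario.n_control, study_index)
    case_counts = tuple(int(x) for x in rng.multinomial(n_case, case_p))
    control_counts = tuple(int(x) for x in rng.multinomial(n_control, ctrl_p))
    study_id = f"sim{study_index + 1:03d}"
    subgroup = (scenario.subgroups[study_index]
                if scenario.subgroups is not None else "synthetic")
    record = StudyRecord(
        study_id=study_id, snp_id="rsSIM", population="synthetic",
        subgroup=subgroup, cohort_id=study_id,
        n_case=n_case, n_control=n_control,
        case_counts=case_counts, control_counts=control_counts,
    )
    if study_index in scenario.effect_only:
        est = odds_ratio(build_contrast(record, GeneticModel.ALLELE))
        from dataclasses import replace
        record = replace(record, case_counts=None, control_counts=None,
                         effect_only=(est.or_point, est.ci_low, est.ci_high))
    return record


def generate_scenario_table(scenario: SyntheticScenario) -> list[StudyRecord]:
    """Generate the full bank of k studies (round-trippable through the
    study-table reader/writer)."""
    return [generate_study(scenario, j) for j in range(scenario.k)]
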
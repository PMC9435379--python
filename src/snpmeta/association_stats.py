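"""Per-study association statistics: odds ratios and Hardy-Weinberg tests.

Odds ratios from 2x2 contrast tables use the Woolf log-OR variance
``1/a + 1/b + 1/c + 1/d``; when any cell is zero the Haldane-Anscombe
continuity correction (add 0.5 to every cell) is applied first and the
estimate is flagged.  Confidence intervals are 95% normal intervals on the
log scale with the conventional 1.96 quantile.

The Hardy-Weinberg equilibrium check is the plain one-degree-of-freedom
chi-square goodness-of-fit test against expected genotype counts
``(n p^2, 2 n p q, n q^2)`` at the sample allele frequency, without
continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .genetic_models import ContrastTable, GeneticModel

#: Normal quantile used for all 95% intervals.
Z95 = 1.96


class DegenerateTableError(ValueError):
    """An entire margin of the 2x2 table is zero; no OR is estimable."""


@dataclass(frozen=True)
class EffectEstimate:
    """A per-study log odds ratio with its standard error and 95% CI."""

    study_id: str
    snp_id: str
    model: GeneticModel | None
    log_or: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError("standard error must be finite and positive")

    @property
    def weight(self) -> float:
        """Inverse-variance weight 1/se^2."""
        return 1.0 / (self.se * self.se)


@dataclass(frozen=True)
class HWEResult:
    """Chi-square Hardy-Weinberg test for one genotype triple (df = 1)."""

    study_id: str
    snp_id: str
    group: str
    chi2: float
    df: int
    p: float
    monomorphic: bool = False


def odds_ratio(table: ContrastTable) -> EffectEstimate:
    """Crude odds ratio of a 2x2 contrast table with Woolf standard error.

    A zero cell triggers the Haldane-Anscombe correction (+0.5 to all four
    cells, for both the point estimate and the variance) and sets the
    ``corrected`` flag.  A table with an entirely empty margin is not
    estimable and raises :class:`DegenerateTableError`.
    """
    a, b, c, d = table.cells()
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DegenerateTableError(
            f"{table.study_id}/{table.snp_id}: zero margin in "
            f"{table.model.value} contrast table {table.cells()}"
        )
    corrected = 0 in table.cells()
    if corrected:
        a, b, c, d = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        study_id=table.study_id, snp_id=table.snp_id, model=table.model,
        log_or=log_or, se=se,
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        corrected=corrected,
    )


def effect_from_reported(
    or_point: float, ci_low: float, ci_high: float,
    *, study_id: str = "", snp_id: str = "",
    model: GeneticModel | None = None,
) -> EffectEstimate:
    """Reconstruct a log-OR effect from a published OR and 95% CI.

    The standard error is recovered from the CI width on the log scale,
    ``(ln hi - ln lo) / (2 * 1.96)``.
    """
    if not (0 < ci_low <= or_point <= ci_high):
        raise ValueError(
            f"reported effect must satisfy 0 < ci_low <= OR <= ci_high, got "
            f"({or_point}, {ci_low}, {ci_high})"
        )
    log_or = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z95)
    return EffectEstimate(
        study_id=study_id, snp_id=snp_id, model=model,
        log_or=log_or, se=se, or_point=or_point,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
    )


def hwe_test(
    genotypes: tuple[int, int, int],
    *, study_id: str = "", snp_id: str = "", group: str = "",
) -> HWEResult:
    """Chi-square Hardy-Weinberg equilibrium test for an (AA, AG, GG) triple.

    A monomorphic sample (one allele absent) trivially satisfies
    equilibrium; it is returned flagged with chi2 = 0 and p = 1 rather than
    raising, so that batch pipelines keep running.
    """
    aa, ag, gg = genotypes
    if min(aa, ag, gg) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = aa + ag + gg
    if n < 1:
        raise ValueError("at least one individual required")
    p_hat = (2 * aa + ag) / (2 * n)
    q_hat = 1.0 - p_hat
    if p_hat == 0.0 or q_hat == 0.0:
        return HWEResult(study_id=study_id, snp_id=snp_id, group=group,
                         chi2=0.0, df=1, p=1.0, monomorphic=True)
    expected = (n * p_hat * p_hat, 2 * n * p_hat * q_hat, n * q_hat * q_hat)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(genotypes, expected))
    return HWEResult(
        study_id=study_id, snp_id=snp_id, group=group,
        chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)),
    )
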
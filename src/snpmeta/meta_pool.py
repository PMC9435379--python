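"""Heterogeneity assessment, fixed/random-effects pooling and subgroup runs.

The pooling strategy mirrors standard meta-analytic practice for
genotype-count data: Cochran's Q on inverse-variance (Woolf) log-OR effects
decides between Mantel-Haenszel fixed-effect pooling of the raw 2x2 tables
and DerSimonian-Laird random effects on the log-OR scale.  The decision rule
is configurable; the default declares heterogeneity when the Q p-value is
below 0.05 *or* I^2 exceeds 50%, and a stricter conjunctive variant
(p < 0.1 *and* I^2 > 50%) is available via :class:`HeterogeneityRule`.

Q and I^2 are always computed on Woolf log-OR effects, including when the
point pooling is Mantel-Haenszel, because MH pooling provides no per-study
variances for a Q statistic.

The Mantel-Haenszel confidence interval uses the Robins-Breslow-Greenland
variance of the pooled log-OR, which remains valid for sparse tables.  The
MH point estimate is always computed from the raw cell counts; for tables
containing a zero cell, only the variance inputs receive the 0.5 continuity
correction.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from collections.abc import Sequence

from scipy import stats

from .association_stats import (
    DegenerateTableError, EffectEstimate, Z95, effect_from_reported, odds_ratio,
)
from .genetic_models import ContrastTable, GeneticModel, build_contrast
from .io_studies import StudyRecord


def _label(study_id: str, snp_id: str) -> str:
    """Unique per-row label: a cohort genotyped for two SNPs shares its
    study_id across rows, so weight maps are keyed study:snp."""
    return f"{study_id}:{snp_id}" if snp_id else study_id


class InsufficientStudiesError(ValueError):
    """Fewer studies than the statistic requires."""


class EmptySubgroupError(ValueError):
    """No usable study in the requested subgroup."""


class PoolingMethod(str, enum.Enum):
    MH_FIXED = "MH-fixed"
    DL_RANDOM = "DL-random"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class HeterogeneityRule:
    """When to abandon fixed-effect pooling for random effects.

    ``combine="any"`` declares heterogeneity when either criterion fires
    (the default, p < 0.05 or I^2 > 50); ``combine="all"`` requires both,
    the conjunctive reading sometimes used with p < 0.1.
    """

    p_threshold: float = 0.05
    i2_threshold: float = 50.0
    combine: str = "any"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0 <= self.i2_threshold <= 100):
            raise ValueError("i2_threshold must lie in [0, 100]")
        if self.combine not in ("any", "all"):
            raise ValueError("combine must be 'any' or 'all'")


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p-value and the I^2 percentage."""

    q: float
    k: int
    df: int
    p: float
    i2: float


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio for one (model x subgroup) analysis."""

    model: GeneticModel
    subgroup_label: str
    method: PoolingMethod
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    k: int
    het: HeterogeneityResult | None
    weights: dict[str, float] = field(default_factory=dict)
    included_studies: tuple[str, ...] = ()
    excluded_studies: tuple[tuple[str, str], ...] = ()  # (study, reason)


def cochran_q(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test on inverse-variance weighted effects.

    I^2 = (Q - df) / Q x 100%, clamped to [0, 100].
    """
    k = len(effects)
    if k < 2:
        raise InsufficientStudiesError(
            f"heterogeneity assessment needs >= 2 studies, got {k}")
    w = [e.weight for e in effects]
    mu = sum(wi * e.log_or for wi, e in zip(w, effects)) / sum(w)
    q = sum(wi * (e.log_or - mu) ** 2 for wi, e in zip(w, effects))
    df = k - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(
        q=q, k=k, df=df, p=float(stats.chi2.sf(q, df)), i2=min(i2, 100.0))


def select_method(het: HeterogeneityResult,
                  rule: HeterogeneityRule = HeterogeneityRule()) -> PoolingMethod:
    """Apply the heterogeneity rule: random effects when it fires, else MH."""
    fires = (het.p < rule.p_threshold, het.i2 > rule.i2_threshold)
    heterogeneous = any(fires) if rule.combine == "any" else all(fires)
    return PoolingMethod.DL_RANDOM if heterogeneous else PoolingMethod.MH_FIXED


def _normal_two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def pool_mantel_haenszel(
    tables: Sequence[ContrastTable],
    het: HeterogeneityResult | None = None,
) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled OR with the RBG variance.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i).  The point estimate is
    computed from the raw counts; tables with a zero cell contribute
    0.5-corrected cells to the variance sums only.  Per-study weights are
    reported as the normalised MH weights b_i c_i / n_i.
    """
    if not tables:
        raise InsufficientStudiesError("no tables to pool")
    r_sum = s_sum = 0.0
    # RBG variance accumulators, on (possibly corrected) cells
    sum_pr = sum_ps_qr = sum_qs = 0.0
    rv = sv = 0.0
    raw_weights: dict[str, float] = {}
    degenerate = 0
    for t in tables:
        a, b, c, d = t.cells()
        n = t.n
        if n == 0 or a + b == 0 or c + d == 0:
            degenerate += 1
            continue
        r_sum += a * d / n
        s_sum += b * c / n
        raw_weights[_label(t.study_id, t.snp_id)] = b * c / n
        if 0 in t.cells():
            a, b, c, d = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
            n = a + b + c + d
        p_i, q_i = (a + d) / n, (b + c) / n
        r_i, s_i = a * d / n, b * c / n
        rv += r_i
        sv += s_i
        sum_pr += p_i * r_i
        sum_ps_qr += p_i * s_i + q_i * r_i
        sum_qs += q_i * s_i
    if degenerate == len(tables) or s_sum == 0 or r_sum == 0:
        raise DegenerateTableError(
            "Mantel-Haenszel pooling: no estimable tables")
    log_or = math.log(r_sum / s_sum)
    var = (sum_pr / (2 * rv * rv)
           + sum_ps_qr / (2 * rv * sv)
           + sum_qs / (2 * sv * sv))
    se = math.sqrt(var)
    total_w = sum(raw_weights.values())
    weights = {s: w / total_w for s, w in raw_weights.items()}
    model = tables[0].model
    return PooledResult(
        model=model, subgroup_label="", method=PoolingMethod.MH_FIXED,
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p=_normal_two_sided_p(log_or / se),
        tau2=0.0, k=len(raw_weights), het=het,
        weights=weights,
        included_studies=tuple(raw_weights),
    )


def dl_tau2(effects: Sequence[EffectEstimate]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance."""
    het = cochran_q(effects)
    w = [e.weight for e in effects]
    sw = sum(w)
    denom = sw - sum(wi * wi for wi in w) / sw
    if denom <= 0:
        return 0.0
    return max(0.0, (het.q - het.df) / denom)


def pool_dersimonian_laird(
    effects: Sequence[EffectEstimate],
    het: HeterogeneityResult | None = None,
) -> PooledResult:
    """DerSimonian-Laird random-effects pooled OR on the log scale.

    Random-effects weights are ``1 / (se_i^2 + tau^2)`` with the DL moment
    estimate of tau^2; with tau^2 = 0 this reduces exactly to
    inverse-variance fixed-effect pooling.
    """
    if len(effects) < 2:
        raise InsufficientStudiesError(
            f"random-effects pooling needs >= 2 studies, got {len(effects)}")
    het = het if het is not None else cochran_q(effects)
    tau2 = dl_tau2(effects)
    w_star = [1.0 / (e.se * e.se + tau2) for e in effects]
    sw = sum(w_star)
    log_or = sum(wi * e.log_or for wi, e in zip(w_star, effects)) / sw
    se = 1.0 / math.sqrt(sw)
    return PooledResult(
        model=effects[0].model, subgroup_label="",
        method=PoolingMethod.DL_RANDOM,
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p=_normal_two_sided_p(log_or / se),
        tau2=tau2, k=len(effects), het=het,
        weights={_label(e.study_id, e.snp_id): wi / sw
                 for e, wi in zip(effects, w_star)},
        included_studies=tuple(_label(e.study_id, e.snp_id) for e in effects),
    )


# reason codes for excluded_studies entries
REASON_NO_DATA = "no genotype counts or reported effect"
REASON_NO_COUNTS = "no genotype counts"
REASON_EFFECT_ONLY_MH = "reported-effect row unusable in count-based MH pooling"
REASON_NOT_IN_SUBGROUP = "outside subgroup"


def study_effects(
    records: Sequence[StudyRecord], model: GeneticModel | str
) -> list[EffectEstimate]:
    """Per-study Woolf effects under one genetic model (count rows only)."""
    model = GeneticModel(model)
    return [odds_ratio(build_contrast(r, model))
            for r in records if r.has_counts]


def run_meta(
    records: Sequence[StudyRecord],
    model: GeneticModel | str,
    subgroup: str = "pooled",
    rule: HeterogeneityRule = HeterogeneityRule(),
) -> PooledResult:
    """One complete pooled analysis: filter, estimate, assess, select, pool.

    ``subgroup="pooled"`` keeps every record; any other label keeps records
    whose ``subgroup`` field matches.  Rows without genotype counts are
    excluded from the recessive, dominant and additive contrasts (their
    reported effect, if any, cannot be re-expressed under those models);
    under the allele model a reported-effect row joins the analysis through
    inverse-variance weighting when the heterogeneity rule selects random
    effects, and is excluded with a logged reason when the count-based
    Mantel-Haenszel path is taken.
    """
    model = GeneticModel(model)
    excluded: list[tuple[str, str]] = []
    if subgroup == "pooled":
        selected = list(records)
    else:
        selected = [r for r in records if r.subgroup == subgroup]

    count_rows = [r for r in selected if r.has_counts]
    effect_rows = [r for r in selected if r.has_effect]
    for r in selected:
        if r.unavailable:
            excluded.append((r.study_id, REASON_NO_DATA))
    if model is not GeneticModel.ALLELE:
        for r in effect_rows:
            excluded.append((r.study_id, REASON_NO_COUNTS))
        effect_rows = []

    tables = [build_contrast(r, model) for r in count_rows]
    effects = [odds_ratio(t) for t in tables]
    effects += [
        effect_from_reported(*r.effect_only, study_id=r.study_id,
                             snp_id=r.snp_id, model=model)
        for r in effect_rows
    ]
    if not effects:
        raise EmptySubgroupError(
            f"no usable study for model={model.value!r} subgroup={subgroup!r}")

    if len(effects) == 1:
        e = effects[0]
        result = PooledResult(
            model=model, subgroup_label=subgroup,
            method=PoolingMethod.MH_FIXED,
            or_point=e.or_point, ci_low=e.ci_low, ci_high=e.ci_high,
            p=_normal_two_sided_p(e.log_or / e.se),
            tau2=0.0, k=1, het=None,
            weights={_label(e.study_id, e.snp_id): 1.0},
            included_studies=(_label(e.study_id, e.snp_id),),
            excluded_studies=tuple(excluded),
        )
        return result

    het = cochran_q(effects)
    method = select_method(het, rule)
    if method is PoolingMethod.DL_RANDOM:
        pooled = pool_dersimonian_laird(effects, het)
    else:
        for r in effect_rows:
            excluded.append((r.study_id, REASON_EFFECT_ONLY_MH))
        pooled = pool_mantel_haenszel(tables, het)
    from dataclasses import replace
    return replace(pooled, subgroup_label=subgroup,
                   excluded_studies=tuple(excluded))
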
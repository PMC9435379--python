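"""Funnel-plot data and Egger's regression test for small-study bias.

Egger's test is the classical unweighted ordinary-least-squares regression
of the standardised effect ``z_i = theta_i / se_i`` on the precision
``1 / se_i``; a regression intercept far from zero signals funnel-plot
asymmetry.  The intercept's two-sided t-test uses k - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import statsmodels.api as sm

from .association_stats import EffectEstimate


class InsufficientStudiesForEggerError(ValueError):
    """Egger's regression needs at least three studies (df >= 1)."""


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se_intercept: float
    t: float
    df: int
    p: float
    k: int


@dataclass(frozen=True)
class FunnelPoint:
    """One study in funnel-plot coordinates: log-OR against its standard
    error (conventionally drawn with the se axis inverted)."""

    study_id: str
    x: float  # log-OR
    y: float  # standard error


def funnel_data(effects: Sequence[EffectEstimate]) -> list[FunnelPoint]:
    """Funnel-plot coordinates, one point per study, no transformation."""
    if not effects:
        raise ValueError("at least one study required")
    return [FunnelPoint(study_id=e.study_id, x=e.log_or, y=e.se)
            for e in effects]


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's regression test of funnel-plot asymmetry."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesForEggerError(
            f"Egger's test needs >= 3 studies, got {k}")
    precision = np.array([1.0 / e.se for e in effects])
    z = np.array([e.log_or / e.se for e in effects])
    fit = sm.OLS(z, sm.add_constant(precision)).fit()
    intercept = float(fit.params[0])
    se_int = float(fit.bse[0])
    t = intercept / se_int
    return EggerResult(
        intercept=intercept, se_intercept=se_int, t=t,
        df=k - 2, p=float(fit.pvalues[0]), k=k,
    )
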
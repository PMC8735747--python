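"""Publication-bias diagnostics: Egger regression, Begg-Mazumdar rank
correlation, and funnel-plot data export.

Egger's test regresses each study's standard normal deviate (log OR / SE)
on its precision (1 / SE) by ordinary least squares; under no small-study
bias the intercept is zero, and the test is a two-sided t on the intercept
with k - 2 degrees of freedom.

Begg's test standardizes each effect against the fixed-effect pooled value
using the variance v_i* = se_i^2 - 1/sum(1/se_j^2) (the variance of
theta_i - theta_FE), then computes Kendall's S between the standardized
effects and their variances. The normal approximation for S uses the
tie-corrected variance and, for small meta-analyses (k < 10), a continuity
correction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectEstimate
from .errors import DegenerateDesignError, InsufficientStudiesError
from .pooling import PoolResult

__all__ = ["EggerResult", "BeggResult", "egger_test", "begg_test", "funnel_data"]


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    slope: float
    t_stat: float
    df: int
    p: float


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    s_statistic: int
    n_concordant: int
    n_discordant: int
    z: float
    p: float
    continuity_corrected: bool


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger weighted-regression intercept test for funnel asymmetry.

    Requires k >= 3 (the regression spends two parameters). Raises
    DegenerateDesignError when all precisions coincide, since the slope is
    then unidentifiable.
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Egger's test requires k >= 3, got {k}")
    precision = np.array([1.0 / e.se for e in effects])
    snd = np.array([e.log_or / e.se for e in effects])
    if np.ptp(precision) == 0:
        raise DegenerateDesignError(
            "all studies have identical precision; Egger regression is degenerate"
        )
    fit = stats.linregress(precision, snd)
    df = k - 2
    if fit.intercept_stderr == 0:
        # exact collinear fit: the intercept either is 0 (no asymmetry,
        # p = 1) or is known without error (p = 0)
        t_stat = 0.0 if fit.intercept == 0 else math.inf * math.copysign(1, fit.intercept)
        p = 1.0 if fit.intercept == 0 else 0.0
    else:
        t_stat = fit.intercept / fit.intercept_stderr
        p = float(2 * stats.t.sf(abs(t_stat), df))
    return EggerResult(
        intercept=float(fit.intercept),
        intercept_se=float(fit.intercept_stderr),
        slope=float(fit.slope),
        t_stat=float(t_stat),
        df=df,
        p=p,
    )


def _kendall_s(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    """Kendall score by pair enumeration: (S, concordant, discordant)."""
    n = len(x)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            prod = np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])
            if prod > 0:
                conc += 1
            elif prod < 0:
                disc += 1
    return conc - disc, conc, disc


def _tie_term(values: np.ndarray) -> float:
    return sum(t * (t - 1) * (2 * t + 5) for t in Counter(values.tolist()).values())


def begg_test(effects: Sequence[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar rank correlation test for publication bias.

    Standardizes each study effect against the fixed-effect pooled log OR,
    correlates the standardized effects with their variances (Kendall), and
    refers S to its tie-corrected normal approximation. The continuity
    correction |S| - 1 is applied when k < 10.
    """
    k = len(effects)
    if k < 2:
        raise InsufficientStudiesError(f"Begg's test requires k >= 2, got {k}")
    v = np.array([e.var for e in effects])
    y = np.array([e.log_or for e in effects])
    w = 1.0 / v
    theta_fe = float((w * y).sum() / w.sum())
    v_star = v - 1.0 / w.sum()
    # v_star is positive unless a study carries all the weight; guard the sqrt
    v_star = np.maximum(v_star, np.finfo(float).tiny)
    t_std = (y - theta_fe) / np.sqrt(v_star)
    s, conc, disc = _kendall_s(t_std, v)
    n_pairs = k * (k - 1) // 2
    tau = s / n_pairs
    var_s = (
        k * (k - 1) * (2 * k + 5) - _tie_term(t_std) - _tie_term(v)
    ) / 18.0
    continuity = k < 10
    if var_s <= 0:
        z = 0.0
    elif continuity:
        z = max(0.0, abs(s) - 1.0) / math.sqrt(var_s) * (1 if s >= 0 else -1)
    else:
        z = s / math.sqrt(var_s)
    p = float(2 * stats.norm.sf(abs(z)))
    return BeggResult(
        kendall_tau=float(tau),
        s_statistic=int(s),
        n_concordant=conc,
        n_discordant=disc,
        z=float(z),
        p=p,
        continuity_corrected=continuity,
    )


def funnel_data(
    effects: Sequence[EffectEstimate], pooled: PoolResult
) -> pd.DataFrame:
    """Funnel-plot table: per-study (log OR, SE) with pseudo-95% guide lines.

    Rows are sorted by SE (most precise first). The guide columns give the
    pooled log OR +/- 1.96 * SE at each study's SE, the usual funnel
    envelope.
    """
    if not effects:
        raise InsufficientStudiesError("no effects for funnel data")
    z = stats.norm.ppf(0.975)
    df = pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "log_or": [e.log_or for e in effects],
            "se": [e.se for e in effects],
        }
    ).sort_values("se", kind="stable", ignore_index=True)
    df["guide_low"] = pooled.log_or - z * df["se"]
    df["guide_high"] = pooled.log_or + z * df["se"]
    return df
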
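"""Fixed-effect and DerSimonian-Laird random-effects pooling.

Given per-study log odds ratios theta_i with standard errors se_i:

* fixed effect (inverse variance): weights w_i = 1/se_i^2, pooled estimate
  sum(w_i theta_i)/sum(w_i), SE 1/sqrt(sum w_i);
* heterogeneity: Cochran's Q = sum w_i (theta_i - theta_FE)^2 on k-1 df,
  I^2 = max(0, (Q - df)/Q) * 100;
* DerSimonian-Laird random effects: method-of-moments between-study
  variance tau^2 = max(0, (Q - df)/C) with C = sum w_i - sum w_i^2/sum w_i,
  then inverse-variance pooling with weights 1/(se_i^2 + tau^2).

The pooled-effect test is a Wald z against the standard normal (no
Knapp-Hartung adjustment). With a single study every pooling function is a
passthrough and the heterogeneity fields are not applicable (None).

A Mantel-Haenszel fixed-effect estimator over the raw 2x2 tables (with the
Robins-Breslow-Greenland variance) is provided as an alternative; inverse
variance remains the default since it is what the DL machinery reuses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import StudyTable
from .effects import EffectEstimate, study_effect
from .errors import InsufficientStudiesError
from .models import GeneticModel, TwoByTwo, derive_2x2

__all__ = [
    "PoolingMethod",
    "PoolResult",
    "ModelResult",
    "heterogeneity",
    "pool_fixed_iv",
    "pool_random_dl",
    "pool_mantel_haenszel",
    "run_model",
]


class PoolingMethod(str, Enum):
    FIXED_IV = "fixed_iv"
    RANDOM_DL = "random_dl"
    FIXED_MH = "fixed_mh"


@dataclass(frozen=True)
class PoolResult:
    """Pooled effect with heterogeneity statistics.

    ``Q``, ``p_q`` and ``i2`` are None when k = 1 (not applicable).
    ``weights`` are normalized per-study weights summing to 1, keyed and
    ordered as the input effects.
    """

    method: PoolingMethod
    k: int
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    Q: float | None
    df: int
    p_q: float | None
    i2: float | None
    tau2: float
    weights: tuple[tuple[str, float], ...]
    ci_level: float = 0.95


def _q_statistic(effects: Sequence[EffectEstimate]) -> tuple[float, int, float, float]:
    """(Q, df, p_q, i2) from fixed-effect inverse-variance weights."""
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.var for e in effects])
    theta_fe = float((w * y).sum() / w.sum())
    q = float((w * (y - theta_fe) ** 2).sum())
    df = len(effects) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, p_q, i2


def heterogeneity(
    effects: Sequence[EffectEstimate],
) -> tuple[float, int, float, float]:
    """Cochran's Q, its df and p-value, and I^2 (percent).

    Requires at least two studies; a single study has no within-set
    dispersion to measure.
    """
    if len(effects) < 2:
        raise InsufficientStudiesError(
            f"heterogeneity requires k >= 2 studies, got {len(effects)}"
        )
    return _q_statistic(effects)


def _pool(
    effects: Sequence[EffectEstimate],
    tau2: float,
    method: PoolingMethod,
    q: float | None,
    df: int,
    p_q: float | None,
    i2: float | None,
    ci_level: float,
) -> PoolResult:
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / (e.var + tau2) for e in effects])
    theta = float((w * y).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    zq = stats.norm.ppf(0.5 + ci_level / 2)
    z = theta / se
    p = float(2 * stats.norm.sf(abs(z)))
    wn = w / w.sum()
    return PoolResult(
        method=method,
        k=len(effects),
        log_or=theta,
        se=se,
        or_=math.exp(theta),
        ci_low=math.exp(theta - zq * se),
        ci_high=math.exp(theta + zq * se),
        z=float(z),
        p=p,
        Q=q,
        df=df,
        p_q=p_q,
        i2=i2,
        tau2=tau2,
        weights=tuple(zip([e.study_id for e in effects], wn.tolist())),
        ci_level=ci_level,
    )


def pool_fixed_iv(
    effects: Sequence[EffectEstimate], ci_level: float = 0.95
) -> PoolResult:
    """Inverse-variance fixed-effect pooling (passthrough for k = 1)."""
    if not effects:
        raise InsufficientStudiesError("no effects to pool")
    if len(effects) == 1:
        q, df, p_q, i2 = None, 0, None, None
    else:
        q, df, p_q, i2 = _q_statistic(effects)
    return _pool(effects, 0.0, PoolingMethod.FIXED_IV, q, df, p_q, i2, ci_level)


def pool_random_dl(
    effects: Sequence[EffectEstimate], ci_level: float = 0.95
) -> PoolResult:
    """DerSimonian-Laird random-effects pooling (passthrough for k = 1).

    tau^2 is truncated at zero, so when Q <= df the result coincides exactly
    with the fixed-effect inverse-variance pool.
    """
    if not effects:
        raise InsufficientStudiesError("no effects to pool")
    if len(effects) == 1:
        result = _pool(
            effects, 0.0, PoolingMethod.RANDOM_DL, None, 0, None, None, ci_level
        )
        return result
    q, df, p_q, i2 = _q_statistic(effects)
    w = np.array([1.0 / e.var for e in effects])
    c = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (q - df) / c)
    return _pool(effects, tau2, PoolingMethod.RANDOM_DL, q, df, p_q, i2, ci_level)


def pool_mantel_haenszel(
    tables: Sequence[TwoByTwo],
    study_ids: Sequence[str] | None = None,
    ci_level: float = 0.95,
) -> PoolResult:
    """Mantel-Haenszel fixed-effect pooled OR over raw 2x2 tables.

    Point estimate sum(a_i d_i / n_i) / sum(b_i c_i / n_i); variance of the
    log OR by the Robins-Breslow-Greenland formula. Heterogeneity statistics
    are computed from the per-table inverse-variance effects for
    comparability with the other estimators.
    """
    if not tables:
        raise InsufficientStudiesError("no tables to pool")
    ids = list(study_ids) if study_ids is not None else [""] * len(tables)
    # zero-cell tables get the same continuity correction as study_effect
    ts = [t.corrected() if t.has_zero_cell else t for t in tables]
    n = np.array([t.a + t.b + t.c + t.d for t in ts])
    r = np.array([t.a * t.d for t in ts]) / n
    s = np.array([t.b * t.c for t in ts]) / n
    p_ = np.array([t.a + t.d for t in ts]) / n
    q_ = np.array([t.b + t.c for t in ts]) / n
    theta = math.log(r.sum() / s.sum())
    var = (
        (p_ * r).sum() / (2 * r.sum() ** 2)
        + (p_ * s + q_ * r).sum() / (2 * r.sum() * s.sum())
        + (q_ * s).sum() / (2 * s.sum() ** 2)
    )
    se = math.sqrt(var)
    effects = [study_effect(t, i) for t, i in zip(tables, ids)]
    if len(effects) > 1:
        q, df, p_q, i2 = _q_statistic(effects)
    else:
        q, df, p_q, i2 = None, 0, None, None
    zq = stats.norm.ppf(0.5 + ci_level / 2)
    z = theta / se
    wmh = r + s  # MH weights are proportional to b*c/n for the OR; report r+s share
    wn = wmh / wmh.sum()
    return PoolResult(
        method=PoolingMethod.FIXED_MH,
        k=len(tables),
        log_or=theta,
        se=se,
        or_=math.exp(theta),
        ci_low=math.exp(theta - zq * se),
        ci_high=math.exp(theta + zq * se),
        z=float(z),
        p=float(2 * stats.norm.sf(abs(z))),
        Q=q,
        df=df,
        p_q=p_q,
        i2=i2,
        tau2=0.0,
        weights=tuple(zip(ids, wn.tolist())),
        ci_level=ci_level,
    )


@dataclass(frozen=True)
class ModelResult:
    """Everything computed for one genetic model on one study set."""

    model: GeneticModel
    effects: tuple[EffectEstimate, ...]
    fixed: PoolResult
    random: PoolResult
    selected: PoolingMethod

    @property
    def pooled(self) -> PoolResult:
        return self.random if self.selected is PoolingMethod.RANDOM_DL else self.fixed


def run_model(
    table: StudyTable,
    model: GeneticModel,
    method: str = "random",
    ci_level: float = 0.95,
) -> ModelResult:
    """Derive tables, estimate per-study effects, and pool, for one model.

    ``method`` selects which pool is flagged as the headline result:
    ``"random"`` (default, DL), ``"fixed"`` (IV), or ``"auto"`` (random
    exactly when the Q-test p-value is < 0.10, the conventional gate).
    Both pools are always computed and reported.
    """
    if len(table) == 0:
        raise InsufficientStudiesError("empty study table")
    effects = tuple(
        study_effect(derive_2x2(s.cases, s.controls, model), s.study_id, ci_level)
        for s in table
    )
    fixed = pool_fixed_iv(effects, ci_level)
    random = pool_random_dl(effects, ci_level)
    if method == "random":
        selected = PoolingMethod.RANDOM_DL
    elif method == "fixed":
        selected = PoolingMethod.FIXED_IV
    elif method == "auto":
        gate = fixed.p_q is not None and fixed.p_q < 0.10
        selected = PoolingMethod.RANDOM_DL if gate else PoolingMethod.FIXED_IV
    else:
        raise ValueError(f"unknown effect-model choice {method!r}")
    return ModelResult(
        model=model, effects=effects, fixed=fixed, random=random, selected=selected
    )
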
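"""Per-study odds ratios with Wald confidence intervals.

The effect measure is the log odds ratio ln(ad/bc) of the 2x2 table, with
the usual large-sample standard error sqrt(1/a + 1/b + 1/c + 1/d). If any
cell is zero the Haldane-Anscombe correction (0.5 added to all four cells
of that table only) is applied before taking logs, and the estimate is
flagged as corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .models import TwoByTwo

__all__ = ["EffectEstimate", "study_effect"]


@dataclass(frozen=True)
class EffectEstimate:
    """Log odds ratio, SE and Wald CI for one study under one model."""

    study_id: str
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    corrected: bool = False

    @property
    def var(self) -> float:
        return self.se**2


def study_effect(
    table: TwoByTwo, study_id: str = "", ci_level: float = 0.95
) -> EffectEstimate:
    """Odds ratio of a 2x2 table with Wald CI on the log scale.

    Zero cells trigger the Haldane-Anscombe +0.5 correction of the whole
    table; after correction every cell is positive so the estimate always
    exists.
    """
    corrected = table.has_zero_cell
    t = table.corrected() if corrected else table
    log_or = math.log((t.a * t.d) / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return EffectEstimate(
        study_id=study_id,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        ci_level=ci_level,
        corrected=corrected,
    )
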
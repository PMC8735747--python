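"""Subgroup analysis and leave-one-out sensitivity analysis.

Subgroup analysis partitions the study table by a metadata key (ethnicity
in the glioma application) and pools within each stratum; single-study
strata are reported as passthrough estimates with heterogeneity fields not
applicable rather than suppressed. Leave-one-out analysis re-pools the
remaining k-1 studies with each study omitted in turn, to check that no
single study drives the pooled estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataset import StudyTable
from .errors import InsufficientStudiesError, ValidationError
from .models import GeneticModel
from .pooling import ModelResult, run_model

__all__ = ["SubgroupReport", "SensitivityReport", "subgroup_analysis", "leave_one_out"]


@dataclass(frozen=True)
class SubgroupReport:
    """Per-stratum pooling results plus the overall pool for reference."""

    key: str
    model: GeneticModel
    groups: tuple[tuple[str, ModelResult], ...]  # (display label, result)
    overall: ModelResult

    def group(self, label: str) -> ModelResult:
        norm = label.strip().casefold()
        for lab, res in self.groups:
            if lab.strip().casefold() == norm:
                return res
        raise KeyError(label)


@dataclass(frozen=True)
class SensitivityReport:
    """Leave-one-out results keyed by the omitted study."""

    model: GeneticModel
    omitted: tuple[tuple[str, ModelResult], ...]

    def __getitem__(self, omitted_id: str) -> ModelResult:
        for sid, res in self.omitted:
            if sid == omitted_id:
                return res
        raise KeyError(omitted_id)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for sid, res in self.omitted:
            pooled = res.pooled
            rows.append(
                {
                    "omitted_id": sid,
                    "k": pooled.k,
                    "or": pooled.or_,
                    "ci_low": pooled.ci_low,
                    "ci_high": pooled.ci_high,
                    "p": pooled.p,
                }
            )
        return pd.DataFrame(rows)


def _metadata_value(study, key: str) -> str:
    if key in ("subgroup", "ethnicity"):  # ethnicity is the canonical use
        value = study.subgroup
    elif key == "design":
        value = study.design or ""
    elif key == "year":
        value = str(study.year)
    elif key == "author":
        value = study.author
    else:
        raise ValidationError(f"unknown subgroup key {key!r}")
    if not str(value).strip():
        raise ValidationError(
            f"study {study.study_id!r} has no value for subgroup key {key!r}"
        )
    return str(value)


def subgroup_analysis(
    table: StudyTable,
    key: str = "subgroup",
    model: GeneticModel = GeneticModel.ALLELE,
    method: str = "random",
    ci_level: float = 0.95,
) -> SubgroupReport:
    """Partition by a metadata key and pool each stratum under one model.

    Labels are compared case-insensitively after trimming, so "Non-Asian"
    and "non-asian" fall in the same stratum; the first-seen spelling is
    used for display. Stratum order follows first appearance in the table.
    """
    if len(table) == 0:
        raise InsufficientStudiesError("empty study table")
    order: list[str] = []
    labels: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for s in table:
        raw = _metadata_value(s, key)
        norm = raw.strip().casefold()
        if norm not in members:
            order.append(norm)
            labels[norm] = raw.strip()
            members[norm] = []
        members[norm].append(s.study_id)
    groups = tuple(
        (
            labels[norm],
            run_model(table.subset(members[norm]), model, method, ci_level),
        )
        for norm in order
    )
    overall = run_model(table, model, method, ci_level)
    return SubgroupReport(key=key, model=model, groups=groups, overall=overall)


def leave_one_out(
    table: StudyTable,
    model: GeneticModel = GeneticModel.ALLELE,
    method: str = "random",
    ci_level: float = 0.95,
) -> SensitivityReport:
    """Re-pool with each study omitted in turn (requires k >= 2)."""
    if len(table) < 2:
        raise InsufficientStudiesError(
            f"leave-one-out requires k >= 2 studies, got {len(table)}"
        )
    omitted = tuple(
        (sid, run_model(table.drop(sid), model, method, ci_level))
        for sid in table.study_ids
    )
    return SensitivityReport(model=model, omitted=omitted)
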
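"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` chains the stages — read/validate, HWE screen, per-model
2x2 derivation, per-study effects, fixed and random pooling, subgroup and
leave-one-out analyses, and Egger/Begg bias tests — and collects everything
into a :class:`Report` that serializes to JSON at full precision. Rounding
happens only in the text rendering, which follows the conventions of
published meta-analyses: odds ratios to two decimals, p-values to three
with "<.001" below 0.0005.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

from . import __version__
from .bias import BeggResult, EggerResult, begg_test, egger_test, funnel_data
from .dataset import StudyTable, builtin_fixture, read_studies
from .errors import DegenerateAnalysisError, InsufficientStudiesError
from .hwe import HweResult, hwe_chi_square, hwe_filter
from .models import GeneticModel
from .pooling import ModelResult, PoolResult, PoolingMethod, run_model
from .strata import (
    SensitivityReport,
    SubgroupReport,
    leave_one_out,
    subgroup_analysis,
)

__all__ = [
    "ModelSection",
    "Report",
    "run_pipeline",
    "render_text",
    "fmt_or",
    "fmt_p",
]

ALL_MODELS = tuple(GeneticModel)


def fmt_or(x: float) -> str:
    return f"{x:.2f}"


def fmt_p(p: float | None) -> str:
    """Paper-style p: three decimals without the leading zero, '<.001' floor."""
    if p is None:
        return "-"
    if p < 0.0005:
        return "<.001"
    s = f"{p:.3f}"
    return s[1:] if s.startswith("0.") else s


def fmt_i2(i2: float | None) -> str:
    return "-" if i2 is None else f"{i2:.1f}"


def _fmt_or_ci(r: PoolResult) -> str:
    return f"{fmt_or(r.or_)} ({fmt_or(r.ci_low)}, {fmt_or(r.ci_high)})"


@dataclass(frozen=True)
class ModelSection:
    """All results for one genetic model, plus degraded-stage warnings."""

    model: GeneticModel
    overall: ModelResult
    subgroup: SubgroupReport | None
    sensitivity: SensitivityReport | None
    egger: EggerResult | None
    begg: BeggResult | None
    funnel: Any  # pandas DataFrame
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class Report:
    """Machine-readable pipeline output; every rendered number lives here."""

    provenance: str
    options: dict
    version: str
    timestamp: str
    n_studies: int
    total_cases: int
    total_controls: int
    hwe: tuple[tuple[str, HweResult], ...]
    hwe_alpha: float
    excluded: tuple[tuple[str, HweResult], ...]
    sections: tuple[ModelSection, ...]

    def section(self, model: GeneticModel | str) -> ModelSection:
        model = GeneticModel.parse(model) if isinstance(model, str) else model
        for sec in self.sections:
            if sec.model is model:
                return sec
        raise KeyError(model)

    def to_dict(self) -> dict:
        return _as_jsonable(self)

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _as_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, GeneticModel):
        return obj.value
    if isinstance(obj, PoolingMethod):
        return obj.value
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if hasattr(obj, "to_dict") and not dataclasses.is_dataclass(obj):  # DataFrame
        return obj.to_dict(orient="records")
    if isinstance(obj, float) and obj != obj:  # NaN
        return None
    return obj


def run_pipeline(
    source: str | Path | StudyTable = "fixture",
    models: Sequence[GeneticModel | str] | None = None,
    subgroup_key: str | None = "subgroup",
    hwe_alpha: float = 0.01,
    method: str = "random",
    ci_level: float = 0.95,
) -> Report:
    """Run the complete meta-analysis and return a Report.

    ``source`` is a studies file path, the literal string ``"fixture"`` for
    the built-in glioma table, or an existing StudyTable. Stages that need
    more studies than remain after HWE screening (heterogeneity, sensitivity,
    bias tests) degrade to warnings rather than failing the pipeline.
    """
    if isinstance(source, StudyTable):
        table = source
    elif str(source) == "fixture":
        table = builtin_fixture()
    else:
        table = read_studies(source)
    if models is None:
        selected_models = ALL_MODELS
    else:
        selected_models = tuple(
            m if isinstance(m, GeneticModel) else GeneticModel.parse(m) for m in models
        )

    hwe_all = tuple((s.study_id, hwe_chi_square(s.controls)) for s in table)
    retained, excluded = hwe_filter(table, alpha=hwe_alpha)

    sections = []
    for model in selected_models:
        warnings: list[str] = []
        overall = run_model(retained, model, method, ci_level)
        sub = None
        if subgroup_key:
            sub = subgroup_analysis(retained, subgroup_key, model, method, ci_level)
        sens = None
        if len(retained) >= 2:
            sens = leave_one_out(retained, model, method, ci_level)
        else:
            warnings.append("sensitivity analysis skipped: fewer than 2 studies")
        egger = begg = None
        try:
            egger = egger_test(overall.effects)
        except DegenerateAnalysisError as exc:
            warnings.append(f"Egger test unavailable: {exc}")
        try:
            begg = begg_test(overall.effects)
        except DegenerateAnalysisError as exc:
            warnings.append(f"Begg test unavailable: {exc}")
        funnel = funnel_data(overall.effects, overall.pooled)
        sections.append(
            ModelSection(
                model=model,
                overall=overall,
                subgroup=sub,
                sensitivity=sens,
                egger=egger,
                begg=begg,
                funnel=funnel,
                warnings=tuple(warnings),
            )
        )
    return Report(
        provenance=table.provenance,
        options={
            "models": [m.value for m in selected_models],
            "subgroup_key": subgroup_key,
            "hwe_alpha": hwe_alpha,
            "method": method,
            "ci_level": ci_level,
        },
        version=__version__,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        n_studies=len(table),
        total_cases=table.total_cases,
        total_controls=table.total_controls,
        hwe=hwe_all,
        hwe_alpha=hwe_alpha,
        excluded=tuple(excluded),
        sections=tuple(sections),
    )


def _model_label(model: GeneticModel) -> str:
    return model.value.capitalize() + " model"


def render_text(report: Report) -> str:
    """Human-readable tables mirroring the report's machine content."""
    lines: list[str] = []
    lines.append(f"snpmeta {report.version} — {report.provenance}")
    lines.append(
        f"{report.n_studies} studies, {report.total_cases} cases / "
        f"{report.total_controls} controls"
    )
    lines.append("")
    lines.append(f"HWE screen (controls, chi-square 1 df, exclude p < "
                 f"{report.hwe_alpha:g}):")
    for sid, res in report.hwe:
        status = "excluded" if any(e[0] == sid for e in report.excluded) else "retained"
        lines.append(f"  {sid:<18s} q={res.q:.4f}  chi2={res.chi2:.3f}  "
                     f"p={fmt_p(res.p)}  [{status}]")
    lines.append("")

    header = (f"{'Genetic model':<20s} {'Het p':>6s} {'I2(%)':>6s} "
              f"{'Model':>6s} {'OR (95% CI)':>20s} {'P':>6s}")
    lines.append("Overall analysis:")
    lines.append(header)
    for sec in report.sections:
        pooled = sec.overall.pooled
        tag = "R" if sec.overall.selected is PoolingMethod.RANDOM_DL else "F"
        lines.append(
            f"{_model_label(sec.model):<20s} {fmt_p(pooled.p_q):>6s} "
            f"{fmt_i2(pooled.i2):>6s} {tag:>6s} {_fmt_or_ci(pooled):>20s} "
            f"{fmt_p(pooled.p):>6s}"
        )
    lines.append("")

    if any(sec.subgroup for sec in report.sections):
        lines.append("Subgroup analysis:")
        lines.append(f"{'Genetic model':<20s} {'Subgroup':<12s} {'Het p':>6s} "
                     f"{'I2(%)':>6s} {'Model':>6s} {'OR (95% CI)':>20s} {'P':>6s}")
        for sec in report.sections:
            if sec.subgroup is None:
                continue
            for label, res in sec.subgroup.groups:
                pooled = res.pooled
                tag = "R" if res.selected is PoolingMethod.RANDOM_DL else "F"
                lines.append(
                    f"{_model_label(sec.model):<20s} {label:<12s} "
                    f"{fmt_p(pooled.p_q):>6s} {fmt_i2(pooled.i2):>6s} {tag:>6s} "
                    f"{_fmt_or_ci(pooled):>20s} {fmt_p(pooled.p):>6s}"
                )
        lines.append("")

    if any(sec.sensitivity for sec in report.sections):
        lines.append("Leave-one-out sensitivity (pooled OR with study omitted):")
        for sec in report.sections:
            if sec.sensitivity is None:
                continue
            for sid, res in sec.sensitivity.omitted:
                lines.append(
                    f"  {_model_label(sec.model):<20s} omit {sid:<18s} "
                    f"{_fmt_or_ci(res.pooled)}"
                )
        lines.append("")

    lines.append("Publication bias:")
    for sec in report.sections:
        egger = f"Egger p={fmt_p(sec.egger.p)}" if sec.egger else "Egger n/a"
        begg = f"Begg p={fmt_p(sec.begg.p)}" if sec.begg else "Begg n/a"
        lines.append(f"  {_model_label(sec.model):<20s} {egger:<16s} {begg}")
    for sec in report.sections:
        for w in sec.warnings:
            lines.append(f"  warning [{sec.model.value}]: {w}")
    return "\n".join(lines) + "\n"
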
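"""Synthetic multi-study case-control genotype data with known truth.

The generator emulates the structure of a small SNP meta-analysis: k
case-control studies of a biallelic marker, each with its own sample sizes
and control mutant-allele frequency. Controls are drawn from exact
Hardy-Weinberg genotype proportions at frequency q; cases are drawn from
those proportions tilted multiplicatively by psi^g for g in {0, 1, 2}
copies of the mutant allele and renormalized — the log-additive
(per-allele) risk model, under which the allele-model odds ratio targets
psi. Between-study heterogeneity enters as study-specific log odds ratios
ln(psi_i) ~ Normal(ln psi, tau^2).

Genotype counts are drawn jointly (multinomial per arm), not allele-wise,
so cases can and do depart from HWE when psi != 1, as biology implies under
association. Each study gets its own deterministic substream spawned from
the global seed, so adding a study never perturbs earlier studies' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dataset import GenotypeCounts, Study, StudyTable
from .errors import ValidationError
from .models import GeneticModel
from .pooling import run_model

__all__ = ["SimConfig", "RecoverySummary", "simulate_studies", "recover_parameters"]


def _per_study(value, k: int, name: str) -> list:
    """Broadcast a scalar or validate a length-k sequence."""
    if np.isscalar(value):
        return [value] * k
    values = list(value)
    if len(values) != k:
        raise ValidationError(f"{name} must be scalar or length {k}, got {len(values)}")
    return values


@dataclass(frozen=True)
class SimConfig:
    """Configuration for the study-table generator.

    Defaults mirror the glioma application's scale: four studies with
    per-arm sizes spanning the published range, control mutant-allele
    frequencies around 0.15, a modest per-allele odds ratio of 1.3, and no
    between-study heterogeneity.
    """

    k: int = 4
    n_cases: int | Sequence[int] = (205, 157, 756, 477)
    n_controls: int | Sequence[int] = (205, 160, 815, 477)
    q: float | Sequence[float] = 0.15
    psi: float = 1.3
    tau: float = 0.0
    seed: int = 0
    subgroups: Sequence[str] | None = None  # per-study labels, optional

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        for name in ("n_cases", "n_controls"):
            for v in _per_study(getattr(self, name), self.k, name):
                if int(v) != v or v < 1:
                    raise ValidationError(f"{name} entries must be integers >= 1")
        for qi in _per_study(self.q, self.k, "q"):
            if not (0.0 < qi < 1.0):
                raise ValidationError(f"q must lie strictly in (0, 1), got {qi}")
        if self.psi <= 0:
            raise ValidationError("psi must be > 0")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if self.subgroups is not None and len(self.subgroups) != self.k:
            raise ValidationError("subgroups must have one label per study")


def _genotype_probs(q: float, psi_i: float) -> tuple[np.ndarray, np.ndarray]:
    """(control, case) genotype probabilities (CC, CT, TT)."""
    control = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    tilt = np.array([1.0, psi_i, psi_i**2])
    case = control * tilt
    return control, case / case.sum()


def simulate_studies(cfg: SimConfig) -> StudyTable:
    """Draw a StudyTable under the configured truth; fully reproducible."""
    n_cases = [int(v) for v in _per_study(cfg.n_cases, cfg.k, "n_cases")]
    n_controls = [int(v) for v in _per_study(cfg.n_controls, cfg.k, "n_controls")]
    qs = [float(v) for v in _per_study(cfg.q, cfg.k, "q")]
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.k)
    studies = []
    for i in range(cfg.k):
        rng = np.random.default_rng(streams[i])
        log_psi_i = rng.normal(math.log(cfg.psi), cfg.tau)
        control_p, case_p = _genotype_probs(qs[i], math.exp(log_psi_i))
        control_counts = rng.multinomial(n_controls[i], control_p)
        case_counts = rng.multinomial(n_cases[i], case_p)
        studies.append(
            Study(
                study_id=f"sim{i + 1:03d}",
                author=f"Synthetic{i + 1}",
                year=2000 + i,
                subgroup=cfg.subgroups[i] if cfg.subgroups else "simulated",
                design="simulated",
                cases=GenotypeCounts(*(int(c) for c in case_counts)),
                controls=GenotypeCounts(*(int(c) for c in control_counts)),
            )
        )
    return StudyTable(
        studies=tuple(studies),
        provenance=f"simulated(seed={cfg.seed}, psi={cfg.psi}, tau={cfg.tau})",
    )


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo summary of estimator behaviour over repeated datasets."""

    n_reps: int
    model: GeneticModel
    true_log_or: float
    mean_log_or: float
    ci_coverage: float  # fraction of CIs containing the true log OR
    mean_tau2: float
    q_rejection_rate: float  # Q-test p < 0.10
    effect_rejection_rate: float  # pooled Wald p < alpha
    alpha: float
    rep_seeds: tuple[int, ...] = field(repr=False, default=())
    tau2_by_rep: tuple[float, ...] = field(repr=False, default=())
    log_or_by_rep: tuple[float, ...] = field(repr=False, default=())


def rep_seeds(seed: int, n_reps: int) -> tuple[int, ...]:
    """Deterministic per-replicate seeds derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint32)
    return tuple(int(s) % (2**31) for s in state)


def recover_parameters(
    cfg: SimConfig,
    n_reps: int,
    model: GeneticModel = GeneticModel.ALLELE,
    method: str = "random",
    alpha: float = 0.05,
) -> RecoverySummary:
    """Repeated simulate-then-analyze: bias, coverage, and rejection rates.

    Each replicate draws a fresh StudyTable (seeds derived deterministically
    from ``cfg.seed``), runs the full pipeline for ``model``, and records
    the pooled log OR, whether its CI covers the truth, the DL tau^2, the
    Q-test outcome at the 0.10 gate, and the pooled Wald test outcome at
    ``alpha``.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    seeds = rep_seeds(cfg.seed, n_reps)
    truth = math.log(cfg.psi)
    log_ors, tau2s = [], []
    covered = q_reject = effect_reject = 0
    for s in seeds:
        table = simulate_studies(replace(cfg, seed=s))
        result = run_model(table, model, method=method)
        pooled = result.pooled
        log_ors.append(pooled.log_or)
        tau2s.append(result.random.tau2)
        if math.log(pooled.ci_low) <= truth <= math.log(pooled.ci_high):
            covered += 1
        if pooled.p_q is not None and pooled.p_q < 0.10:
            q_reject += 1
        if pooled.p < alpha:
            effect_reject += 1
    return RecoverySummary(
        n_reps=n_reps,
        model=model,
        true_log_or=truth,
        mean_log_or=float(np.mean(log_ors)),
        ci_coverage=covered / n_reps,
        mean_tau2=float(np.mean(tau2s)),
        q_rejection_rate=q_reject / n_reps,
        effect_rejection_rate=effect_reject / n_reps,
        alpha=alpha,
        rep_seeds=seeds,
        tau2_by_rep=tuple(tau2s),
        log_or_by_rep=tuple(log_ors),
    )
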
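"""Genetic inheritance models: mapping genotype counts to 2x2 exposure tables.

Five standard comparisons are supported for a biallelic SNP with wild-type
allele C and mutant allele T:

========== ===========================================
allele     T vs C (each individual contributes 2 alleles)
dominant   TT + CT vs CC
recessive  TT vs CT + CC
heterozygote  CT vs CC (TT individuals excluded)
homozygote    TT vs CC (CT individuals excluded)
========== ===========================================

Each model reduces case and control genotype counts to a single 2x2
exposed/unexposed x case/control contingency table on which an odds ratio
is defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .dataset import GenotypeCounts
from .errors import DegenerateTableError, ValidationError

__all__ = ["GeneticModel", "TwoByTwo", "derive_2x2", "allele_frequency"]


class GeneticModel(str, Enum):
    ALLELE = "allele"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    HETEROZYGOTE = "heterozygote"
    HOMOZYGOTE = "homozygote"

    @classmethod
    def parse(cls, name: str) -> "GeneticModel":
        try:
            return cls(name.strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValidationError(
                f"unknown genetic model {name!r}; expected one of: {valid}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TwoByTwo:
    """Exposed/unexposed x case/control table.

    ``a`` exposed cases, ``b`` unexposed cases, ``c`` exposed controls,
    ``d`` unexposed controls. Cells are reals so a continuity correction
    (+0.5) can be represented.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValidationError(f"2x2 cell {name!r} must be non-negative")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def corrected(self, delta: float = 0.5) -> "TwoByTwo":
        """Haldane-Anscombe correction: add ``delta`` to every cell."""
        return TwoByTwo(self.a + delta, self.b + delta, self.c + delta, self.d + delta)

    def swap_groups(self) -> "TwoByTwo":
        """Exchange the case and control rows."""
        return TwoByTwo(self.c, self.d, self.a, self.b)

    def swap_exposure(self) -> "TwoByTwo":
        """Exchange the exposed and unexposed columns."""
        return TwoByTwo(self.b, self.a, self.d, self.c)


def _cells(g: GenotypeCounts, model: GeneticModel) -> tuple[float, float]:
    """(exposed, unexposed) for one group under the model."""
    if model is GeneticModel.ALLELE:
        return g.ct + 2 * g.tt, 2 * g.cc + g.ct
    if model is GeneticModel.DOMINANT:
        return g.tt + g.ct, g.cc
    if model is GeneticModel.RECESSIVE:
        return g.tt, g.ct + g.cc
    if model is GeneticModel.HETEROZYGOTE:
        return g.ct, g.cc
    if model is GeneticModel.HOMOZYGOTE:
        return g.tt, g.cc
    raise AssertionError(model)


def derive_2x2(
    cases: GenotypeCounts, controls: GenotypeCounts, model: GeneticModel
) -> TwoByTwo:
    """Build the 2x2 contingency table for a study under a genetic model.

    Under the heterozygote and homozygote models individuals with the
    excluded genotype simply drop out of the table (that is what "CT vs CC"
    means); under the allele model each individual contributes two alleles.

    Raises
    ------
    DegenerateTableError
        If either the case or the control margin of the derived table is
        zero (no informative individuals/alleles in that group).
    """
    a, b = _cells(cases, model)
    c, d = _cells(controls, model)
    if a + b == 0 or c + d == 0:
        raise DegenerateTableError(
            f"{model.value} model: a group contributes no informative "
            f"observations (case margin {a + b}, control margin {c + d})"
        )
    return TwoByTwo(a, b, c, d)


def allele_frequency(g: GenotypeCounts) -> float:
    """Sample frequency of the mutant allele T: (ct + 2*tt) / (2*n)."""
    if g.n < 1:
        raise ValidationError("allele frequency undefined for an empty group")
    return (g.ct + 2 * g.tt) / (2 * g.n)
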
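"""Study-level genotype-count data: types, I/O, and the built-in glioma fixture.

The unit of input is one case-control study of a biallelic SNP, summarised
as genotype counts (CC / CT / TT, with C the wild-type and T the mutant
allele) in cases and controls, plus study metadata. A :class:`StudyTable`
is an ordered collection of such studies; order is preserved from the input
file because it determines reporting order.

The four VEGFR2 rs2305948 / glioma case-control studies (Vasconcelos 2019,
Gao 2016, Chen 2012, Zhang 2016; 1595 cases, 1657 controls) ship with the
package and are returned by :func:`builtin_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import ConsistencyError, SchemaError, ValidationError

__all__ = [
    "GenotypeCounts",
    "Study",
    "StudyTable",
    "read_studies",
    "write_studies",
    "builtin_fixture",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
]

REQUIRED_COLUMNS = (
    "study_id",
    "author",
    "year",
    "subgroup",
    "case_cc",
    "case_ct",
    "case_tt",
    "control_cc",
    "control_ct",
    "control_tt",
)
OPTIONAL_COLUMNS = ("design", "quality_score", "case_n", "control_n")

_COUNT_FIELDS = (
    "case_cc",
    "case_ct",
    "case_tt",
    "control_cc",
    "control_ct",
    "control_tt",
)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one group (cases or controls) of one study.

    Attributes
    ----------
    cc : int
        Wild-type homozygotes.
    ct : int
        Heterozygotes.
    tt : int
        Mutant homozygotes.
    """

    cc: int
    ct: int
    tt: int

    def __post_init__(self) -> None:
        for name in ("cc", "ct", "tt"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, int):
                raise ValidationError(
                    f"genotype count {name!r} must be an integer, got {v!r}"
                )
            if v < 0:
                raise ValidationError(
                    f"genotype count {name!r} must be non-negative, got {v}"
                )

    @property
    def n(self) -> int:
        """Number of individuals in the group."""
        return self.cc + self.ct + self.tt

    def swapped_alleles(self) -> "GenotypeCounts":
        """Relabel C<->T (swap the two homozygote counts)."""
        return GenotypeCounts(cc=self.tt, ct=self.ct, tt=self.cc)


@dataclass(frozen=True)
class Study:
    """One case-control study: metadata plus case and control genotype counts."""

    study_id: str
    author: str
    year: int
    subgroup: str
    cases: GenotypeCounts
    controls: GenotypeCounts
    design: str | None = None
    quality_score: int | None = None

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be a non-empty string")
        if self.cases.n < 1:
            raise ConsistencyError(
                f"study {self.study_id!r}: case group has zero individuals"
            )
        if self.controls.n < 1:
            raise ConsistencyError(
                f"study {self.study_id!r}: control group has zero individuals"
            )

    @property
    def subgroup_key(self) -> str:
        """Normalized subgroup label for case-insensitive grouping."""
        return self.subgroup.strip().casefold()


@dataclass(frozen=True)
class StudyTable:
    """Ordered collection of studies; input row order is preserved."""

    studies: tuple[Study, ...]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate study_id values: {sorted(dupes)}")
        object.__setattr__(self, "studies", tuple(self.studies))

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[Study]:
        return iter(self.studies)

    def __getitem__(self, study_id: str) -> Study:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(s.study_id for s in self.studies)

    @property
    def total_cases(self) -> int:
        return sum(s.cases.n for s in self.studies)

    @property
    def total_controls(self) -> int:
        return sum(s.controls.n for s in self.studies)

    def subset(self, study_ids: Iterable[str], provenance: str | None = None) -> "StudyTable":
        """Restrict to the given ids, keeping this table's order."""
        wanted = set(study_ids)
        missing = wanted - set(self.study_ids)
        if missing:
            raise KeyError(f"unknown study ids: {sorted(missing)}")
        return StudyTable(
            studies=tuple(s for s in self.studies if s.study_id in wanted),
            provenance=provenance or self.provenance,
        )

    def drop(self, study_id: str) -> "StudyTable":
        if study_id not in self.study_ids:
            raise KeyError(study_id)
        return StudyTable(
            studies=tuple(s for s in self.studies if s.study_id != study_id),
            provenance=f"{self.provenance} minus {study_id}",
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.studies:
            rows.append(
                {
                    "study_id": s.study_id,
                    "author": s.author,
                    "year": s.year,
                    "subgroup": s.subgroup,
                    "design": s.design,
                    "quality_score": s.quality_score,
                    "case_n": s.cases.n,
                    "control_n": s.controls.n,
                    "case_cc": s.cases.cc,
                    "case_ct": s.cases.ct,
                    "case_tt": s.cases.tt,
                    "control_cc": s.controls.cc,
                    "control_ct": s.controls.ct,
                    "control_tt": s.controls.tt,
                }
            )
        return pd.DataFrame(rows)


def _coerce_count(value, study_id: str, column: str) -> int:
    """Integer-coerce a count cell, rejecting negatives and true floats."""
    if pd.isna(value):
        raise ValidationError(f"study {study_id!r}: missing value in {column!r}")
    f = float(value)
    if f != int(f):
        raise ValidationError(
            f"study {study_id!r}: {column!r} must be an integer count, got {value!r}"
        )
    i = int(f)
    if i < 0:
        raise ValidationError(
            f"study {study_id!r}: {column!r} must be non-negative, got {i}"
        )
    return i


def _row_to_study(row: pd.Series) -> Study:
    study_id = str(row["study_id"]).strip()
    counts = {c: _coerce_count(row[c], study_id, c) for c in _COUNT_FIELDS}
    cases = GenotypeCounts(counts["case_cc"], counts["case_ct"], counts["case_tt"])
    controls = GenotypeCounts(
        counts["control_cc"], counts["control_ct"], counts["control_tt"]
    )
    for declared_col, group, got in (
        ("case_n", "case", cases.n),
        ("control_n", "control", controls.n),
    ):
        if declared_col in row.index and not pd.isna(row[declared_col]):
            declared = _coerce_count(row[declared_col], study_id, declared_col)
            if declared != got:
                raise ConsistencyError(
                    f"study {study_id!r}: declared {group} n = {declared} but "
                    f"genotype counts sum to {got}"
                )
    design = None
    if "design" in row.index and not pd.isna(row["design"]):
        design = str(row["design"]).strip()
    quality = None
    if "quality_score" in row.index and not pd.isna(row["quality_score"]):
        quality = _coerce_count(row["quality_score"], study_id, "quality_score")
    return Study(
        study_id=study_id,
        author=str(row["author"]).strip(),
        year=_coerce_count(row["year"], study_id, "year"),
        subgroup=str(row["subgroup"]).strip(),
        design=design,
        quality_score=quality,
        cases=cases,
        controls=controls,
    )


def read_studies(path: str | Path, sep: str | None = None) -> StudyTable:
    """Read a delimited studies file (comma default, tab accepted).

    The header must name the required columns
    ``study_id, author, year, subgroup, case_cc, case_ct, case_tt,
    control_cc, control_ct, control_tt``; ``design``, ``quality_score``,
    ``case_n`` and ``control_n`` are optional. Row order is preserved.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        For a negative or non-integer count, naming the study and field.
    ConsistencyError
        If a declared group size disagrees with the genotype sum.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    studies = tuple(_row_to_study(row) for _, row in df.iterrows())
    return StudyTable(studies=studies, provenance=str(path))


def write_studies(table: StudyTable, path: str | Path, sep: str | None = None) -> None:
    """Write a StudyTable back to delimited text in the read_studies schema."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.to_dataframe().to_csv(path, sep=sep, index=False)


def builtin_fixture() -> StudyTable:
    """The four rs2305948/glioma case-control studies shipped with the package.

    Returns the published genotype counts for Vasconcelos 2019 (Non-Asian),
    Gao 2016, Chen 2012 and Zhang 2016 (Asian): 1595 cases and 1657 controls
    in total.
    """
    ref = resources.files("snpmeta").joinpath("data/rs2305948_glioma.csv")
    with resources.as_file(ref) as p:
        table = read_studies(p)
    return replace(table, provenance="fixture:rs2305948_glioma")
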
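import pytest

from snpmeta import GenotypeCounts, Study, StudyTable, builtin_fixture


@pytest.fixture(scope="session")
def glioma() -> StudyTable:
    """The built-in four-study rs2305948/glioma table."""
    return builtin_fixture()


@pytest.fixture()
def two_studies() -> StudyTable:
    """A minimal synthetic two-study table for structural tests."""
    return StudyTable(
        studies=(
            Study(
                study_id="s1",
                author="A",
                year=2001,
                subgroup="east",
                cases=GenotypeCounts(50, 40, 10),
                controls=GenotypeCounts(60, 32, 8),
            ),
            Study(
                study_id="s2",
                author="B",
                year=2002,
                subgroup="west",
                cases=GenotypeCounts(70, 25, 5),
                controls=GenotypeCounts(65, 30, 5),
            ),
        ),
        provenance="synthetic",
    )
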
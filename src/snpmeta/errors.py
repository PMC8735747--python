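"""Exception hierarchy for snpmeta.

All package errors derive from :class:`SnpMetaError` so callers can catch
one base class. Validation-type errors (bad input data) are distinguished
from degenerate-analysis errors (data that is structurally fine but cannot
support the requested computation), which matters for CLI exit codes.
"""


class SnpMetaError(Exception):
    """Base class for all snpmeta errors."""


class SchemaError(SnpMetaError):
    """Input file is missing a required column or has an unusable header."""


class ValidationError(SnpMetaError):
    """A field value violates an invariant (e.g. negative genotype count)."""


class ConsistencyError(SnpMetaError):
    """Internally inconsistent input (declared n != genotype sum, empty group)."""


class DegenerateAnalysisError(SnpMetaError):
    """Data cannot support the requested computation."""


class DegenerateTableError(DegenerateAnalysisError):
    """A derived 2x2 table has an empty margin (no informative individuals)."""


class MonomorphicMarkerError(DegenerateAnalysisError):
    """All observed alleles identical; HWE test undefined."""


class InsufficientStudiesError(DegenerateAnalysisError):
    """Fewer studies than the statistic requires (Q needs 2, Egger needs 3)."""


class DegenerateDesignError(DegenerateAnalysisError):
    """Regression design is singular (e.g. all precisions equal in Egger's test)."""
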
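"""Exception hierarchy for the ntcpselect pipeline.

All errors derive from :class:`NTCPSelectError` so callers (and the CLI) can
map them to coarse categories: input/format problems, model/configuration
problems, and internal invariant violations.
"""


class NTCPSelectError(Exception):
    """Base class for all package errors."""


# ---------------------------------------------------------------- DVH errors
class DVHError(NTCPSelectError, ValueError):
    """A dose-volume histogram violates its invariants."""


class NonMonotoneVolume(DVHError):
    """Cumulative volume increases somewhere along the dose axis."""


class BadOrigin(DVHError):
    """Curve does not start at (dose 0, volume fraction 1)."""


class LengthMismatch(DVHError):
    """dose_edges and cum_volume have different lengths (or length < 2)."""


class NegativeBin(DVHError):
    """A differential DVH bin has negative volume fraction."""


class DomainError(NTCPSelectError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ZeroDoseWithNegativeExponent(DomainError):
    """gEUD with a < 0 is undefined when a bin receives exactly zero dose."""


# --------------------------------------------------------------- NTCP errors
class ModelError(NTCPSelectError):
    """Problems with an NTCP model specification or its evaluation."""


class MissingCovariate(ModelError, KeyError):
    """A covariate required by a model term is absent."""


class MissingStructure(ModelError, KeyError):
    """A structure required by a dose covariate has no DVH in the plan."""


class UnknownModel(ModelError, KeyError):
    """A comparison references a model name absent from the registry."""


class SchemaError(ModelError, ValueError):
    """A registry file does not conform to the NTCPModelSpec schema."""


class DuplicateModelName(SchemaError):
    """Two registry entries share a name."""


# ------------------------------------------------------------ cohort errors
class CohortError(NTCPSelectError, ValueError):
    """Problems with cohort-level inputs."""


class DuplicatePatient(CohortError):
    """Two qualification results share a patient_id."""


class EmptyCohort(CohortError):
    """An operation that needs at least one patient received none."""


class AllZeroDifferences(CohortError):
    """Every paired difference is zero; the signed-rank test is undefined."""


# ----------------------------------------------------------------- IO errors
class FormatError(NTCPSelectError, ValueError):
    """An on-disk artifact does not match its declared format."""


class HeaderMismatch(FormatError):
    """A CSV file's header differs from the canonical one."""


class ParseError(FormatError):
    """A row could not be parsed; the message carries the line number."""
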
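"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`HepaprotError` so the CLI can abort
with a stage-tagged message instead of a bare traceback.
"""


class HepaprotError(Exception):
    """Base class for all package errors."""


class FormatError(HepaprotError):
    """A delimited input file violates the expected dialect."""


class ConsistencyError(HepaprotError):
    """Cross-references between tables (runs, channels, samples) do not line up."""


class ConfigurationError(HepaprotError):
    """A configuration object violates its invariants."""


class InvalidDataError(HepaprotError):
    """Data values violate a stage precondition (e.g. missing values, non-positive means)."""


class DegenerateInputError(HepaprotError):
    """Input carries no usable signal (e.g. an all-constant matrix)."""


class OntologyError(HepaprotError):
    """The term graph is not a rooted acyclic is_a DAG."""


class AnnotationError(HepaprotError):
    """Protein annotations reference unknown terms."""


class UndefinedTestError(HepaprotError):
    """A statistical test is undefined for the given partition (e.g. empty complement)."""


class NotFoundError(HepaprotError):
    """No protein satisfies the requested constraints."""
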
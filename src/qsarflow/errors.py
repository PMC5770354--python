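"""Exception hierarchy for the pipeline.

Every stage failure maps onto one of these so the orchestrator can report
the failing stage and the CLI can translate them into exit codes.
"""


class QsarflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QsarflowError):
    """Invalid user configuration (missing column, unknown option, bad spec)."""


class InputError(QsarflowError):
    """Unreadable or malformed input file / payload."""


class NotFoundError(InputError):
    """A requested resource (accession, fixture) does not exist."""


class EmptyDatasetError(QsarflowError):
    """No records survive a stage; the pipeline cannot proceed."""


class AlignmentError(QsarflowError):
    """Row or column identities do not line up between two tables."""


class TooSmallError(QsarflowError):
    """Dataset too small for the requested operation."""


class DomainError(QsarflowError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InternalConsistencyError(QsarflowError):
    """An invariant that an upstream stage should have guaranteed is violated."""


class UndefinedModelabilityError(QsarflowError):
    """Modelability cannot be computed (e.g. constant activities)."""
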
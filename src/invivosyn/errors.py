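"""Exception hierarchy.

All package-specific failures derive from :class:`InvivoSynError` so that
callers (and the CLI) can distinguish bad input from genuine bugs.
"""


class InvivoSynError(Exception):
    """Base class for all invivosyn errors."""


class SchemaError(InvivoSynError):
    """Input table does not match the expected schema (missing column,
    unmappable group label, ...)."""


class ConsistencyError(InvivoSynError):
    """Internally contradictory input: a mouse in two groups, duplicated
    (mouse, day) measurements, non-monotone days."""


class StudyStructureError(InvivoSynError):
    """Dataset lacks the structure required for a 4-group synergy analysis
    (a treatment arm absent or without analyzable curves)."""


class DomainError(InvivoSynError):
    """Value outside the mathematical domain of an operation (non-positive
    volume, zero duration, t_eval <= 0, TGI >= 1)."""


class NotAnalyzableError(DomainError):
    """Curve cannot enter the growth-rate calculation (fewer than two
    measurements)."""


class NotComputableError(InvivoSynError):
    """A single-day baseline quantity cannot be computed because a group has
    no measurement at the requested day."""


class ConfigError(InvivoSynError):
    """Invalid scenario or analysis configuration."""
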
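"""Exception hierarchy for the encounterdq pipeline.

Every error a caller may want to branch on derives from
:class:`EncounterDQError`; the CLI maps subclasses to exit codes.
"""


class EncounterDQError(Exception):
    """Base class for all package errors."""


class SchemaError(EncounterDQError):
    """A dataset is structurally unusable (e.g. a required column is absent)."""


class RowParseError(EncounterDQError):
    """A row could not be parsed (strict mode); carries the offending row index."""

    def __init__(self, row: int, message: str) -> None:
        self.row = row
        super().__init__(f"row {row}: {message}")


class ConfigurationError(EncounterDQError):
    """An option or configuration value is invalid; names the offending field."""


class InsufficientDataError(EncounterDQError):
    """Not enough observations for the requested computation."""


class DegenerateVarianceError(EncounterDQError):
    """Paired differences have zero variance; t and d are undefined."""


class InsufficientPairsError(InsufficientDataError):
    """Fewer than two users have records in both comparison windows."""
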
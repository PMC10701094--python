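"""Exception hierarchy shared across the toolkit.

All toolkit errors derive from :class:`ChimeraKitError` so callers can catch
one base class; parse-level errors carry enough location information
(line number, record index, finding code) to be surfaced in QC reports.
"""

from __future__ import annotations


class ChimeraKitError(Exception):
    """Base class for all toolkit errors."""


class FlagFormatError(ChimeraKitError, ValueError):
    """A flag key or value contains a forbidden character."""


class FlagPolicyError(ChimeraKitError, ValueError):
    """An unrecognized flag key was set while allow_undefined was false."""


class MalformedFlagError(ChimeraKitError, ValueError):
    """A flag value is present but does not satisfy its contract."""


class NotApplicableError(ChimeraKitError, ValueError):
    """An operation's precondition on record annotation state is unmet."""


class HybParseError(ChimeraKitError, ValueError):
    """A hyb-format line failed to parse.

    Attributes
    ----------
    line_number : int or None
        1-based line number within the source, when known.
    code : str
        Machine-readable finding code (``field-count``, ``numeric-parse``,
        ``coordinate-order``, ``span-exceeds-seq``, ``empty-field``, ...).
    """

    def __init__(self, message: str, line_number: int | None = None,
                 code: str = "parse"):
        self.line_number = line_number
        self.code = code
        prefix = f"line {line_number}: " if line_number is not None else ""
        super().__init__(f"{prefix}{message}")


class SerializationError(ChimeraKitError, ValueError):
    """A record violating its invariants was refused serialization."""


class ViennaParseError(ChimeraKitError, ValueError):
    """A Vienna dot-bracket record failed to parse."""

    def __init__(self, message: str, record_index: int | None = None):
        self.record_index = record_index
        prefix = f"record {record_index}: " if record_index is not None else ""
        super().__init__(f"{prefix}{message}")


class MergeError(ChimeraKitError, RuntimeError):
    """Concurrent hyb/fold iteration failed (mismatch or stream imbalance)."""


class EvaluationError(ChimeraKitError, ValueError):
    """A segment identifier could not be classified under strict policy."""


class ConfigurationError(ChimeraKitError, ValueError):
    """A rule file, id-map, mixture, or run configuration is invalid."""
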
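"""Exception hierarchy and lint-style issue records."""

from __future__ import annotations

from dataclasses import dataclass


class HedError(Exception):
    """Base class for all hedlite errors."""


class SchemaError(HedError):
    """The vocabulary schema is structurally invalid."""


class SchemaParseError(SchemaError):
    """A schema document could not be parsed.

    Carries the 1-based line number of the offending entry when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateNodeError(SchemaError):
    """Two schema nodes share a (case-insensitive) name."""


class UnknownTagError(HedError):
    """A tag name does not resolve in the schema."""


class HedStringParseError(HedError):
    """An annotation string is malformed (parens, empty groups, bad tags)."""


class DefinitionError(HedError):
    """A definition is malformed, conflicting, or unresolvable."""


class ConfigError(HedError):
    """A user-supplied configuration (trial spec, session spec) is invalid."""


class FormatError(HedError):
    """An input file violates its required tabular/JSON format."""


@dataclass(frozen=True)
class Issue:
    """A non-fatal validation finding.

    code: stable machine-readable identifier (e.g. ``unmatched-offset``)
    message: human-readable explanation
    file: originating file path, when applicable
    line: 1-based data-row number within that file, when applicable
    """

    code: str
    message: str
    file: str | None = None
    line: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = ""
        if self.file:
            loc = f"{self.file}:"
            if self.line is not None:
                loc += f"{self.line}:"
            loc += " "
        return f"{loc}[{self.code}] {self.message}"
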
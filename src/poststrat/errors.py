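"""Structured exceptions shared across the package.

Every user-facing failure mode maps to one of these; the CLI translates them
into exit code 1 with the message on stderr.
"""

from __future__ import annotations


class PoststratError(Exception):
    """Base class for all package errors."""


class SchemaError(PoststratError):
    """A declared column is missing or a schema is self-inconsistent."""


class ValidationError(PoststratError):
    """Input data violates a contract (missing value, duplicate cell, ...)."""


class PositivityError(PoststratError):
    """A covariate cell required by the estimand has no empirical support.

    Carries the offending cell keys so callers can report them.
    """

    def __init__(self, message: str, cells: list[tuple[str, ...]] | None = None):
        super().__init__(message)
        self.cells = list(cells or [])


class ConfigError(PoststratError):
    """A simulation or run configuration is invalid (probabilities out of
    range, proportions not summing to one, ...)."""
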
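"""Exception hierarchy.

Every error raised by this package derives from :class:`MwctError` and
carries a short machine-readable ``category`` used by the CLI for
diagnostics and exit codes.
"""

from __future__ import annotations


class MwctError(Exception):
    """Base class for all package errors."""

    category = "error"


class StructuralInputError(MwctError):
    """Malformed in-memory input: unequal trace lengths, empty traces, ..."""

    category = "structural-input"


class ConstraintViolationError(MwctError):
    """A weight tern violates the open-simplex constraints."""

    category = "constraint-violation"


class ParameterError(MwctError):
    """An operation parameter is out of its admissible range."""

    category = "parameter"


class ConfigError(ParameterError):
    """Invalid optimizer or CLI configuration."""

    category = "config"


class FormatError(MwctError):
    """A file does not conform to the expected dialect."""

    category = "format"


class SamplingError(FormatError):
    """Time axis of a recording file is not strictly uniform."""

    category = "sampling"


class DegenerateReferenceError(MwctError):
    """The lead II reference has zero excursion; percentages are undefined."""

    category = "degenerate-reference"


class GeometryError(MwctError):
    """Degenerate lead-vector geometry in the synthetic generator."""

    category = "geometry"
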
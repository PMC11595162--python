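"""Exception hierarchy with stable exit-code semantics.

Contract errors (bad arguments, mismatched schemas) map to exit code 2 in
the CLI; content errors (well-formed input whose content cannot be
processed, e.g. an empty pocket) map to exit code 3.
"""


class PoseTriageError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ContractError(PoseTriageError):
    """An API contract was violated (wrong types, mismatched names, bad config)."""

    exit_code = 2


class ContentError(PoseTriageError):
    """Input is syntactically valid but its content cannot be processed."""

    exit_code = 3


class ParseError(ContentError):
    """A file could not be parsed under its declared format."""


class StructureError(ContentError):
    """A molecular structure is chemically inconsistent (valence, connectivity)."""


class NumericError(PoseTriageError):
    """A numeric computation hit a degenerate configuration."""

    exit_code = 1
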
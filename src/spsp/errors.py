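"""Exception hierarchy shared by all spsp modules.

Every error raised by the library derives from :class:`SpspError`.  The
``exit_code`` attribute is what the CLI returns when the error escapes to
the top level: 2 for usage/configuration problems, 3 for data or protocol
problems.
"""


class SpspError(Exception):
    """Base class for all library errors."""

    exit_code = 3


class ConfigError(SpspError):
    """Invalid run configuration or synthetic-spec field."""

    exit_code = 2


class DataIOError(SpspError):
    """File could not be read or written."""


class FormatError(DataIOError):
    """Structurally malformed input file (e.g. ragged rows)."""


class ParseError(FormatError):
    """A cell could not be parsed as a number; message names the cell."""


class ConsistencyError(SpspError):
    """File contents disagree with manifest metadata."""


class ManifestError(SpspError):
    """Invalid dataset manifest (duplicates, missing fields)."""


class DomainError(SpspError):
    """Operation preconditions violated (bad shapes, empty input...)."""


class DegenerateInputError(DomainError):
    """Input is constant or otherwise cannot support the operation."""


class DegeneratePartitionError(DomainError):
    """Partition edges collapsed because of insufficient distinct values."""


class NotConvergedError(SpspError):
    """Iterative selection exhausted its budget without satisfying the rule."""


class ProtocolError(SpspError):
    """Cross-validation protocol requirements violated."""
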
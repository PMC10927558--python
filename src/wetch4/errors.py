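"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration problems (2), data/schema
problems (3), numerical/degenerate-input problems (4).
"""


class WetCH4Error(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidConfigError(WetCH4Error):
    """A configuration value violates its contract (bad grid extent, fractions
    not summing to one, ...)."""

    exit_code = 2


class AlignmentError(WetCH4Error):
    """Two gridded objects do not share the same grid/time axes."""

    exit_code = 3


class SchemaError(WetCH4Error):
    """A file does not match the expected schema (missing column, bad units,
    non-numeric entry); message carries the offending column/row."""

    exit_code = 3


class CapacityError(WetCH4Error):
    """More sites requested than available wetland cells."""

    exit_code = 2


class InsufficientDataError(WetCH4Error):
    """Not enough usable time steps for the requested lag structure."""

    exit_code = 3


class DegenerateInputError(WetCH4Error):
    """A statistical routine received degenerate input (constant residuals,
    collinear regressors) and refuses to return a silent zero."""

    exit_code = 4
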
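"""Exception hierarchy shared across the package.

Each error class carries the process exit code used by the command-line
interface: 2 for configuration/input problems, 3 for numerical failures,
4 for landscape-connectivity failures.
"""


class RlkinError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(RlkinError):
    """Malformed user input (sequence, structure, file, parameter)."""

    exit_code = 2


class ParseError(InputError):
    """A string or file could not be parsed."""


class ValidityError(InputError):
    """A parsed object violates a structural invariant."""


class ConfigError(RlkinError):
    """Inconsistent or incomplete pipeline configuration."""

    exit_code = 2


class NumericalError(RlkinError):
    """A numerical routine produced non-finite or unusable results."""

    exit_code = 3


class ConnectivityError(RlkinError):
    """A landscape could not be connected within the allowed bounds."""

    exit_code = 4
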
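"""Exception hierarchy.

Each class maps to a distinct CLI exit code (see :mod:`hdxmix.cli`):
input errors (bad sequences/files), configuration errors (inconsistent
options), and domain errors (arguments outside a formula's validity).
"""


class HdxError(Exception):
    """Base class for all hdxmix errors."""

    exit_code = 1


class InputError(HdxError):
    """Malformed user input: sequences, files, unknown residue letters."""

    exit_code = 2


class ConfigurationError(HdxError):
    """Inconsistent or incomplete run configuration."""

    exit_code = 3


class DomainError(HdxError, ValueError):
    """Argument outside the mathematical/physical domain of a formula."""

    exit_code = 4


class NoExchangeableAmideError(DomainError):
    """The queried position carries no backbone amide hydrogen
    (N-terminal residue or proline)."""

    exit_code = 4
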
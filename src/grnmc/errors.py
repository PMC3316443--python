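"""Exception hierarchy shared across the package."""


class GrnmcError(Exception):
    """Base class for all errors raised by grnmc."""


class DialectSyntaxError(GrnmcError):
    """Malformed network file (equation or table dialect).

    Carries 1-based ``line`` and ``column`` of the offending token.
    """

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class UnknownGeneError(GrnmcError):
    """A rule or query refers to a gene the network does not declare."""


class FormulaSyntaxError(GrnmcError):
    """Malformed temporal-logic formula; carries the character offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnboundNameError(GrnmcError):
    """A formula name is neither a gene of the model nor a bound state variable."""


class StateLiteralRangeError(GrnmcError):
    """A ``#k`` state literal exceeds the model's state space."""
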
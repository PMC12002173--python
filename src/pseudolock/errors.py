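"""Exception taxonomy shared across the package.

Three failure classes cover every operation: malformed input text
(:class:`NewickParseError`), a named entity that does not exist
(:class:`NotFoundError`), and an argument that violates a precondition
(:class:`InvalidArgumentError`).
"""


class PseudolockError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(PseudolockError, ValueError):
    """An argument violates an operation's precondition."""


class NotFoundError(PseudolockError, KeyError):
    """A referenced node, edge, gene, sequence or file does not exist."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


class NewickParseError(PseudolockError, ValueError):
    """Malformed Newick text; carries the parser's position information."""
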
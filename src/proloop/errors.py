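"""Exception hierarchy.

All data-level failures raise :class:`ProloopError` subclasses so the CLI can
map them to exit code 1; programming-contract violations raise
:class:`ContractError` (a ValueError).
"""


class ProloopError(Exception):
    """Base class for data-level errors."""


class AlignmentFormatError(ProloopError):
    """Malformed alignment input (ragged rows, bad records)."""


class EmptyInputError(ProloopError):
    """Input stream contained no records."""


class NewickParseError(ProloopError):
    """Malformed Newick string or duplicate leaf labels."""


class TaxonTableError(ProloopError):
    """Missing or malformed taxon-table entries."""


class ContractError(ValueError):
    """A caller violated a documented precondition."""
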
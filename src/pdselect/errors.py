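"""Exception hierarchy.

Every error raised on a user-facing code path derives from :class:`PdSelectError`
so the command-line layer can map failures to distinct exit codes.
"""


class PdSelectError(Exception):
    """Base class for all pdselect errors."""


class NewickParseError(PdSelectError):
    """Malformed newick text; the message names the offending position."""


class TreeValidationError(PdSelectError):
    """A parsed tree violates a structural invariant (duplicate labels,
    negative or missing branch lengths, unary nodes, root out-degree < 2)."""


class UnknownTaxonError(PdSelectError):
    """A requested taxon is not a leaf label of the tree."""

    def __init__(self, taxon: str):
        super().__init__(f"unknown taxon: {taxon!r} is not a leaf label of the tree")
        self.taxon = taxon


class SchemaError(PdSelectError):
    """A tabular input is missing required columns."""


class RecordValidationError(PdSelectError):
    """A taxon-record row carries an invalid or inconsistent value; the
    message names the row and the offending token."""


class SelectionError(PdSelectError):
    """Selection preconditions violated (empty eligible pool, k too large,
    preselected/excluded overlap)."""


class OracleRefusalError(PdSelectError):
    """The exhaustive oracle refuses pools large enough to explode
    combinatorially."""
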
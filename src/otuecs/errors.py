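"""Exception hierarchy.

All data-level failures derive from :class:`DataError` so the CLI can map
them to a single exit code; programming errors (bad arguments) raise the
builtin ``ValueError`` family instead.
"""


class DataError(Exception):
    """Base class for malformed or inconsistent input data."""


class FormatError(DataError):
    """Syntactic problem in an input file (duplicate ids, bad columns, ...)."""


class AlignmentError(FormatError):
    """Sequences that should be aligned are not (unequal lengths, bad chars)."""


class OntologyError(DataError):
    """Structural problem in an ontology (cyclic is_a, dangling edge)."""


class UndefinedDistanceError(DataError):
    """A pair of sequences shares no comparable alignment columns."""


class DegenerateNullError(DataError):
    """The permutation null is constant; a Z-score cannot be formed."""
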
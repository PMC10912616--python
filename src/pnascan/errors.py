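"""Exception hierarchy.

All validation and parse failures raise a :class:`PnascanError` subclass so
the CLI can map them uniformly to exit status 2.
"""


class PnascanError(Exception):
    """Base class for all tool-specific errors."""


class FastaParseError(PnascanError):
    """Malformed FASTA input (bad alphabet, empty record, duplicate contig)."""


class GffParseError(PnascanError):
    """Malformed or inconsistent GFF3 input."""


class SequenceAlphabetError(PnascanError):
    """A sequence contains characters outside the permitted alphabet."""


class WindowOutOfBoundsError(PnascanError):
    """A requested start-codon window does not fit on its contig."""


class FixtureBuildError(PnascanError):
    """A synthetic-fixture spec is inconsistent or could not be realized."""
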
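"""Antisense PNA design against the translational start window.

The designed PNA is the reverse complement of the sense-strand window
spanning ``upstream`` bases 5' of the start codon and ``downstream`` bases
starting at its first base (defaults −5..+5, a 10-mer). A PNA base
sequence written N-terminus→C-terminus is identified with the antisense
DNA strand written 5'→3', so the anti-groEL PNA for the sense window
5'-GTCAAATGGC-3' is written GCCATTTGAC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from pnascan.errors import (
    PnascanError,
    SequenceAlphabetError,
    WindowOutOfBoundsError,
)
from pnascan.genome_io import GeneModel, GenomeRecord

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")
_IUPAC = frozenset("ACGTNRYSWKMBDHV")


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement of an uppercase DNA string.

    Raises :class:`SequenceAlphabetError` naming the 1-based position of
    the first non-nucleotide character.
    """
    for i, c in enumerate(seq):
        if c not in _IUPAC:
            raise SequenceAlphabetError(
                f"non-nucleotide character {c!r} at position {i + 1}"
            )
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases (S counts as G/C; other ambiguity codes do not)."""
    if not seq:
        return 0.0
    return sum(c in "GCS" for c in seq) / len(seq)


@dataclass(frozen=True)
class TargetWindow:
    """The −u..+d start-codon window of one transcript.

    ``genomic_interval`` is the 0-based half-open footprint on the contig;
    ``sense_sequence`` is read 5'→3' on the coding strand, so for minus-
    strand genes it is the reverse complement of the genomic slice. Bases
    ``u..u+2`` of the sense sequence are the annotated start codon.
    """

    transcript_id: str
    genome_id: str
    contig_id: str
    strand: str
    genomic_interval: tuple[int, int]
    sense_sequence: str
    offset_range: tuple[int, int] = (5, 5)
    crosses_splice_junction: bool = False

    def __post_init__(self) -> None:
        u, d = self.offset_range
        if len(self.sense_sequence) != u + d:
            raise PnascanError(
                f"window sense sequence length {len(self.sense_sequence)} "
                f"!= upstream+downstream {u + d}"
            )


@dataclass(frozen=True)
class PNAOligo:
    """A PNA base sequence with conjugate metadata.

    ``base_sequence`` is written N-terminus→C-terminus and restricted to
    {A,C,G,T}. Conjugates (cell-penetrating peptide, fluorophore, amide)
    are opaque labels; no chemistry is modeled. ``tm_celsius`` is optional
    user-supplied metadata — no melting-temperature model is implemented.
    """

    pna_id: str
    base_sequence: str
    n_terminal_conjugate: str = ""
    c_terminal_conjugate: str = ""
    source_window: TargetWindow | None = None
    tm_celsius: float | None = None

    def __post_init__(self) -> None:
        bad = set(self.base_sequence) - set("ACGT")
        if bad:
            raise SequenceAlphabetError(
                f"PNA '{self.pna_id}': base sequence must be over "
                f"{{A,C,G,T}}, found {sorted(bad)}"
            )
        if not self.base_sequence:
            raise SequenceAlphabetError(f"PNA '{self.pna_id}': empty base sequence")

    @property
    def length(self) -> int:
        return len(self.base_sequence)


def _record_lookup(
    genomes: Sequence[GenomeRecord], genome_id: str, contig_id: str
) -> GenomeRecord:
    for rec in genomes:
        if rec.genome_id == genome_id and rec.contig_id == contig_id:
            return rec
    raise PnascanError(
        f"contig '{contig_id}' of genome '{genome_id}' not found in genome set"
    )


def extract_start_window(
    model: GeneModel,
    genomes: Sequence[GenomeRecord],
    upstream: int = 5,
    downstream: int = 5,
) -> TargetWindow:
    """Extract the −upstream..+downstream window around a gene's start codon.

    The window is taken on the genomic sequence flanking the first CDS base
    even for spliced genes; ``crosses_splice_junction`` flags windows that
    span a gap between the model's exon segments. ``downstream`` must be at
    least 3 so the full start codon is inside the window.
    """
    if upstream < 0:
        raise PnascanError("upstream must be >= 0")
    if downstream < 3:
        raise PnascanError("downstream must be >= 3")
    rec = _record_lookup(genomes, model.genome_id, model.contig_id)
    tss = model.tss_position
    if model.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream + 1, tss + upstream + 1
    if start < 0 or end > rec.length:
        raise WindowOutOfBoundsError(
            f"window out of bounds: transcript '{model.transcript_id}' "
            f"[{start},{end}) on contig '{model.contig_id}' of length {rec.length}"
        )
    genomic_slice = rec.sequence[start:end]
    sense = genomic_slice if model.strand == "+" else revcomp(genomic_slice)
    crosses = any(
        start < gap_end and gap_start < end
        for gap_start, gap_end in _segment_gaps(model.exon_segments)
    )
    return TargetWindow(
        transcript_id=model.transcript_id,
        genome_id=model.genome_id,
        contig_id=model.contig_id,
        strand=model.strand,
        genomic_interval=(start, end),
        sense_sequence=sense,
        offset_range=(upstream, downstream),
        crosses_splice_junction=crosses,
    )


def _segment_gaps(segments: tuple[tuple[int, int], ...]) -> list[tuple[int, int]]:
    return [
        (segments[i][1], segments[i + 1][0])
        for i in range(len(segments) - 1)
        if segments[i + 1][0] > segments[i][1]
    ]


def design_antisense(
    window: TargetWindow,
    pna_id: str,
    n_conjugate: str = "",
    c_conjugate: str = "",
) -> PNAOligo:
    """Emit the antisense PNA for a target window.

    The base sequence is the reverse complement of the window's sense
    sequence; length is upstream+downstream (10 with defaults). Conjugate
    labels are attached verbatim.
    """
    return PNAOligo(
        pna_id=pna_id,
        base_sequence=revcomp(window.sense_sequence),
        n_terminal_conjugate=n_conjugate,
        c_terminal_conjugate=c_conjugate,
        source_window=window,
    )
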
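"""Genome FASTA / GFF3 ingest and report output.

Coordinate convention: every in-memory interval is 0-based half-open
``[start, end)``; all file I/O (GFF3 in, report TSV out) is 1-based
inclusive, matching GFF3 and the way bacterial loci are cited
(e.g. "18,715–20,361 bp").

The translational start site (TSS) of a gene model is the genomic
coordinate of the *first base of the start codon* in transcription order:
the smallest CDS start on the plus strand, the largest CDS end minus one
on the minus strand. Throughout this package "TSS" means the translation
start, not a transcription start site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
from urllib.parse import unquote

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

from pnascan.errors import FastaParseError, GffParseError, PnascanError

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes accepted after uppercasing.
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

#: Report columns, in output order.
REPORT_COLUMNS = (
    "query_id",
    "genome_id",
    "contig_id",
    "start",
    "end",
    "orientation",
    "overlap_class",
    "gene_ids",
    "tss_included",
)


@dataclass(frozen=True)
class GenomeRecord:
    """A named contig sequence belonging to a named genome."""

    genome_id: str
    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaParseError(
                f"record '{self.contig_id}' in genome '{self.genome_id}' is empty"
            )
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence) if c in bad
            )
            raise FastaParseError(
                f"record '{self.contig_id}': non-IUPAC character "
                f"{self.sequence[pos]!r} at sequence position {pos + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene with ordered CDS/exon segments and a derived TSS.

    ``cds_segments`` / ``exon_segments`` are tuples of 0-based half-open
    genomic intervals sorted in genomic order. ``tss_position`` is the
    0-based genomic coordinate of the first base of the start codon.
    """

    gene_id: str
    transcript_id: str
    genome_id: str
    contig_id: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    exon_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GffParseError(
                f"transcript '{self.transcript_id}': strand must be + or -, "
                f"got {self.strand!r}"
            )
        if not self.cds_segments:
            raise GffParseError(
                f"transcript '{self.transcript_id}' has no CDS segments"
            )
        prev_end = None
        for s, e in self.cds_segments:
            if e <= s:
                raise GffParseError(
                    f"transcript '{self.transcript_id}': empty CDS segment [{s},{e})"
                )
            if prev_end is not None and s < prev_end:
                raise GffParseError(
                    f"transcript '{self.transcript_id}': CDS segments overlap "
                    "or are unsorted"
                )
            prev_end = e

    @property
    def tss_position(self) -> int:
        """First base of the start codon, 0-based genomic."""
        if self.strand == "+":
            return self.cds_segments[0][0]
        return self.cds_segments[-1][1] - 1

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint from first to last segment (half-open)."""
        segs = self.cds_segments + self.exon_segments
        return min(s for s, _ in segs), max(e for _, e in segs)

    def start_codon_positions(self) -> tuple[int, int, int]:
        """Genomic coordinates of the three start-codon bases."""
        t = self.tss_position
        if self.strand == "+":
            return (t, t + 1, t + 2)
        return (t - 2, t - 1, t)


class AnnotationSet:
    """Gene models keyed by (genome_id, transcript_id) plus overlap indexes.

    Interval trees over CDS and exon segments answer hit-classification
    queries; a per-contig TSS list supports the start-site rule. The
    companion genome set fixes which contigs are known.
    """

    def __init__(
        self,
        gene_models: Mapping[tuple[str, str], GeneModel],
        genomes: Iterable[GenomeRecord],
    ) -> None:
        self.gene_models: dict[tuple[str, str], GeneModel] = dict(gene_models)
        self.contig_lengths: dict[tuple[str, str], int] = {
            (g.genome_id, g.contig_id): g.length for g in genomes
        }
        for model in self.gene_models.values():
            key = (model.genome_id, model.contig_id)
            if key not in self.contig_lengths:
                raise GffParseError(
                    f"transcript '{model.transcript_id}' refers to unknown "
                    f"contig '{model.contig_id}' in genome '{model.genome_id}'"
                )
            clen = self.contig_lengths[key]
            for s, e in model.cds_segments:
                if s < 0 or e > clen:
                    raise GffParseError(
                        f"CDS segment [{s + 1},{e}] of transcript "
                        f"'{model.transcript_id}' extends beyond contig "
                        f"'{model.contig_id}' (length {clen})"
                    )
        self._cds_index: dict[tuple[str, str], IntervalTree] = {}
        self._exon_index: dict[tuple[str, str], IntervalTree] = {}
        self._genes_by_contig: dict[tuple[str, str], list[GeneModel]] = {}
        for model in self.gene_models.values():
            key = (model.genome_id, model.contig_id)
            cds = self._cds_index.setdefault(key, IntervalTree())
            for s, e in model.cds_segments:
                cds.addi(s, e, model.transcript_id)
            exo = self._exon_index.setdefault(key, IntervalTree())
            for s, e in model.exon_segments:
                exo.addi(s, e, model.transcript_id)
            self._genes_by_contig.setdefault(key, []).append(model)

    def __len__(self) -> int:
        return len(self.gene_models)

    def has_contig(self, genome_id: str, contig_id: str) -> bool:
        return (genome_id, contig_id) in self.contig_lengths

    def genes_on_contig(self, genome_id: str, contig_id: str) -> list[GeneModel]:
        return self._genes_by_contig.get((genome_id, contig_id), [])

    def cds_overlaps(
        self, genome_id: str, contig_id: str, start: int, end: int
    ) -> set[str]:
        """Transcript ids whose CDS segments overlap [start, end)."""
        tree = self._cds_index.get((genome_id, contig_id))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def exon_overlaps(
        self, genome_id: str, contig_id: str, start: int, end: int
    ) -> set[str]:
        """Transcript ids whose exon segments overlap [start, end)."""
        tree = self._exon_index.get((genome_id, contig_id))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


@dataclass(frozen=True)
class GenomeSet:
    """One genome's sequence records together with its annotation."""

    genome_id: str
    records: tuple[GenomeRecord, ...]
    annotations: AnnotationSet


def read_fasta(path: str | Path, genome_id: str) -> list[GenomeRecord]:
    """Read a (multi-record) FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased (soft-masking discarded); the header token
    before the first whitespace becomes the contig id. Duplicate contig
    ids within one genome and non-IUPAC characters are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"FASTA file not found: {path}")
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            record = GenomeRecord(genome_id=genome_id, contig_id=rec.id, sequence=seq)
        except FastaParseError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
        if rec.id in seen:
            raise FastaParseError(
                f"{path}: duplicate contig_id '{rec.id}' within genome "
                f"'{genome_id}'"
            )
        seen.add(rec.id)
        records.append(record)
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = unquote(value.strip())
    return attrs


def _resolve_owner(attrs: dict[str, str], line_no: int, ftype: str) -> str | None:
    """Owner transcript of a CDS/exon row: Parent, then ID, then gene/locus_tag."""
    if "Parent" in attrs:
        # multi-parent features are attached to the first parent only
        return attrs["Parent"].split(",")[0]
    for fallback in ("ID", "gene", "locus_tag"):
        if fallback in attrs:
            logger.warning(
                "GFF line %d: %s feature has no Parent; falling back to %s=%s",
                line_no, ftype, fallback, attrs[fallback],
            )
            return attrs[fallback]
    return None


def read_gff(path: str | Path, genomes: Sequence[GenomeRecord]) -> AnnotationSet:
    """Parse a GFF3 file into an :class:`AnnotationSet`.

    CDS and exon rows are grouped per transcript via their ``Parent``
    attribute (``ID``, then ``gene``/``locus_tag``, as logged fallbacks for
    parent-less bacterial dialects). GFF 1-based inclusive coordinates are
    converted to 0-based half-open. Transcripts without any CDS are skipped
    with a warning; transcripts without exon rows inherit their CDS
    segments as exons.
    """
    path = Path(path)
    if not path.exists():
        raise GffParseError(f"GFF file not found: {path}")
    genome_ids = {g.genome_id for g in genomes}
    if len(genome_ids) != 1:
        raise GffParseError(
            f"read_gff expects records from exactly one genome, got {sorted(genome_ids)}"
        )
    genome_id = next(iter(genome_ids))
    contig_ids = {g.contig_id for g in genomes}

    parent_of: dict[str, str] = {}  # feature ID -> its Parent (mRNA -> gene)
    cds_rows: dict[str, list[tuple[int, int, str, str]]] = {}
    exon_rows: dict[str, list[tuple[int, int]]] = {}
    mrna_ids: set[str] = set()

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(
                    f"{path}:{line_no}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, col9 = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffParseError(
                    f"{path}:{line_no}: non-integer coordinates "
                    f"{start_s!r}..{end_s!r}"
                ) from exc
            if start < 1 or end < start:
                raise GffParseError(
                    f"{path}:{line_no}: invalid coordinate range {start}..{end}"
                )
            attrs = _parse_attributes(col9)
            if ftype in ("mRNA", "transcript"):
                if "ID" in attrs:
                    mrna_ids.add(attrs["ID"])
                    if "Parent" in attrs:
                        parent_of[attrs["ID"]] = attrs["Parent"].split(",")[0]
                continue
            if ftype == "CDS":
                if strand not in ("+", "-"):
                    raise GffParseError(
                        f"{path}:{line_no}: CDS strand must be + or -, got "
                        f"{strand!r}"
                    )
                if seqid not in contig_ids:
                    raise GffParseError(
                        f"{path}:{line_no}: CDS on unknown contig '{seqid}'"
                    )
                owner = _resolve_owner(attrs, line_no, "CDS")
                if owner is None:
                    logger.warning(
                        "%s:%d: CDS with unresolvable parent skipped", path, line_no
                    )
                    continue
                cds_rows.setdefault(owner, []).append((start - 1, end, seqid, strand))
            elif ftype == "exon":
                owner = _resolve_owner(attrs, line_no, "exon")
                if owner is None:
                    logger.warning(
                        "%s:%d: exon with unresolvable parent skipped", path, line_no
                    )
                    continue
                exon_rows.setdefault(owner, []).append((start - 1, end))
            # gene rows and other feature types carry no segment information we use

    models: dict[tuple[str, str], GeneModel] = {}
    for transcript_id, rows in sorted(cds_rows.items()):
        contigs = {r[2] for r in rows}
        strands = {r[3] for r in rows}
        if len(contigs) > 1 or len(strands) > 1:
            raise GffParseError(
                f"transcript '{transcript_id}' mixes contigs or strands"
            )
        contig_id = rows[0][2]
        strand = rows[0][3]
        cds = tuple(sorted((s, e) for s, e, *_ in rows))
        exons = tuple(sorted(exon_rows.get(transcript_id, []))) or cds
        gene_id = parent_of.get(transcript_id, transcript_id)
        models[(genome_id, transcript_id)] = GeneModel(
            gene_id=gene_id,
            transcript_id=transcript_id,
            genome_id=genome_id,
            contig_id=contig_id,
            strand=strand,
            cds_segments=cds,
            exon_segments=exons,
        )

    skipped = mrna_ids - set(cds_rows)
    for tid in sorted(skipped):
        logger.warning("transcript '%s' has no CDS; skipped", tid)

    return AnnotationSet(models, genomes)


def load_genome_set(
    fasta_path: str | Path, gff_path: str | Path, genome_id: str
) -> GenomeSet:
    """Load one genome's FASTA + GFF3 pair into a :class:`GenomeSet`."""
    records = read_fasta(fasta_path, genome_id)
    annotations = read_gff(gff_path, records)
    return GenomeSet(genome_id=genome_id, records=tuple(records), annotations=annotations)


def write_report(hits: Sequence, path: str | Path) -> None:
    """Write annotated hits as the tab-delimited report.

    One row per hit; ``start``/``end`` are 1-based inclusive; ``gene_ids``
    comma-separated (empty for intergenic); rows sorted by
    (genome_id, contig_id, start, orientation).
    """
    rows = []
    for ann in hits:
        hit = ann.hit
        rows.append(
            {
                "query_id": hit.query_id,
                "genome_id": hit.genome_id,
                "contig_id": hit.contig_id,
                "start": hit.interval[0] + 1,
                "end": hit.interval[1],
                "orientation": hit.orientation,
                "overlap_class": ann.overlap_class,
                "gene_ids": ",".join(ann.gene_ids),
                "tss_included": "yes" if ann.tss_included else "no",
            }
        )
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    if len(df):
        df = df.sort_values(
            ["genome_id", "contig_id", "start", "orientation"], kind="mergesort"
        ).reset_index(drop=True)
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise PnascanError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report TSV written by :func:`write_report`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != REPORT_COLUMNS:
        raise PnascanError(f"{path}: not a pnascan report (unexpected columns)")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df
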
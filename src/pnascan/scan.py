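"""Holo-genome off-target scanning and hit classification.

Every occurrence of a query sequence or its reverse complement on the
plus-strand text is reported, including overlapping occurrences.
Orientation ``forward`` means the query string itself occurs on the plus
strand as written; ``revcomp`` means the query's reverse complement does
(the biologically active case for an antisense PNA: its reverse
complement lying in a transcript's sense strand). A palindromic query
(equal to its own reverse complement) is reported once per position, as
``forward``.

Hits are classified against the annotation with precedence
``TSS_included > CDS_internal > exon > SD_region > intergenic``. The
default TSS rule calls a hit "Translational Start Site Included" iff its
footprint contains the first base of a start codon; an alternative rule
accepts any of the three start-codon bases. The Shine-Dalgarno window
defaults to coding-strand offsets −15..−5 relative to the start codon's
first base.

Exact matching is literal: a genome position holding N (or any non-ACGT
code) never matches. The opt-in IUPAC mode expands genome ambiguity codes
to character classes instead. Mismatch search counts substitutions only
(Hamming distance); in that mode an ambiguous genome base counts as a
mismatch unless IUPAC expansion is enabled.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pnascan.design import PNAOligo, revcomp
from pnascan.errors import PnascanError
from pnascan.genome_io import AnnotationSet, GenomeRecord, GenomeSet, load_genome_set

ORIENT_FORWARD = "forward"
ORIENT_REVCOMP = "revcomp"

#: genome ambiguity code -> set of concrete bases it stands for
_IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

CLASS_TSS = "TSS_included"
CLASS_CDS = "CDS_internal"
CLASS_EXON = "exon"
CLASS_SD = "SD_region"
CLASS_INTERGENIC = "intergenic"


@dataclass(frozen=True)
class HitRecord:
    """One genomic occurrence of a query or its reverse complement."""

    query_id: str
    genome_id: str
    contig_id: str
    interval: tuple[int, int]
    orientation: str
    mismatches: int = 0


@dataclass(frozen=True)
class HitAnnotation:
    """A hit with its genomic-context classification."""

    hit: HitRecord
    overlap_class: str
    gene_ids: tuple[str, ...]

    @property
    def tss_included(self) -> bool:
        return self.overlap_class == CLASS_TSS


def _normalize_queries(
    queries: Iterable[PNAOligo | tuple[str, str] | str] | PNAOligo | str,
) -> list[tuple[str, str]]:
    """Accept PNAOligo objects, (id, seq) pairs, or raw sequences."""
    if isinstance(queries, (PNAOligo, str)):
        queries = [queries]
    out: list[tuple[str, str]] = []
    for q in queries:
        if isinstance(q, PNAOligo):
            qid, seq = q.pna_id, q.base_sequence
        elif isinstance(q, str):
            qid, seq = q, q
        else:
            qid, seq = q
        seq = seq.upper()
        if not seq:
            raise PnascanError("empty query sequence")
        bad = set(seq) - set("ACGT")
        if bad:
            raise PnascanError(
                f"query '{qid}': alphabet must be {{A,C,G,T}}, found {sorted(bad)}"
            )
        out.append((qid, seq))
    return out


def _find_all(text: str, pattern: str) -> Iterable[int]:
    """All (overlapping) occurrence offsets of pattern in text."""
    i = text.find(pattern)
    while i != -1:
        yield i
        i = text.find(pattern, i + 1)


def _find_all_iupac(text: str, pattern: str) -> Iterable[int]:
    """Occurrences where each genome code's expansion contains the query base."""
    classes = []
    for base in pattern:
        codes = "".join(
            code for code, concrete in _IUPAC_EXPAND.items() if base in concrete
        )
        classes.append(f"[{codes}]")
    rx = re.compile("(?=(" + "".join(classes) + "))")
    return (m.start() for m in rx.finditer(text))


def _sort_hits(hits: list[HitRecord]) -> list[HitRecord]:
    return sorted(
        hits,
        key=lambda h: (h.genome_id, h.contig_id, h.interval[0], h.orientation),
    )


def find_exact_matches(
    queries: Iterable[PNAOligo | tuple[str, str] | str] | PNAOligo | str,
    genomes: Sequence[GenomeRecord],
    iupac: bool = False,
) -> list[HitRecord]:
    """Every exact occurrence of each query and its reverse complement.

    Overlapping occurrences are all reported. With ``iupac=True`` genome
    ambiguity codes match as character classes; by default they match
    nothing.
    """
    pairs = _normalize_queries(queries)
    finder = _find_all_iupac if iupac else _find_all
    hits: list[HitRecord] = []
    for qid, seq in pairs:
        rc = revcomp(seq)
        passes = [(seq, ORIENT_FORWARD)]
        if rc != seq:
            passes.append((rc, ORIENT_REVCOMP))
        for rec in genomes:
            for pattern, orientation in passes:
                for pos in finder(rec.sequence, pattern):
                    hits.append(
                        HitRecord(
                            query_id=qid,
                            genome_id=rec.genome_id,
                            contig_id=rec.contig_id,
                            interval=(pos, pos + len(seq)),
                            orientation=orientation,
                        )
                    )
    return _sort_hits(hits)


def find_mismatch_matches(
    query: PNAOligo | tuple[str, str] | str,
    genomes: Sequence[GenomeRecord],
    max_mismatches: int,
    iupac: bool = False,
) -> list[HitRecord]:
    """All positions within Hamming distance ``max_mismatches`` of the query.

    Both orientations are searched; substitutions only, no indels. At
    ``max_mismatches=0`` the result equals :func:`find_exact_matches`.
    """
    (qid, seq), = _normalize_queries(query)
    if not 0 <= max_mismatches < len(seq):
        raise PnascanError(
            f"max_mismatches must satisfy 0 <= k < query length "
            f"({len(seq)}), got {max_mismatches}"
        )
    if max_mismatches == 0:
        return find_exact_matches([(qid, seq)], genomes, iupac=iupac)
    rc = revcomp(seq)
    passes = [(seq, ORIENT_FORWARD)]
    if rc != seq:
        passes.append((rc, ORIENT_REVCOMP))
    hits: list[HitRecord] = []
    L = len(seq)
    for rec in genomes:
        text = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        n = rec.length - L + 1
        if n <= 0:
            continue
        for pattern, orientation in passes:
            mism = np.zeros(n, dtype=np.int32)
            for j, ch in enumerate(pattern.encode("ascii")):
                if iupac:
                    allowed = [
                        code.encode()[0]
                        for code, concrete in _IUPAC_EXPAND.items()
                        if chr(ch) in concrete
                    ]
                    col = text[j : j + n]
                    ok = np.zeros(n, dtype=bool)
                    for a in allowed:
                        ok |= col == a
                    mism += ~ok
                else:
                    mism += text[j : j + n] != ch
            for pos in np.flatnonzero(mism <= max_mismatches):
                hits.append(
                    HitRecord(
                        query_id=qid,
                        genome_id=rec.genome_id,
                        contig_id=rec.contig_id,
                        interval=(int(pos), int(pos) + L),
                        orientation=orientation,
                        mismatches=int(mism[pos]),
                    )
                )
    return _sort_hits(hits)


def _tss_hit_transcripts(
    ann: AnnotationSet,
    genome_id: str,
    contig_id: str,
    start: int,
    end: int,
    tss_rule: str,
) -> set[str]:
    out = set()
    for model in ann.genes_on_contig(genome_id, contig_id):
        if tss_rule == "first-base":
            positions = (model.tss_position,)
        elif tss_rule == "any-start-codon-base":
            positions = model.start_codon_positions()
        else:
            raise PnascanError(f"unknown tss rule: {tss_rule!r}")
        if any(start <= p < end for p in positions):
            out.add(model.transcript_id)
    return out


def _sd_interval(model, sd_window: tuple[int, int]) -> tuple[int, int]:
    """Genomic footprint of the Shine-Dalgarno window for one gene.

    Offsets are on the coding strand relative to the start codon's first
    base; (−15, −5) means the 11 bases from 15 to 5 upstream, inclusive.
    """
    lo, hi = sd_window
    t = model.tss_position
    if model.strand == "+":
        return (t + lo, t + hi + 1)
    return (t - hi, t - lo + 1)


def annotate_hits(
    hits: Sequence[HitRecord],
    annotations: AnnotationSet,
    sd_window: tuple[int, int] = (-15, -5),
    tss_rule: str = "first-base",
) -> list[HitAnnotation]:
    """Classify each hit by genomic context.

    Precedence: TSS_included > CDS_internal > exon > SD_region >
    intergenic. ``gene_ids`` lists every transcript contributing the
    winning class, sorted; it is empty exactly for intergenic hits.
    """
    out: list[HitAnnotation] = []
    for hit in hits:
        if not annotations.has_contig(hit.genome_id, hit.contig_id):
            raise PnascanError(
                f"hit on unknown contig '{hit.contig_id}' of genome "
                f"'{hit.genome_id}'"
            )
        s, e = hit.interval
        tss = _tss_hit_transcripts(
            annotations, hit.genome_id, hit.contig_id, s, e, tss_rule
        )
        if tss:
            out.append(HitAnnotation(hit, CLASS_TSS, tuple(sorted(tss))))
            continue
        cds = annotations.cds_overlaps(hit.genome_id, hit.contig_id, s, e)
        if cds:
            out.append(HitAnnotation(hit, CLASS_CDS, tuple(sorted(cds))))
            continue
        exon = annotations.exon_overlaps(hit.genome_id, hit.contig_id, s, e)
        if exon:
            out.append(HitAnnotation(hit, CLASS_EXON, tuple(sorted(exon))))
            continue
        sd = {
            m.transcript_id
            for m in annotations.genes_on_contig(hit.genome_id, hit.contig_id)
            if max(s, _sd_interval(m, sd_window)[0])
            < min(e, _sd_interval(m, sd_window)[1])
        }
        if sd:
            out.append(HitAnnotation(hit, CLASS_SD, tuple(sorted(sd))))
            continue
        out.append(HitAnnotation(hit, CLASS_INTERGENIC, ()))
    return out


def _coerce_genome_sets(
    genome_sets: Sequence[GenomeSet | tuple],
) -> list[GenomeSet]:
    out = []
    for gs in genome_sets:
        if isinstance(gs, GenomeSet):
            out.append(gs)
        else:
            fasta, gff, *rest = gs
            genome_id = rest[0] if rest else Path(fasta).stem
            out.append(load_genome_set(fasta, gff, genome_id))
    return out


def scan_holo_genome(
    queries: Iterable[PNAOligo | tuple[str, str] | str] | PNAOligo | str,
    genome_sets: Sequence[GenomeSet | tuple],
    max_mismatches: int = 0,
    sd_window: tuple[int, int] = (-15, -5),
    tss_rule: str = "first-base",
    iupac: bool = False,
) -> tuple[list[HitAnnotation], pd.DataFrame]:
    """Scan all queries across every genome of a host-symbiont set.

    Returns the concatenated annotated hits plus a per-(query, genome)
    summary with ``n_hits``, ``n_TSS_included`` and
    ``n_genes_cds_overlap`` — the number of distinct transcripts whose CDS
    overlaps any hit of that query in that genome, in either orientation.
    Every (query, genome) pair appears in the summary, zeros included.
    """
    if not genome_sets:
        raise PnascanError("at least one genome set is required")
    sets = _coerce_genome_sets(genome_sets)
    pairs = _normalize_queries(queries)
    annotated: list[HitAnnotation] = []
    counts: dict[tuple[str, str], dict[str, int]] = {}
    cds_genes: dict[tuple[str, str], set[str]] = defaultdict(set)
    for qid, _seq in pairs:
        for gs in sets:
            counts[(qid, gs.genome_id)] = {"n_hits": 0, "n_TSS_included": 0}
    for gs in sets:
        for qid, seq in pairs:
            if max_mismatches == 0:
                hits = find_exact_matches([(qid, seq)], gs.records, iupac=iupac)
            else:
                hits = find_mismatch_matches(
                    (qid, seq), gs.records, max_mismatches, iupac=iupac
                )
            anns = annotate_hits(
                hits, gs.annotations, sd_window=sd_window, tss_rule=tss_rule
            )
            annotated.extend(anns)
            key = (qid, gs.genome_id)
            counts[key]["n_hits"] += len(anns)
            counts[key]["n_TSS_included"] += sum(a.tss_included for a in anns)
            for a in anns:
                s, e = a.hit.interval
                cds_genes[key] |= gs.annotations.cds_overlaps(
                    a.hit.genome_id, a.hit.contig_id, s, e
                )
    rows = [
        {
            "query_id": qid,
            "genome_id": gid,
            "n_hits": c["n_hits"],
            "n_TSS_included": c["n_TSS_included"],
            "n_genes_cds_overlap": len(cds_genes[(qid, gid)]),
        }
        for (qid, gid), c in counts.items()
    ]
    summary = pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "genome_id",
            "n_hits",
            "n_TSS_included",
            "n_genes_cds_overlap",
        ],
    ).sort_values(["query_id", "genome_id"], kind="mergesort").reset_index(drop=True)
    return annotated, summary
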
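"""Deterministic synthetic genomes with planted query occurrences.

Builds small multi-genome fixtures — i.i.d. background sequence at a
stated GC fraction, plus/minus-strand genes whose CDS begins with ATG,
optionally spliced, and query occurrences planted at chosen coordinates —
together with a machine-readable ground-truth table computed by a naive
scan and brute-force classification of the emitted sequence. The builder
*verifies* planted-site uniqueness: if a planted (or forbidden) sequence
recurs by chance in the random background, the background is redrawn a
bounded number of times, so the ground truth is exact, not probabilistic.

Identical spec + seed yields byte-identical FASTA/GFF3/ground-truth
files. The default fixture mirrors the geometry of an aphid–*Buchnera*
holo-genome study: an AT-rich "symbiont" genome carrying a groEL-like
target gene (whose −5..+5 start window reverse-complements to
GCCATTTGAC) and a pyrG-like gene with the same 10-mer mid-CDS, and a
larger "host" genome whose only near-match is a one-mismatch decoy at a
host gene's start site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from pnascan.design import revcomp
from pnascan.errors import FixtureBuildError

_MAX_REDRAWS = 50

CLASS_TSS = "TSS_included"
CLASS_CDS = "CDS_internal"
CLASS_SD = "SD_region"
CLASS_INTERGENIC = "intergenic"


@dataclass(frozen=True)
class ContigSpec:
    genome_id: str
    contig_id: str
    length: int
    gc: float


@dataclass(frozen=True)
class GeneSpec:
    """A planted gene. ``tss`` is the 1-based genomic coordinate of the
    first start-codon base; ``intron`` (coding_offset, length) splits the
    CDS after ``coding_offset`` coding bases."""

    gene_id: str
    genome_id: str
    contig_id: str
    strand: str
    tss: int
    cds_length: int
    intron: tuple[int, int] | None = None


@dataclass(frozen=True)
class PlantSpec:
    """A planted query occurrence. ``position`` is the 1-based genomic
    start of the written footprint; orientation ``forward`` writes the
    query itself, ``revcomp`` writes its reverse complement (so a scan for
    the query reports the hit with that orientation)."""

    query: str
    genome_id: str
    contig_id: str
    position: int
    orientation: str
    intended_class: str


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    contigs: tuple[ContigSpec, ...]
    genes: tuple[GeneSpec, ...] = ()
    plants: tuple[PlantSpec, ...] = ()
    forbidden_sequences: tuple[str, ...] = ()


@dataclass(frozen=True)
class FixtureBuild:
    """Paths of a built fixture: one FASTA+GFF3 pair per genome plus the
    ground-truth TSV."""

    out_dir: Path
    fasta_paths: tuple[tuple[str, Path], ...]
    gff_paths: tuple[tuple[str, Path], ...]
    ground_truth_path: Path

    def genome_pairs(self) -> list[tuple[Path, Path, str]]:
        """(fasta, gff, genome_id) triplets, e.g. for scan_holo_genome."""
        gff = dict(self.gff_paths)
        return [(fa, gff[gid], gid) for gid, fa in self.fasta_paths]


def _gene_segments(gene: GeneSpec) -> list[tuple[int, int]]:
    """0-based half-open CDS segments in genomic order."""
    t = gene.tss - 1
    L = gene.cds_length
    if gene.intron is None:
        if gene.strand == "+":
            return [(t, t + L)]
        return [(t - L + 1, t + 1)]
    k, ilen = gene.intron
    if not 3 <= k < L:
        raise FixtureBuildError(
            f"gene '{gene.gene_id}': intron offset {k} must be in [3, cds_length)"
        )
    if gene.strand == "+":
        return [(t, t + k), (t + k + ilen, t + L + ilen)]
    seg1 = (t - k + 1, t + 1)
    seg2_hi = t - k - ilen + 1
    seg2 = (seg2_hi - (L - k), seg2_hi)
    return [seg2, seg1]


def _validate_spec(spec: FixtureSpec) -> None:
    contig_len: dict[tuple[str, str], int] = {}
    for c in spec.contigs:
        key = (c.genome_id, c.contig_id)
        if key in contig_len:
            raise FixtureBuildError(f"duplicate contig {key}")
        if c.length <= 0 or not 0.0 <= c.gc <= 1.0:
            raise FixtureBuildError(f"contig {key}: bad length or GC fraction")
        contig_len[key] = c.length
    for g in spec.genes:
        key = (g.genome_id, g.contig_id)
        if key not in contig_len:
            raise FixtureBuildError(f"gene '{g.gene_id}' on unknown contig {key}")
        if g.strand not in ("+", "-"):
            raise FixtureBuildError(f"gene '{g.gene_id}': strand must be + or -")
        if g.cds_length < 3 or g.cds_length % 3 != 0:
            raise FixtureBuildError(
                f"gene '{g.gene_id}': cds_length must be a positive multiple of 3"
            )
        for s, e in _gene_segments(g):
            if s < 0 or e > contig_len[key]:
                raise FixtureBuildError(
                    f"gene '{g.gene_id}': segment [{s},{e}) out of contig bounds"
                )
    seen_intervals: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for p in spec.plants:
        key = (p.genome_id, p.contig_id)
        if key not in contig_len:
            raise FixtureBuildError(f"plant on unknown contig {key}")
        if p.orientation not in ("forward", "revcomp"):
            raise FixtureBuildError(f"plant orientation must be forward/revcomp")
        bad = set(p.query) - set("ACGT")
        if bad:
            raise FixtureBuildError(f"plant query must be over ACGT, found {bad}")
        s = p.position - 1
        e = s + len(p.query)
        if s < 0 or e > contig_len[key]:
            raise FixtureBuildError(
                f"plant '{p.query}' at {p.position} out of contig bounds"
            )
        for s2, e2 in seen_intervals.get(key, []):
            if s < e2 and s2 < e:
                raise FixtureBuildError(
                    f"colliding plants on contig {key} at [{s},{e}) and [{s2},{e2})"
                )
        seen_intervals.setdefault(key, []).append((s, e))


def _naive_occurrences(
    query: str, sequences: dict[tuple[str, str], str]
) -> set[tuple[str, str, int, str]]:
    """All (genome, contig, 0-based offset, orientation) occurrences of a
    query or its reverse complement, by direct substring comparison."""
    rc = revcomp(query)
    out = set()
    L = len(query)
    for (gid, cid), seq in sequences.items():
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            if window == query:
                out.add((gid, cid, i, "forward"))
            elif window == rc:
                out.add((gid, cid, i, "revcomp"))
    return out


def _classify(
    s: int, e: int, genes: Sequence[GeneSpec], sd_window: tuple[int, int] = (-15, -5)
) -> str:
    """Brute-force hit class against the spec's gene list (first-base TSS
    rule, default SD window); independent of the scan module."""
    tss_hit = cds_hit = sd_hit = False
    for g in genes:
        t = g.tss - 1
        if s <= t < e:
            tss_hit = True
        for cs, ce in _gene_segments(g):
            if s < ce and cs < e:
                cds_hit = True
        lo, hi = sd_window
        if g.strand == "+":
            sd = (t + lo, t + hi + 1)
        else:
            sd = (t - hi, t - lo + 1)
        if s < sd[1] and sd[0] < e:
            sd_hit = True
    if tss_hit:
        return CLASS_TSS
    if cds_hit:
        return CLASS_CDS
    if sd_hit:
        return CLASS_SD
    return CLASS_INTERGENIC


def _compose(
    spec: FixtureSpec, attempt: int
) -> dict[tuple[str, str], str]:
    rng = np.random.default_rng(spec.seed + attempt)
    seqs: dict[tuple[str, str], list[str]] = {}
    for c in spec.contigs:
        p_gc = c.gc / 2.0
        p_at = (1.0 - c.gc) / 2.0
        arr = rng.choice(
            np.array(list("ACGT")), size=c.length, p=[p_at, p_gc, p_gc, p_at]
        )
        seqs[(c.genome_id, c.contig_id)] = list(arr)
    for g in spec.genes:
        seq = seqs[(g.genome_id, g.contig_id)]
        t = g.tss - 1
        if g.strand == "+":
            seq[t], seq[t + 1], seq[t + 2] = "A", "T", "G"
        else:
            seq[t - 2], seq[t - 1], seq[t] = "C", "A", "T"
    for p in spec.plants:
        seq = seqs[(p.genome_id, p.contig_id)]
        written = p.query if p.orientation == "forward" else revcomp(p.query)
        s = p.position - 1
        seq[s : s + len(written)] = list(written)
    # a plant overlapping a start codon must preserve it
    for g in spec.genes:
        seq = seqs[(g.genome_id, g.contig_id)]
        t = g.tss - 1
        codon = (
            "".join(seq[t : t + 3])
            if g.strand == "+"
            else revcomp("".join(seq[t - 2 : t + 1]))
        )
        if codon != "ATG":
            raise FixtureBuildError(
                f"gene '{g.gene_id}': a plant overwrote its start codon "
                f"(now {codon})"
            )
    return {k: "".join(v) for k, v in seqs.items()}


def _expected_occurrences(
    spec: FixtureSpec,
) -> dict[str, set[tuple[str, str, int, str]]]:
    expected: dict[str, set] = {}
    for p in spec.plants:
        orient = p.orientation
        if p.query == revcomp(p.query):
            orient = "forward"  # palindromes are reported once, forward
        expected.setdefault(p.query, set()).add(
            (p.genome_id, p.contig_id, p.position - 1, orient)
        )
    return expected


def build_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureBuild:
    """Realize a fixture spec on disk.

    Composes the sequence in memory, verifies planted-site uniqueness
    (redrawing the background up to a bounded retry count if a planted or
    forbidden sequence recurs by chance), checks every plant's intended
    class against the brute-force classifier, and only then writes one
    FASTA+GFF3 pair per genome plus ``ground_truth.tsv``. Deterministic:
    identical spec + seed gives byte-identical files.
    """
    _validate_spec(spec)
    expected = _expected_occurrences(spec)
    sequences = None
    for attempt in range(_MAX_REDRAWS):
        candidate = _compose(spec, attempt)
        ok = True
        for query, exp in expected.items():
            if _naive_occurrences(query, candidate) != exp:
                ok = False
                break
        if ok:
            for forb in spec.forbidden_sequences:
                if _naive_occurrences(forb, candidate):
                    ok = False
                    break
        if ok:
            sequences = candidate
            break
    if sequences is None:
        raise FixtureBuildError(
            f"could not realize fixture in {_MAX_REDRAWS} background redraws; "
            "planted or forbidden sequences keep recurring by chance"
        )

    # ground truth: naive scan + brute-force classification per planted query
    genes_by_contig: dict[tuple[str, str], list[GeneSpec]] = {}
    for g in spec.genes:
        genes_by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)
    gt_rows: list[tuple] = []
    for query in sorted(expected):
        for gid, cid, off, orient in sorted(_naive_occurrences(query, sequences)):
            cls = _classify(
                off, off + len(query), genes_by_contig.get((gid, cid), [])
            )
            gt_rows.append(
                (query, gid, cid, off + 1, off + len(query), orient, cls)
            )
    for p in spec.plants:
        orient = "forward" if p.query == revcomp(p.query) else p.orientation
        row = next(
            r
            for r in gt_rows
            if r[0] == p.query
            and (r[1], r[2], r[3], r[5]) == (p.genome_id, p.contig_id, p.position, orient)
        )
        if row[6] != p.intended_class:
            raise FixtureBuildError(
                f"plant '{p.query}' at {p.contig_id}:{p.position}: intended "
                f"class {p.intended_class} but placement yields {row[6]}"
            )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome_ids = sorted({c.genome_id for c in spec.contigs})
    fasta_paths, gff_paths = [], []
    for gid in genome_ids:
        fasta = out_dir / f"{gid}.fasta"
        with open(fasta, "w") as fh:
            for c in spec.contigs:
                if c.genome_id != gid:
                    continue
                seq = sequences[(gid, c.contig_id)]
                fh.write(f">{c.contig_id}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        gff = out_dir / f"{gid}.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            genes = sorted(
                (g for g in spec.genes if g.genome_id == gid),
                key=lambda g: (g.contig_id, min(s for s, _ in _gene_segments(g))),
            )
            for g in genes:
                segs = _gene_segments(g)
                span = (min(s for s, _ in segs) + 1, max(e for _, e in segs))
                tid = f"{g.gene_id}.t1"
                fh.write(
                    f"{g.contig_id}\tpnascan\tgene\t{span[0]}\t{span[1]}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                fh.write(
                    f"{g.contig_id}\tpnascan\tmRNA\t{span[0]}\t{span[1]}\t.\t"
                    f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
                )
                coding_order = segs if g.strand == "+" else list(reversed(segs))
                phases = []
                done = 0
                for s, e in coding_order:
                    phases.append((3 - done % 3) % 3)
                    done += e - s
                phase_by_seg = dict(zip(map(tuple, coding_order), phases))
                for i, (s, e) in enumerate(segs, start=1):
                    fh.write(
                        f"{g.contig_id}\tpnascan\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tID={tid}.exon{i};Parent={tid}\n"
                    )
                    fh.write(
                        f"{g.contig_id}\tpnascan\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t{phase_by_seg[(s, e)]}\tID={tid}.cds;Parent={tid}\n"
                    )
        fasta_paths.append((gid, fasta))
        gff_paths.append((gid, gff))

    gt_path = out_dir / "ground_truth.tsv"
    with open(gt_path, "w") as fh:
        fh.write(
            "query\tgenome_id\tcontig_id\tstart\tend\torientation\toverlap_class\n"
        )
        for row in gt_rows:
            fh.write("\t".join(map(str, row)) + "\n")

    return FixtureBuild(
        out_dir=out_dir,
        fasta_paths=tuple(fasta_paths),
        gff_paths=tuple(gff_paths),
        ground_truth_path=gt_path,
    )


#: Anti-groEL PNA base sequence (N→C), the reverse complement of the
#: −5..+5 sense window 5'-GTCAAATGGC-3'.
ANTI_GROEL_PNA = "GCCATTTGAC"
#: Its two-mismatch control (substitutions at positions 3 and 9).
CONTROL_PNA = "GCGATTTGTC"
#: One-mismatch variant of the anti-groEL PNA used as the host decoy.
DECOY_VARIANT = "GCCATATGAC"


def default_paper_fixture() -> FixtureSpec:
    """Two-genome fixture mirroring the aphid–*Buchnera* study geometry.

    The 5 kb AT-rich "symbiont" genome carries a groEL-like plus-strand
    gene whose −5..+5 window sense sequence is GTCAAATGGC (so the designed
    antisense PNA is GCCATTTGAC), a pyrG-like gene carrying the same
    10-mer in mid-CDS, and a minus-strand gene with no planted matches.
    The 20 kb "host" genome has five genes (one spliced) and a single
    decoy: the reverse complement of a one-mismatch variant of the PNA at
    a host gene's start site, so the exact scan finds nothing in the host
    but a k=1 scan does. The two-mismatch control sequence is forbidden
    from occurring anywhere.
    """
    window_sense = revcomp(ANTI_GROEL_PNA)  # GTCAAATGGC
    decoy_written = revcomp(DECOY_VARIANT)  # GTCATATGGC
    assert decoy_written[5:8] == "ATG"
    return FixtureSpec(
        seed=20260928,
        contigs=(
            ContigSpec("symbiont", "sym1", 5000, 0.26),
            ContigSpec("host", "host1", 20000, 0.30),
        ),
        genes=(
            GeneSpec("groEL_like", "symbiont", "sym1", "+", 1001, 900),
            GeneSpec("pyrG_like", "symbiont", "sym1", "+", 2501, 600),
            GeneSpec("rpoA_like", "symbiont", "sym1", "-", 4200, 600),
            GeneSpec("hostg1", "host", "host1", "+", 3001, 1500),
            GeneSpec("hostg2", "host", "host1", "-", 6500, 900),
            GeneSpec("hostg3", "host", "host1", "+", 9001, 2400, intron=(300, 200)),
            GeneSpec("hostg4", "host", "host1", "-", 15000, 1200),
            GeneSpec("hostg5", "host", "host1", "+", 17001, 1500),
        ),
        plants=(
            # target site: window sense strand at the groEL-like TSS
            PlantSpec(ANTI_GROEL_PNA, "symbiont", "sym1", 996, "revcomp", CLASS_TSS),
            # the same 10-mer mid-CDS of the pyrG-like gene
            PlantSpec(ANTI_GROEL_PNA, "symbiont", "sym1", 2801, "revcomp", CLASS_CDS),
            # host decoy: 1-mismatch variant at a host gene's start site
            PlantSpec(DECOY_VARIANT, "host", "host1", 2996, "revcomp", CLASS_TSS),
        ),
        forbidden_sequences=(CONTROL_PNA,),
    )
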
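import numpy as np
import pytest

from pnascan import (
    GenomeRecord,
    build_fixture,
    default_paper_fixture,
    load_genome_set,
    revcomp,
)


def naive_scan(query, records):
    """Independent position-by-position oracle for the exact scanner.

    Counts per-base agreement with numpy instead of substring search, so
    it shares no code path with the str.find-based engine under test.
    Returns the same (genome, contig, interval, orientation) tuples.
    """
    hits = []
    rc = revcomp(query)
    passes = [(query, "forward")] + ([(rc, "revcomp")] if rc != query else [])
    L = len(query)
    for rec in records:
        text = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        n = rec.length - L + 1
        for pattern, orientation in passes:
            pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
            for i in range(max(n, 0)):
                if np.array_equal(text[i : i + L], pat):
                    hits.append(
                        (rec.genome_id, rec.contig_id, (i, i + L), orientation)
                    )
    return sorted(hits)


def brute_force_class(start, end, models, sd_window=(-15, -5)):
    """Brute-force hit classification against every segment of every gene
    model (first-base TSS rule); the oracle for annotate_hits."""
    tss, cds, exon, sd = set(), set(), set(), set()
    for m in models:
        if start <= m.tss_position < end:
            tss.add(m.transcript_id)
        if any(start < e and s < end for s, e in m.cds_segments):
            cds.add(m.transcript_id)
        if any(start < e and s < end for s, e in m.exon_segments):
            exon.add(m.transcript_id)
        lo, hi = sd_window
        t = m.tss_position
        sd_iv = (t + lo, t + hi + 1) if m.strand == "+" else (t - hi, t - lo + 1)
        if start < sd_iv[1] and sd_iv[0] < end:
            sd.add(m.transcript_id)
    if tss:
        return "TSS_included", tuple(sorted(tss))
    if cds:
        return "CDS_internal", tuple(sorted(cds))
    if exon:
        return "exon", tuple(sorted(exon))
    if sd:
        return "SD_region", tuple(sorted(sd))
    return "intergenic", ()


def random_genome(rng, genome_id, contig_id, length, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return GenomeRecord(genome_id=genome_id, contig_id=contig_id, sequence=seq)


@pytest.fixture(scope="session")
def paper_fixture(tmp_path_factory):
    """The default two-genome fixture, built once per session."""
    out = tmp_path_factory.mktemp("paper_fixture")
    return build_fixture(default_paper_fixture(), out)


@pytest.fixture(scope="session")
def paper_genome_sets(paper_fixture):
    return [
        load_genome_set(fa, gff, gid)
        for fa, gff, gid in paper_fixture.genome_pairs()
    ]


@pytest.fixture(scope="session")
def symbiont(paper_genome_sets):
    return next(g for g in paper_genome_sets if g.genome_id == "symbiont")


@pytest.fixture(scope="session")
def host(paper_genome_sets):
    return next(g for g in paper_genome_sets if g.genome_id == "host")
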
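"""Optional check against the real Buchnera aphidicola str. APS genome.

Requires locally downloaded files (network access is needed once to fetch
them, e.g. from NCBI for accession NC_002528.1):

    python scripts/buchnera_check.py --fasta NC_002528.1.fasta --gff NC_002528.1.gff3

Verifies that the groEL CDS is annotated at 18,715..20,361, that the
anti-groEL PNA GCCATTTGAC has its only TSS-included hit at groEL plus a
CDS-internal hit inside pyrG, and that the two-mismatch control
GCGATTTGTC has no TSS-included hit. With --host-fasta/--host-gff it also
reports (without asserting) the number of host genes with CDS overlap for
each query and the annotation files used.
"""

from __future__ import annotations

import argparse
import sys

from pnascan import load_genome_set, scan_holo_genome

PNA = "GCCATTTGAC"
CONTROL = "GCGATTTGTC"
GROEL_START_1BASED = 18_715
GROEL_END_1BASED = 20_361


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fasta", required=True, help="NC_002528.1 FASTA")
    ap.add_argument("--gff", required=True, help="NC_002528.1 GFF3")
    ap.add_argument("--host-fasta", help="A. pisum genome FASTA (optional)")
    ap.add_argument("--host-gff", help="A. pisum annotation GFF3 (optional)")
    args = ap.parse_args()

    buchnera = load_genome_set(args.fasta, args.gff, "buchnera")
    groel = [
        m
        for m in buchnera.annotations.gene_models.values()
        if m.cds_segments[0][0] + 1 == GROEL_START_1BASED
        and m.cds_segments[-1][1] == GROEL_END_1BASED
    ]
    print(f"CDS at {GROEL_START_1BASED}..{GROEL_END_1BASED}: "
          f"{[m.transcript_id for m in groel] or 'NOT FOUND'}")

    sets = [buchnera]
    if args.host_fasta and args.host_gff:
        sets.append(load_genome_set(args.host_fasta, args.host_gff, "host"))

    annotated, summary = scan_holo_genome(
        [("PNA_GroEL", PNA), ("PNA_mm", CONTROL)], sets
    )
    print(summary.to_string(index=False))
    ok = True
    tss_hits = [a for a in annotated
                if a.tss_included and a.hit.genome_id == "buchnera"
                and a.hit.query_id == "PNA_GroEL"]
    print("PNA_GroEL TSS-included Buchnera hits:",
          [(a.hit.interval, a.gene_ids) for a in tss_hits])
    ok &= len(tss_hits) == 1 and bool(groel)
    cds_hits = [a for a in annotated
                if a.overlap_class == "CDS_internal"
                and a.hit.genome_id == "buchnera" and a.hit.query_id == "PNA_GroEL"]
    print("PNA_GroEL CDS-internal Buchnera hits (expect pyrG):",
          [(a.hit.interval, a.gene_ids) for a in cds_hits])
    control_tss = [a for a in annotated if a.tss_included and a.hit.query_id == "PNA_mm"]
    print("PNA_mm TSS-included hits (expect none):",
          [(a.hit.genome_id, a.hit.interval, a.gene_ids) for a in control_tss])
    ok &= not control_tss
    print("RESULT:", "ok" if ok else "MISMATCH")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
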
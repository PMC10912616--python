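# pnascan

Antisense PNA design and holo-genome off-target scanning for
host–symbiont systems.

Peptide nucleic acids (PNAs) conjugated to cell-penetrating peptides can
silence genes of bacteria that cannot be cultured or transformed — such
as *Buchnera aphidicola*, the obligate endosymbiont of the pea aphid —
by hybridizing to an mRNA around its start codon. `pnascan` implements
the computational side of such an experiment:

* **design** — extract the −5..+5 translational-start window of a target
  gene from FASTA + GFF3 and emit the reverse-complement 10-mer PNA
  (window bounds configurable);
* **scan** — find every exact (or ≤k-mismatch) occurrence of a query and
  its reverse complement across one or more genomes (the *holo-genome*:
  symbiont + host) and classify each hit as `TSS_included`,
  `CDS_internal`, `exon`, `SD_region` or `intergenic`;
* **control** — generate mismatch-control PNAs at exactly two (by
  default) substitutions from the active PNA and validate that they have
  no perfect match covering any translational start site;
* **simulate** — build small deterministic annotated genomes with
  planted query occurrences and exact ground truth, for testing and
  demonstration without downloads.

A hit is "TSS included" when its footprint covers the first base of a
start codon (here TSS = translational start site). Such hits predict
silencing; matches internal to a coding region are reported but
tolerated, mirroring how a perfect mid-CDS match in an untargeted gene
need not affect its expression.

## Worked example

Build the bundled two-genome fixture (an AT-rich 5 kb "symbiont" with a
groEL-like target gene and a 20 kb "host"), design the PNA, and scan:

```sh
pnascan simulate --default-paper-fixture --out-dir fx
pnascan design --fasta fx/symbiont.fasta --gff fx/symbiont.gff3 \
    --genome-id symbiont --transcript groEL_like.t1 --out design.tsv
pnascan scan --query GCCATTTGAC --query GCGATTTGTC \
    --genome fx/symbiont.fasta,fx/symbiont.gff3,symbiont \
    --genome fx/host.fasta,fx/host.gff3,host --out report.tsv
```

`design.tsv` contains the designed PNA — the reverse complement of the
target's start window:

```
pna_id              transcript_id  contig_id  strand  window_start  window_end  sense_sequence  pna_sequence
PNA_groEL_like.t1   groEL_like.t1  sym1       +       996           1005        GTCAAATGGC      GCCATTTGAC
```

and the scan log summarizes (stderr):

```
INFO pnascan: query GCCATTTGAC in genome host: 0 hits, 0 TSS_included, 0 genes with CDS overlap
INFO pnascan: query GCCATTTGAC in genome symbiont: 2 hits, 1 TSS_included, 2 genes with CDS overlap
INFO pnascan: query GCGATTTGTC in genome host: 0 hits, 0 TSS_included, 0 genes with CDS overlap
INFO pnascan: query GCGATTTGTC in genome symbiont: 0 hits, 0 TSS_included, 0 genes with CDS overlap
```

Reading: the active PNA GCCATTTGAC matches its own target's start site
(the one `TSS_included` hit) plus one mid-CDS site in an untargeted
pyrG-like gene — reported, but not disqualifying — and nothing in the
host; the two-mismatch control GCGATTTGTC (substitutions at positions 3
and 9) matches nothing anywhere, which is exactly what validates it as a
negative control:

```sh
pnascan control --parent GCCATTTGAC \
    --genome fx/symbiont.fasta,fx/symbiont.gff3,symbiont \
    --genome fx/host.fasta,fx/host.gff3,host --out controls.tsv
```

ranks candidate controls by validation status, off-target CDS hits and
GC similarity to the parent.

To run the same checks against the real *Buchnera* genome (GenBank
NC_002528.1, groEL CDS at 18,715–20,361), download its FASTA + GFF3 and
use `scripts/buchnera_check.py`.

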
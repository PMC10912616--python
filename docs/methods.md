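# Methods

## Problem and model

`pnascan` supports antisense knockdown experiments against bacterial
genes — in particular genes of unculturable endosymbionts such as
*Buchnera aphidicola* inside its aphid host — using peptide nucleic acids
(PNAs). A PNA silences translation by hybridizing to the mRNA around the
start codon; the design rule implemented here takes the sense-strand
window from `upstream` bases 5' of the start codon through `downstream`
bases beginning at its first base (defaults −5..+5, giving a 10-mer,
the length range at which CPP-conjugated PNAs are taken up efficiently
by bacteria) and emits its reverse complement as the PNA base sequence.
A PNA written N-terminus→C-terminus is identified with the antisense DNA
strand written 5'→3'; no melting-temperature model is implemented (Tm is
accepted only as opaque user metadata, since no formula is pinned down
for the published values), and conjugates (cell-penetrating peptide,
fluorophore, amide) are opaque labels.

Because a 10-mer recurs frequently by chance, specificity is assessed by
a *holo-genome* scan: every exact occurrence of the query or its reverse
complement across the symbiont and host genomes is reported and
classified by genomic context. The decisive class is whether a hit's
footprint covers a translational start site (TSS — throughout this
package the first base of a start codon, not a transcription start);
such hits predict silencing, while matches internal to a coding region
are tolerated. Mismatch controls must differ from the active PNA at two
or more positions (a single mismatch can still permit binding at reduced
affinity) and must have no perfect TSS-covering match anywhere in the
holo-genome.

## Coordinates and conventions

* Internal intervals are 0-based half-open; all file I/O (GFF3 in,
  report TSV out) is 1-based inclusive. The conversion is self-inverse:
  GFF `a..b` → internal `[a−1, b)` → reported `a..b`.
* TSS per strand: smallest CDS start (+), largest CDS end − 1 (−).
  For a minus-strand gene the −u..+d window therefore occupies genomic
  `[tss−d+1, tss+u+1)` and its sense sequence is the reverse complement
  of that slice, so the start codon always sits at sense offset `u`.
* Soft-masked (lowercase) sequence is uppercased and treated as
  unmasked; the scan is genome-wide with no masking.
* Transcripts without exon rows (common in bacterial GFFs) inherit their
  CDS segments as exons. GFF parent resolution order is
  `Parent → ID → gene/locus_tag`, logged when a fallback is used.
* Gene-model keys are `(genome_id, transcript_id)`, so independently
  annotated genomes may reuse transcript ids.

## Scanning

* Orientation is reported against the plus-strand text: `forward` means
  the query occurs as written, `revcomp` means its reverse complement
  does (the biologically active case for an antisense PNA, whose reverse
  complement lies in a transcript's sense strand). Overlapping and
  self-overlapping occurrences are all reported; a palindromic query is
  reported once per position, as `forward`.
* The engine is an overlap-aware `str.find` loop per query and
  orientation; correctness is defined by a naive position-by-position
  scan, which the test suite keeps as an independent oracle (together
  with a strand-symmetry property: scanning the reverse-complemented
  genome maps `[s,e)` to `[L−e,L−s)` with orientation flipped).
* Genome ambiguity codes (N etc.) match nothing in exact mode; an
  opt-in IUPAC mode expands them to character classes.
* Mismatch search is Hamming (substitutions only, no indels — PNA:RNA
  duplex mismatches are substitutional), implemented as vectorized
  per-column mismatch counting; `k = 0` reproduces the exact search and
  the hit set is monotone in `k`. An ambiguous genome base counts as a
  mismatch unless IUPAC mode is on.

## Hit classification

Precedence `TSS_included > CDS_internal > exon > SD_region >
intergenic`; `gene_ids` lists only the transcripts contributing the
winning class, so it is empty exactly for intergenic hits.

* TSS rule (default `first-base`): a hit is TSS-included iff its
  footprint contains the *first* base of a start codon — unambiguous and
  strand-symmetric. The alternative `any-start-codon-base` rule accepts
  any of the three codon bases; both are exposed because "overlaps a
  start site" admits either reading.
* Shine-Dalgarno window: no canonical coordinates exist, so the default
  is coding-strand offsets −15..−5 relative to the start codon's first
  base (the canonical placement of the purine-rich ribosome-binding
  motif in bacteria), configurable via `--sd-window`; it is a distinct
  class, never merged into TSS_included.
* The per-(query, genome) summary column `n_genes_cds_overlap` counts
  distinct transcripts whose CDS overlaps any hit in either orientation —
  the closest computable reading of "genes with matches within coding
  regions" used to quantify host off-targets.

## Control generation

Controls are enumerated at Hamming distance exactly `min_mismatches`
(default 2 — the published control used exactly two substitutions, and
larger distances drift in base composition), over all position
combinations (terminal positions included) and all three alternative
bases per position; `--at-least` relaxes to ≥. Ranking is deterministic:
validation passes first, then fewer CDS-internal perfect hits across
genomes, then GC content closest to the parent (a proxy for similar Tm),
then lexicographic sequence. Validation passes iff the candidate has
zero perfect TSS-included hits in every scanned genome; CDS-internal
hits are counted but not disqualifying.

## Synthetic fixtures

The fixture generator emits small annotated genomes with *planted* query
occurrences and a ground-truth table computed by a naive scan plus
brute-force classification of the emitted sequence — so the ground truth
is exact by construction, not probabilistic: if a planted or forbidden
sequence recurs by chance in the i.i.d. random background, the
background is redrawn (bounded retries), and every plant's intended
class is checked before any file is written. Identical spec + seed gives
byte-identical FASTA/GFF3/TSV output.

The default fixture mirrors the geometry of the aphid–*Buchnera* study:
a 5 kb "symbiont" contig at GC 0.26 (Buchnera-like composition) with a
plus-strand groEL-like target whose −5..+5 window reverse-complements to
GCCATTTGAC, a pyrG-like gene carrying the same 10-mer mid-CDS, and a
minus-strand gene; plus a 20 kb "host" contig at GC 0.30 with five genes
(one spliced) whose only near-match is a one-mismatch decoy at a host
gene's start site, so the exact scan finds nothing in the host but a
k=1 scan finds exactly one TSS hit. The two-mismatch control sequence
GCGATTTGTC is forbidden from occurring anywhere. The fixture seed
(20260928) is fixed in the spec for reproducibility. Contig sizes are
kept in the kilobase range so the whole suite and the acceptance script
run in seconds; the scanner itself is linear in genome size.

What the fixture does *not* emulate: real gene density, codon structure
and stop codons, repeats, operons, or a realistically sized host genome.
Passing fixture tests therefore demonstrates coordinate and
classification correctness, not performance or biological hit rates on
real assemblies; `scripts/buchnera_check.py` runs the same checks
against the real *Buchnera* record when the files are available locally.

## Numerical and degenerate-input choices

* Queries must be non-empty and over {A,C,G,T}; a query longer than
  every contig yields an empty result, not an error.
* `max_mismatches` must be below the query length; `min_mismatches = 0`
  for controls is rejected (it would return the parent).
* Report rows sort by (genome_id, contig_id, start, orientation);
  control candidates by the rank key above — all ties broken
  lexicographically, so every output is byte-reproducible.
* Windows that would extend past a contig end are an error ("window out
  of bounds"); `downstream < 3` is rejected so the start codon is always
  inside a designed window.

## Known limitations

No thermodynamic ranking, RNA secondary-structure accessibility, or
local-alignment (BLAST-like) screening; no GenBank/GTF parsing or
compressed-index support; spliced-transcript window extraction is
flagged (`crosses_splice_junction`) rather than resequenced across the
junction. Host off-target counts depend on the annotation release used
and are therefore reported, not asserted, by the real-genome script.
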
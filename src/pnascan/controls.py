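"""Mismatch-control PNA generation and holo-genome validation.

A mismatch control must differ from its parent PNA at two or more
positions — a single-base mismatch can still permit binding at reduced
affinity — and must show no perfect match (in either orientation) at any
translational start site across the scanned genomes. Matches internal to
a CDS are tolerated, as they are for the active PNA, but counted and used
for ranking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

from pnascan.design import PNAOligo, gc_fraction
from pnascan.errors import PnascanError
from pnascan.scan import CLASS_CDS, scan_holo_genome

VALIDATION_UNVALIDATED = "unvalidated"
VALIDATION_PASS = "pass"
VALIDATION_FAIL = "fail"


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise PnascanError(
            f"hamming distance requires equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def mismatch_positions(a: str, b: str) -> tuple[int, ...]:
    """1-based positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise PnascanError(
            f"mismatch positions require equal lengths, got {len(a)} and {len(b)}"
        )
    return tuple(i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y)


@dataclass(frozen=True)
class ControlCandidate:
    """A mismatched variant of a parent PNA with its validation status."""

    parent_id: str
    parent_sequence: str
    base_sequence: str
    mismatch_positions: tuple[int, ...]
    hamming: int
    validation: str = VALIDATION_UNVALIDATED
    fail_reason: str | None = None
    n_tss_hits: int | None = None
    n_cds_hits: int | None = None
    cds_hits_per_genome: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.base_sequence) != len(self.parent_sequence):
            raise PnascanError("candidate and parent lengths differ")
        got = mismatch_positions(self.parent_sequence, self.base_sequence)
        if got != self.mismatch_positions or len(got) != self.hamming:
            raise PnascanError(
                f"candidate '{self.base_sequence}': inconsistent mismatch bookkeeping"
            )

    @property
    def gc_delta(self) -> float:
        """GC-content difference to the parent (proxy for similar Tm)."""
        return gc_fraction(self.base_sequence) - gc_fraction(self.parent_sequence)

    @property
    def rank_key(self) -> tuple:
        """Deterministic ordering: validated passes first, then fewer
        CDS-internal perfect hits, then GC content closest to parent,
        then lexicographic sequence."""
        validation_rank = {VALIDATION_PASS: 0, VALIDATION_UNVALIDATED: 1,
                           VALIDATION_FAIL: 2}[self.validation]
        cds = self.n_cds_hits if self.n_cds_hits is not None else math.inf
        return (validation_rank, cds, abs(self.gc_delta), self.base_sequence)


def _parent_pair(parent: PNAOligo | tuple[str, str] | str) -> tuple[str, str]:
    if isinstance(parent, PNAOligo):
        return parent.pna_id, parent.base_sequence
    if isinstance(parent, str):
        return parent, parent
    return parent


def generate_controls(
    parent: PNAOligo | tuple[str, str] | str,
    min_mismatches: int = 2,
    max_candidates: int | None = None,
    at_least: bool = False,
) -> list[ControlCandidate]:
    """Enumerate mismatch controls for a parent PNA in rank order.

    Default policy: candidates at Hamming distance *exactly*
    ``min_mismatches`` (2 by default), enumerating all position
    combinations and all three alternative bases per mutated position,
    terminal positions included. ``at_least=True`` relaxes to distances
    ``min_mismatches..length``, enumerated in increasing distance. The
    parent itself is never emitted; output is truncated at
    ``max_candidates`` after ranking.
    """
    parent_id, seq = _parent_pair(parent)
    L = len(seq)
    if min_mismatches < 1:
        raise PnascanError(
            "min_mismatches must be >= 1 (0 would return the parent itself)"
        )
    if min_mismatches >= L:
        raise PnascanError(
            f"min_mismatches ({min_mismatches}) must be < parent length ({L})"
        )
    distances = range(min_mismatches, L) if at_least else (min_mismatches,)
    out: list[ControlCandidate] = []
    for m in distances:
        tier: list[ControlCandidate] = []
        for positions in itertools.combinations(range(L), m):
            alt_sets = [
                [b for b in "ACGT" if b != seq[p]] for p in positions
            ]
            for subs in itertools.product(*alt_sets):
                cand = list(seq)
                for p, b in zip(positions, subs):
                    cand[p] = b
                tier.append(
                    ControlCandidate(
                        parent_id=parent_id,
                        parent_sequence=seq,
                        base_sequence="".join(cand),
                        mismatch_positions=tuple(p + 1 for p in positions),
                        hamming=m,
                    )
                )
        tier.sort(key=lambda c: c.rank_key)
        out.extend(tier)
        if max_candidates is not None and len(out) >= max_candidates:
            break
    if max_candidates is not None:
        out = out[:max_candidates]
    return out


def validate_control(
    candidate: ControlCandidate,
    genome_sets: Sequence,
    sd_window: tuple[int, int] = (-15, -5),
    tss_rule: str = "first-base",
) -> ControlCandidate:
    """Scan a candidate across the holo-genome and set its validation.

    Passes iff the candidate has zero perfect TSS_included hits in every
    genome; CDS-internal perfect hits do not fail a candidate but are
    counted for ranking. Deterministic and idempotent for fixed genomes.
    """
    query_id = f"{candidate.parent_id}_mm"
    annotated, summary = scan_holo_genome(
        [(query_id, candidate.base_sequence)],
        genome_sets,
        max_mismatches=0,
        sd_window=sd_window,
        tss_rule=tss_rule,
    )
    n_tss = int(summary["n_TSS_included"].sum())
    cds_per_genome = tuple(
        (row.genome_id, sum(
            1
            for a in annotated
            if a.overlap_class == CLASS_CDS and a.hit.genome_id == row.genome_id
        ))
        for row in summary.itertuples()
    )
    n_cds = sum(n for _, n in cds_per_genome)
    fail_reason = None
    if n_tss > 0:
        first = next(a for a in annotated if a.tss_included)
        fail_reason = (
            f"perfect TSS match in genome '{first.hit.genome_id}' at "
            f"{first.hit.contig_id}:{first.hit.interval[0] + 1} "
            f"(gene {','.join(first.gene_ids)})"
        )
    return replace(
        candidate,
        validation=VALIDATION_FAIL if n_tss else VALIDATION_PASS,
        fail_reason=fail_reason,
        n_tss_hits=n_tss,
        n_cds_hits=n_cds,
        cds_hits_per_genome=cds_per_genome,
    )
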
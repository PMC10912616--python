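import numpy as np
import pytest

from pnascan import (
    AnnotationSet,
    GenomeRecord,
    PnascanError,
    annotate_hits,
    find_exact_matches,
    find_mismatch_matches,
    revcomp,
    scan_holo_genome,
)
from pnascan.genome_io import GeneModel
from tests.conftest import brute_force_class, naive_scan, random_genome


def rec(seq, genome="g", contig="c"):
    return GenomeRecord(genome, contig, seq)


class TestExactMatches:
    def test_planted_revcomp_occurrence(self):
        hits = find_exact_matches("GCCATTTGAC", [rec("TTGTCAAATGGCTT")])
        assert [(h.interval, h.orientation) for h in hits] == [((2, 12), "revcomp")]

    def test_overlapping_occurrences_both_orientations(self):
        hits = find_exact_matches("ATATA", [rec("ATATATATAT")])
        got = sorted((h.interval[0], h.orientation) for h in hits)
        assert got == [
            (0, "forward"), (1, "revcomp"), (2, "forward"),
            (3, "revcomp"), (4, "forward"), (5, "revcomp"),
        ]

    def test_palindrome_reported_once_forward(self):
        # ACGT is its own reverse complement
        hits = find_exact_matches("ACGT", [rec("ACGTACGT")])
        assert [(h.interval[0], h.orientation) for h in hits] == [
            (0, "forward"), (4, "forward"),
        ]

    def test_absent_query_gives_empty_list(self):
        assert find_exact_matches("GGGGGG", [rec("ATATATAT")]) == []

    def test_query_longer_than_contig_is_empty_not_error(self):
        assert find_exact_matches("ACGTACGTACGT", [rec("ACGT")]) == []

    def test_empty_query_rejected(self):
        with pytest.raises(PnascanError, match="empty query"):
            find_exact_matches("", [rec("ACGT")])

    def test_genome_n_never_matches_by_default(self):
        genome = [rec("AANGT")]
        assert find_exact_matches("AAAGT", genome) == []
        # IUPAC mode expands genome codes to character classes
        hits = find_exact_matches("AAAGT", genome, iupac=True)
        assert [(h.interval, h.orientation) for h in hits] == [((0, 5), "forward")]

    def test_multi_query_multi_contig_sorted(self):
        genomes = [rec("GCCATTTGAC", contig="c2"), rec("GTCAAATGGC", contig="c1")]
        hits = find_exact_matches(["GCCATTTGAC"], genomes)
        assert [(h.contig_id, h.orientation) for h in hits] == [
            ("c1", "revcomp"), ("c2", "forward"),
        ]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        genomes = [
            random_genome(rng, "g", f"c{i}", int(rng.integers(200, 2000)), gc=0.4)
            for i in range(2)
        ]
        for _ in range(10):
            L = int(rng.integers(4, 9))
            query = "".join(rng.choice(list("ACGT"), size=L))
            got = sorted(
                (h.genome_id, h.contig_id, h.interval, h.orientation)
                for h in find_exact_matches(query, genomes)
            )
            assert got == naive_scan(query, genomes)

    @pytest.mark.parametrize("seed", range(3))
    def test_strand_symmetry(self, seed):
        """Scanning the reverse-complemented genome maps [s,e) to
        [L-e, L-s) with orientation flipped."""
        rng = np.random.default_rng(100 + seed)
        g = random_genome(rng, "g", "c", 3000, gc=0.45)
        g_rc = GenomeRecord("g", "c", revcomp(g.sequence))
        query = "".join(rng.choice(list("ACGT"), size=7))
        fwd = find_exact_matches(query, [g])
        rev = find_exact_matches(query, [g_rc])
        L = g.length
        flip = {"forward": "revcomp", "revcomp": "forward"}
        mapped = sorted(
            ((L - h.interval[1], L - h.interval[0]), flip[h.orientation])
            for h in fwd
        )
        assert mapped == sorted((h.interval, h.orientation) for h in rev)


class TestMismatchMatches:
    def test_k0_equals_exact_search(self):
        genomes = [rec("TTGTCAAATGGCTTGCCATTTGAC")]
        exact = find_exact_matches("GCCATTTGAC", genomes)
        k0 = find_mismatch_matches("GCCATTTGAC", genomes, 0)
        assert k0 == exact

    def test_hand_enumerated_single_mismatch(self):
        hits = find_mismatch_matches("AAAAT", [rec("AAAAAAAAAA")], 1)
        fwd = [(h.interval[0], h.mismatches) for h in hits if h.orientation == "forward"]
        assert fwd == [(i, 1) for i in range(6)]
        # reverse complement ATTTT is 1-mismatch away at no position
        assert all(h.orientation == "forward" for h in hits)

    def test_planted_two_mismatch_site(self):
        # exactly 2 substitutions from the query: invisible at k=1, found at k=2
        genomes = [rec("TTTTGCGATTTGTCTTTT")]
        assert find_mismatch_matches("GCCATTTGAC", genomes, 1) == []
        hits = find_mismatch_matches("GCCATTTGAC", genomes, 2)
        assert [(h.interval, h.mismatches) for h in hits] == [((4, 14), 2)]

    def test_monotone_in_k(self):
        rng = np.random.default_rng(3)
        genomes = [random_genome(rng, "g", "c", 4000, gc=0.3)]
        query = "GCCATTTGAC"
        previous = set()
        for k in range(0, 6):
            hits = {
                (h.interval, h.orientation)
                for h in find_mismatch_matches(query, genomes, k)
            }
            assert previous <= hits
            previous = hits

    def test_k_at_least_query_length_rejected(self):
        with pytest.raises(PnascanError, match="max_mismatches"):
            find_mismatch_matches("ACGTA", [rec("ACGT")], 5)


def build_annotation(models, seq_len=300):
    genomes = [GenomeRecord("g", "c", "A" * seq_len)]
    return AnnotationSet({("g", m.transcript_id): m for m in models}, genomes)


def gene(tid, strand, cds, exons=None):
    return GeneModel(
        gene_id=tid, transcript_id=tid, genome_id="g", contig_id="c",
        strand=strand, cds_segments=tuple(cds), exon_segments=tuple(exons or cds),
    )


def hit(s, e, genome="g", contig="c"):
    from pnascan.scan import HitRecord

    return HitRecord("q", genome, contig, (s, e), "forward")


class TestAnnotateHits:
    def test_hit_containing_tss_first_base(self):
        ann = build_annotation([gene("t1", "+", [(7, 100)])])
        (res,) = annotate_hits([hit(2, 12)], ann)
        assert res.overlap_class == "TSS_included"
        assert res.tss_included
        assert res.gene_ids == ("t1",)

    def test_mid_cds_hit_is_cds_internal(self):
        # the pyrG-like case: perfect match in the middle of a coding region
        ann = build_annotation([gene("t1", "+", [(10, 200)])])
        (res,) = annotate_hits([hit(80, 90)], ann)
        assert res.overlap_class == "CDS_internal"
        assert not res.tss_included

    def test_intergenic_hit_has_empty_gene_ids(self):
        ann = build_annotation([gene("t1", "+", [(100, 200)])])
        (res,) = annotate_hits([hit(10, 20)], ann)
        assert res.overlap_class == "intergenic"
        assert res.gene_ids == ()

    def test_sd_region_default_window(self):
        # plus strand, tss=100: SD footprint [85, 96)
        ann = build_annotation([gene("t1", "+", [(100, 200)])])
        (res,) = annotate_hits([hit(86, 94)], ann)
        assert res.overlap_class == "SD_region"
        (res,) = annotate_hits([hit(70, 85)], ann)
        assert res.overlap_class == "intergenic"

    def test_sd_region_minus_strand(self):
        # minus strand, tss=199: SD footprint [204, 215)
        ann = build_annotation([gene("t1", "-", [(100, 200)])])
        (res,) = annotate_hits([hit(205, 212)], ann)
        assert res.overlap_class == "SD_region"

    def test_exon_class_when_exon_extends_past_cds(self):
        ann = build_annotation([gene("t1", "+", [(100, 200)], exons=[(80, 200)])])
        (res,) = annotate_hits([hit(82, 90)], ann)
        assert res.overlap_class == "exon"

    def test_tss_precedence_over_cds(self):
        ann = build_annotation(
            [gene("t1", "+", [(7, 100)]), gene("t2", "+", [(0, 50)])]
        )
        (res,) = annotate_hits([hit(2, 12)], ann)
        assert res.overlap_class == "TSS_included"
        assert res.gene_ids == ("t1",)  # only the class winner contributes

    def test_any_start_codon_base_rule(self):
        ann = build_annotation([gene("t1", "+", [(12, 99)])])
        # hit covers base 13 (2nd codon base) but not the first base
        (res,) = annotate_hits([hit(13, 20)], ann, tss_rule="first-base")
        assert res.overlap_class == "CDS_internal"
        (res,) = annotate_hits([hit(13, 20)], ann, tss_rule="any-start-codon-base")
        assert res.overlap_class == "TSS_included"

    def test_unknown_contig_rejected(self):
        ann = build_annotation([gene("t1", "+", [(0, 99)])])
        with pytest.raises(PnascanError, match="unknown contig"):
            annotate_hits([hit(0, 5, contig="nope")], ann)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        models = []
        for i in range(15):
            s = int(rng.integers(0, 900))
            e = min(s + 3 * int(rng.integers(2, 40)), 999)
            models.append(gene(f"t{i}", "+-"[int(rng.integers(2))], [(s, e)]))
        ann = build_annotation(models, seq_len=1000)
        for _ in range(100):
            qs = int(rng.integers(0, 990))
            qe = qs + int(rng.integers(1, 12))
            (res,) = annotate_hits([hit(qs, qe)], ann)
            cls, genes = brute_force_class(qs, qe, models)
            assert (res.overlap_class, res.gene_ids) == (cls, genes)


class TestScanHoloGenome:
    def test_planted_tss_in_one_genome_only(self, paper_genome_sets):
        _, summary = scan_holo_genome("GCCATTTGAC", paper_genome_sets)
        by_genome = summary.set_index("genome_id")
        assert by_genome.loc["symbiont", "n_TSS_included"] == 1
        assert by_genome.loc["host", "n_TSS_included"] == 0

    def test_zero_hit_query_gets_zero_rows(self, paper_genome_sets):
        _, summary = scan_holo_genome("GGGGGGGGGG", paper_genome_sets)
        assert (summary[["n_hits", "n_TSS_included", "n_genes_cds_overlap"]] == 0).all().all()
        assert len(summary) == 2  # every (query, genome) pair present

    def test_same_genome_twice_doubles_counts(self, symbiont):
        _, once = scan_holo_genome("GCCATTTGAC", [symbiont])
        _, twice = scan_holo_genome("GCCATTTGAC", [symbiont, symbiont])
        assert twice["n_hits"].sum() == 2 * once["n_hits"].sum()
        assert twice["n_TSS_included"].sum() == 2 * once["n_TSS_included"].sum()

    def test_empty_genome_sets_rejected(self):
        with pytest.raises(PnascanError, match="at least one genome set"):
            scan_holo_genome("ACGT", [])
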
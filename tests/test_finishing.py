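"""Genome walking, merging, scaffolding and depth computation."""

import numpy as np
import pytest

from pfinish import (
    AmbiguousMergeError,
    Contig,
    ReadSet,
    compute_depth,
    extend_contig,
    fragment_into_contigs,
    scaffold_by_reference,
    simulate_reads,
    walk_close_gaps,
)
from pfinish import canonical_form
from pfinish.sequtils import random_seq, revcomp


def tiled_reads(genome, read_len, step, circular=False):
    """Error-free reads tiling a sequence at a fixed step (oracle pile)."""
    src = genome + genome[:read_len] if circular else genome
    limit = len(genome) if circular else len(genome) - read_len + 1
    reads = [
        (f"r{i}", src[i : i + read_len], "I" * read_len)
        for i in range(0, limit, step)
    ]
    return ReadSet(reads=reads, read_len=read_len)


class TestExtendContig:
    def test_no_overlapping_read_leaves_contig_unchanged(self, random_dna):
        contig = Contig("c", random_dna(300))
        reads = tiled_reads(random_dna(500), 60, 10)
        out = extend_contig(contig, reads, "right")
        assert out.sequence == contig.sequence
        assert out.provenance[-1]["bases_added"] == 0

    def test_repeated_extension_reconstructs_reference(self, random_dna):
        # oracle: the reference string itself
        ref = random_dna(200)
        reads = tiled_reads(ref, 50, 10)
        contig = Contig("c", ref[:100])
        # error-free reads: a single read may carry the final bases
        out = extend_contig(contig, reads, "right", min_overlap=30,
                            min_support=1)
        assert out.sequence == ref

    def test_left_extension_mirrors_right(self, random_dna):
        ref = random_dna(200)
        reads = tiled_reads(ref, 50, 10)
        contig = Contig("c", ref[100:])
        out = extend_contig(contig, reads, "left", min_overlap=30,
                            min_support=1)
        assert out.sequence == ref

    def test_majority_vote_picks_most_supported_base(self, random_dna):
        # brute-force count over a constructed read pile: 3 vote A, 1 votes C
        stem = random_dna(60)
        good, bad = stem[10:] + "A", stem[10:] + "C"
        reads = ReadSet(
            reads=[("g1", good, "I" * 51), ("g2", good, "I" * 51),
                   ("g3", good, "I" * 51), ("b1", bad, "I" * 51)],
            read_len=51,
        )
        out = extend_contig(Contig("c", stem), reads, "right", min_overlap=30)
        assert out.sequence == stem + "A"

    def test_empty_read_set_is_logged_noop(self, random_dna):
        contig = Contig("c", random_dna(100))
        out = extend_contig(contig, ReadSet(reads=[], read_len=50), "right")
        assert out.sequence == contig.sequence
        assert out.provenance[-1]["bases_added"] == 0

    def test_extension_never_shrinks_contig(self, small_plastome, small_reads):
        p, _ = small_plastome
        contigs, _ = fragment_into_contigs(p, n_contigs=4, min_gap=120, seed=5)
        for c in contigs:
            for side in ("left", "right"):
                assert len(extend_contig(c, small_reads, side)) >= len(c)


class TestWalkCloseGaps:
    def test_recovers_circular_genome_from_fragments(self, small_plastome, small_reads):
        p, _ = small_plastome
        contigs, _ = fragment_into_contigs(p, n_contigs=4, min_gap=120, seed=8)
        assembled, report = walk_close_gaps(contigs, small_reads)
        assert report.circular
        assert len(assembled) == 1
        assert canonical_form(assembled[0].sequence, min_len=500) == canonical_form(
            p.sequence, min_len=500
        )
        assert report.gaps_open == 0

    def test_complete_contig_returned_unchanged(self, small_plastome, small_reads):
        p, _ = small_plastome
        assembled, report = walk_close_gaps([Contig("full", p.sequence)], small_reads)
        assert report.circular
        assert report.rounds == 0
        assert assembled[0].sequence == p.sequence

    def test_withheld_reads_leave_gap_open(self, small_plastome):
        p, _ = small_plastome
        n = len(p.sequence)
        contigs, truth = fragment_into_contigs(p, n_contigs=4, min_gap=120, seed=8)
        gs, ge = truth.extra["gaps"][2]
        reads = simulate_reads([(p.sequence, 1.0)], read_len=100,
                               mean_depth=40, seed=7)

        def touches_gap(start):
            span = {(start + k) % n for k in range(100)}
            gap = {i % n for i in range(gs, gs + (ge - gs) % n)}
            return bool(span & gap)

        keep = [i for i, (_g, s, _st) in enumerate(reads.truth)
                if not touches_gap(s)]
        assembled, report = walk_close_gaps(contigs, reads.subset(keep))
        assert not report.circular
        assert report.gaps_open == 1
        assert len(assembled) == 1  # all other gaps were closed
        assert len(assembled[0].sequence) < n

    def test_ambiguous_merge_partner_raises(self, random_dna):
        shared = random_dna(150)
        a = Contig("a", random_dna(200) + shared)
        b = Contig("b", shared + random_dna(180))
        c = Contig("c", shared + random_dna(220))
        with pytest.raises(AmbiguousMergeError):
            walk_close_gaps([a, b, c], ReadSet(reads=[], read_len=100))

    def test_merge_conserves_sequence_content(self, random_dna):
        # two contigs with a 120 bp exact overlap, no reads involved
        left, mid, right = random_dna(300), random_dna(120), random_dna(300)
        a = Contig("a", left + mid)
        b = Contig("b", mid + right)
        assembled, report = walk_close_gaps([a, b], ReadSet(reads=[], read_len=100))
        assert len(assembled) == 1
        assert assembled[0].sequence == left + mid + right
        assert report.merges[0]["overlap"] == 120


class TestScaffoldByReference:
    def test_recovers_order_and_orientation(self, random_dna):
        ref = random_dna(6000)
        truth = [(200, 1400, False), (1800, 3200, True), (3600, 5600, False)]
        contigs = []
        for i, (s, e, rc) in enumerate(truth):
            seq = ref[s:e]
            contigs.append(Contig(f"c{i}", revcomp(seq) if rc else seq))
        res = scaffold_by_reference(contigs, ref)
        assert [p.contig_id for p in res.placements] == ["c0", "c1", "c2"]
        assert [p.orientation for p in res.placements] == ["+", "-", "+"]
        assert [(p.ref_start, p.ref_end) for p in res.placements] == [
            (s, e) for s, e, _rc in truth
        ]
        assert res.gap_estimates == [400, 400]
        assert not res.unplaced

    def test_single_contig_trivially_placed(self, random_dna):
        ref = random_dna(2000)
        res = scaffold_by_reference([Contig("c", ref[500:1500])], ref)
        assert len(res.placements) == 1 and not res.unplaced

    def test_foreign_contig_reported_unplaced(self, random_dna):
        ref = random_dna(5000)
        contigs = [Contig("good", ref[1000:2500]), Contig("junk", random_dna(1000))]
        res = scaffold_by_reference(contigs, ref)
        assert res.unplaced == ["junk"]


class TestComputeDepth:
    def test_zero_reads_gives_zero_profile(self, random_dna):
        asm = random_dna(500)
        prof = compute_depth(asm, ReadSet(reads=[], read_len=100))
        assert prof.mean_depth == 0.0
        assert prof.uncovered == [(0, 500)]

    def test_tiling_reads_give_exact_arithmetic_mean(self, random_dna):
        # oracle: mean = n * L / G exactly
        genome = random_dna(1200)
        reads = tiled_reads(genome, 100, 50, circular=True)
        prof = compute_depth(genome, reads)
        assert prof.mean_depth == pytest.approx(len(reads) * 100 / 1200)
        assert prof.n_reads_mapped == len(reads)

    def test_simulated_depth_within_three_sigma(self, random_dna):
        genome = random_dna(5000)
        reads = simulate_reads([(genome, 1.0)], read_len=100,
                               mean_depth=50, seed=21)
        prof = compute_depth(genome, reads)
        lam = 50 * len(genome) / 100
        sigma = 50 / np.sqrt(lam)
        assert abs(prof.mean_depth - 50) < 3 * sigma

    def test_depth_conservation(self, small_plastome, small_reads):
        # sum of per-base coverage equals total aligned read bases,
        # even with multi-mapping reads in the IR
        p, _ = small_plastome
        prof = compute_depth(p.sequence, small_reads)
        assert prof.counts.sum() == pytest.approx(prof.total_aligned)

    def test_ir_reads_cover_both_copies(self, small_plastome, small_reads):
        p, _ = small_plastome
        prof = compute_depth(p.sequence, small_reads)
        ira = prof.interval_mean(*p.regions["IRa"])
        irb = prof.interval_mean(*p.regions["IRb"])
        lsc = prof.interval_mean(*p.regions["LSC"])
        # fractional multi-mapping keeps both copies near the genome mean
        assert ira == pytest.approx(lsc, rel=0.15)
        assert irb == pytest.approx(lsc, rel=0.15)
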
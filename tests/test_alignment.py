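"""Augmented reference, affine semi-global scoring, projection and SAM output."""

from __future__ import annotations

import numpy as np
import pytest

from helpers import overlap_affine_score, random_seq
from splicechain.alignment import (
    AlignConfig,
    AugmentedReference,
    ReadAlignment,
    align_read,
    apply_unaligned_threshold,
    build_augmented_reference,
    project_to_genome,
    select_primary,
    sam_record,
    write_sam,
)
from splicechain.chaining import MamChain
from splicechain.index import Exon, IndexConfig, build_index
from splicechain.mam import Mam


def make_index(seq_len=600, exon_ivs=((100, 150), (300, 350))):
    rng = np.random.default_rng(42)
    genome = {"chr1": random_seq(rng, seq_len)}
    exons = {
        Exon("chr1", s, e, frozenset({"g1"}), frozenset({"t1"})) for s, e in exon_ivs
    }
    return build_index(genome, exons, IndexConfig(F=50)), genome


def chain_of(ivs, read_pos=0):
    mams = []
    c = read_pos
    for s, e in ivs:
        mams.append(Mam("chr1", s, e, c, c + (e - s), 1.0))
        c += e - s
    return MamChain(mams, 0.0)


class TestAugmentedReference:
    def test_two_segments_one_junction(self):
        idx, genome = make_index()
        aug = build_augmented_reference(chain_of([(100, 150), (300, 350)]), idx)
        assert len(aug.sequence) == 100
        assert aug.sequence == genome["chr1"][100:150] + genome["chr1"][300:350]
        assert aug.blocks == [(0, 100, 150), (50, 300, 350)]

    def test_single_segment(self):
        idx, genome = make_index()
        aug = build_augmented_reference(chain_of([(100, 150)]), idx)
        assert aug.sequence == genome["chr1"][100:150]
        assert len(aug.blocks) == 1

    def test_adjacent_segments_merge(self):
        idx, genome = make_index(exon_ivs=((100, 150), (150, 200)))
        aug = build_augmented_reference(chain_of([(100, 150), (150, 200)]), idx)
        assert len(aug.blocks) == 1
        assert aug.sequence == genome["chr1"][100:200]


class TestAlignRead:
    def aug(self, seq):
        return AugmentedReference("chr1", seq, [(0, 0, len(seq))])

    def test_identical_sequences_full_match(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 120)
        score, blocks = align_read(seq, self.aug(seq), AlignConfig())
        assert score == 2 * 120
        assert blocks[0].tolist() == [[0, 120]] and blocks[1].tolist() == [[0, 120]]

    def test_single_substitution(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 100)
        read = seq[:50] + ("A" if seq[50] != "A" else "C") + seq[51:]
        score, _ = align_read(read, self.aug(seq), AlignConfig())
        assert score == 2 * 99 - 2

    def test_matches_quadratic_affine_dp_oracle(self):
        rng = np.random.default_rng(3)
        cfg = AlignConfig()
        for _ in range(80):
            ref = random_seq(rng, int(rng.integers(10, 200)))
            read = random_seq(rng, int(rng.integers(10, 200)))
            score, _ = align_read(read, self.aug(ref), cfg)
            expected = overlap_affine_score(
                ref, read, cfg.match, cfg.mismatch, cfg.gap_open, cfg.gap_extend
            )
            assert score == pytest.approx(expected)


class TestProjection:
    def project(self, idx, read, ivs):
        aug = build_augmented_reference(chain_of(ivs), idx)
        score, blocks = align_read(read, aug, AlignConfig())
        return project_to_genome("r1", read, score, blocks, aug)

    def test_perfect_two_exon_read(self):
        idx, genome = make_index()
        read = genome["chr1"][100:150] + genome["chr1"][300:350]
        aln = self.project(idx, read, [(100, 150), (300, 350)])
        assert aln.cigar_string() == "50M150N50M"
        assert aln.start == 100
        assert aln.junctions == [(150, 300)]

    def test_perfect_single_exon_read(self):
        idx, genome = make_index()
        aln = self.project(idx, genome["chr1"][100:150], [(100, 150)])
        assert aln.cigar_string() == "50M"
        assert aln.junctions == []

    def test_deletion_inside_first_exon(self):
        idx, genome = make_index()
        read = (
            genome["chr1"][100:120]
            + genome["chr1"][122:150]
            + genome["chr1"][300:350]
        )
        aln = self.project(idx, read, [(100, 150), (300, 350)])
        assert aln.cigar_string() == "20M2D28M150N50M"
        assert aln.edit_distance == 2

    def test_soft_clips_on_unmatched_read_tail(self):
        idx, genome = make_index()
        rng = np.random.default_rng(9)
        read = genome["chr1"][100:150] + genome["chr1"][300:350] + random_seq(rng, 30)
        aln = self.project(idx, read, [(100, 150), (300, 350)])
        consumed = sum(n for op, n in aln.cigar if op in "MIS")
        assert consumed == len(read)
        assert aln.cigar[-1][0] == "S"


class TestSelectPrimary:
    def aln(self, score, start=0, end_span=100, junctions=()):
        a = ReadAlignment(
            "r", "chr1", start, False, [("M", end_span)], score, 0, "A" * end_span
        )
        a.junctions = list(junctions)
        return a

    def test_highest_score_wins(self):
        alns = select_primary([self.aln(100), self.aln(90)])
        assert alns[0].is_primary and not alns[1].is_primary

    def test_tie_broken_by_genomic_span(self):
        short = self.aln(100, end_span=500)
        long = self.aln(100, end_span=800)
        alns = select_primary([long, short])
        assert short.is_primary and not long.is_primary

    def test_tie_broken_by_annotated_junctions(self):
        ann = {("chr1", 150, 300)}
        a = self.aln(100, junctions=[(150, 300)])
        b = self.aln(100, junctions=[(140, 290)])
        select_primary([b, a], annotated_junctions=ann)
        assert a.is_primary and not b.is_primary


class TestUnalignedThreshold:
    def aln(self, score):
        return ReadAlignment("r", "chr1", 0, False, [("M", 10)], score, 0, "A" * 10)

    def test_below_threshold_unaligned(self):
        a = apply_unaligned_threshold(self.aln(990), 1000, AlignConfig())
        assert a.is_unaligned

    def test_above_threshold_aligned(self):
        a = apply_unaligned_threshold(self.aln(1200), 1000, AlignConfig())
        assert not a.is_unaligned

    def test_zero_fraction_never_unaligned(self):
        cfg = AlignConfig(X_unaligned=0.0)
        assert not apply_unaligned_threshold(self.aln(-5), 1000, cfg).is_unaligned

    def test_quarter_substitution_read_sits_at_boundary(self):
        """25% substitutions with the default scoring meet the threshold exactly."""
        rng = np.random.default_rng(5)
        n = 200
        ref = random_seq(rng, n)
        read = list(ref)
        idxs = rng.choice(n, n // 4, replace=False)
        for i in idxs:
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        read = "".join(read)
        cfg = AlignConfig()
        aug = AugmentedReference("chr1", ref, [(0, 0, n)])
        score, _ = align_read(read, aug, cfg)
        # substitutions only: score = 2*(0.75n) - 2*(0.25n) = n = 0.5*m*n
        assert score >= cfg.X_unaligned * cfg.match * n


class TestSamOutput:
    def test_sam_round_trips_through_pysam(self, tmp_path):
        idx, genome = make_index()
        read = genome["chr1"][100:150] + genome["chr1"][300:350]
        aug = build_augmented_reference(chain_of([(100, 150), (300, 350)]), idx)
        score, blocks = align_read(read, aug, AlignConfig())
        aln = project_to_genome("r1", read, score, blocks, aug)
        aln.is_primary = True
        path = tmp_path / "out.sam"
        write_sam([aln], idx.chrom_lengths, path)

        import pysam

        with pysam.AlignmentFile(str(path), "r") as fh:
            (rec,) = list(fh)
        assert rec.cigarstring == "50M150N50M"
        assert rec.reference_start == 100
        assert rec.query_sequence == read
        assert rec.get_tag("NM") == 0

    def test_unmapped_record_fields(self):
        a = ReadAlignment("r1", "*", 0, False, [], 0, 0, "ACGT", is_unaligned=True)
        fields = sam_record(a).split("\t")
        assert fields[1] == "4" and fields[3] == "0" and fields[5] == "*"

    def test_reverse_flag(self):
        a = ReadAlignment(
            "r1", "chr1", 10, True, [("M", 4)], 8, 0, "ACGT", is_primary=True
        )
        assert int(sam_record(a).split("\t")[1]) & 16
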
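"""Index construction: GTF reading, parts, flanks, segments, small container."""

from __future__ import annotations

import numpy as np
import pytest

from splicechain.index import (
    Exon,
    GtfParseError,
    IndexConfig,
    build_flanks,
    build_index,
    build_parts,
    build_segments,
    load_index,
    read_annotation,
    save_index,
)


def ex(start, end, chrom="chr1", genes=("g1",), txs=("t1",)):
    return Exon(chrom, start, end, frozenset(genes), frozenset(txs))


GTF_LINE = 'chr1\tsrc\texon\t{}\t{}\t.\t+\t.\tgene_id "{}"; transcript_id "{}";\n'


class TestReadAnnotation:
    def test_coordinates_converted_to_zero_based_half_open(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_LINE.format(101, 200, "g1", "t1"))
        (exon,) = read_annotation(p)
        assert (exon.chrom, exon.start, exon.end) == ("chr1", 100, 200)

    def test_identical_intervals_merge_transcript_ids(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            GTF_LINE.format(101, 200, "g1", "t1") + GTF_LINE.format(101, 200, "g1", "t2")
        )
        (exon,) = read_annotation(p)
        assert exon.transcript_ids == {"t1", "t2"}

    def test_empty_gtf_gives_empty_set(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text("# just a comment\n")
        assert read_annotation(p) == set()

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text("chr1\tonly\tthree\n")
        with pytest.raises(GtfParseError, match=":1:"):
            read_annotation(p)

    def test_inverted_exon_rejected_with_warning(self, tmp_path, caplog):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_LINE.format(200, 100, "g1", "t1"))
        with caplog.at_level("WARNING"):
            assert read_annotation(p) == set()
        assert "rejected" in caplog.text


class TestBuildParts:
    @pytest.mark.parametrize(
        "exons,expected",
        [
            ([(100, 200), (150, 250)], [(100, 250)]),
            ([(100, 200), (300, 400)], [(100, 200), (300, 400)]),
            ([(400, 450)], [(400, 450)]),
        ],
    )
    def test_connected_components(self, exons, expected):
        parts = build_parts({ex(s, e) for s, e in exons})
        assert [(p.start, p.end) for p in parts] == expected

    def test_part_records_exon_coordinates(self):
        (part,) = build_parts({ex(100, 200), ex(150, 250)})
        assert part.exon_coords == (100, 150, 200, 250)


class TestBuildFlanks:
    def test_isolated_part_gets_two_flanks(self):
        (part,) = build_parts({ex(1000, 2000)})
        flanks = build_flanks([part], F=300, chrom_length=5000)
        assert [(f.start, f.end) for f in flanks] == [(700, 1000), (2000, 2300)]

    def test_short_gap_becomes_single_flank(self):
        parts = build_parts({ex(1000, 2000), ex(2100, 2500)})
        flanks = build_flanks(parts, F=300, chrom_length=5000)
        assert (2000, 2100) in [(f.start, f.end) for f in flanks]

    def test_part_at_chromosome_start_has_no_left_flank(self):
        (part,) = build_parts({ex(0, 100)})
        flanks = build_flanks([part], F=300, chrom_length=5000)
        assert [(f.start, f.end) for f in flanks] == [(100, 400)]

    def test_all_flanks_at_most_f_and_disjoint_from_parts(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            starts = np.sort(rng.integers(0, 20_000, 6))
            exons = {ex(int(s), int(s) + int(rng.integers(20, 400))) for s in starts}
            parts = build_parts(exons)
            flanks = build_flanks(parts, F=500, chrom_length=25_000)
            ivs = sorted(
                [(p.start, p.end, "p") for p in parts]
                + [(f.start, f.end, "f") for f in flanks]
            )
            assert all(f.end - f.start <= 500 for f in flanks)
            for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
                assert e1 <= s2, "parts/flanks overlap"


class TestBuildSegments:
    def test_long_gaps_become_plain_segments(self):
        # overlapping exons yielding coordinate array [0, 30, 60]
        (part,) = build_parts({ex(0, 30), ex(0, 60)})
        assert part.exon_coords == (0, 30, 60)
        segs = build_segments(part, X_seg=25)
        assert {(s.start, s.end) for s in segs} == {(0, 30), (30, 60)}

    def test_short_pair_extends_upwards(self):
        # coords [0, 10, 40]: pair (0,10) cannot extend down, extends up to 40
        (part,) = build_parts({ex(0, 10), ex(0, 40)})
        assert part.exon_coords == (0, 10, 40)
        segs = build_segments(part, X_seg=25)
        assert {(s.start, s.end) for s in segs} == {(0, 40), (10, 40)}

    def test_whole_part_below_minimum_is_small(self):
        (part,) = build_parts({ex(0, 10)})
        (seg,) = build_segments(part, X_seg=25)
        assert (seg.start, seg.end, seg.is_small) == (0, 10, True)


class TestBuildIndex:
    def make_genome(self, n=2000):
        rng = np.random.default_rng(0)
        return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, n))}

    def test_small_exon_goes_to_container_not_segments(self):
        exons = {
            ex(100, 200, genes=("g1",)),
            ex(300, 308, genes=("g1",)),
            ex(400, 550, genes=("g1",)),
        }
        idx = build_index(self.make_genome(), exons)
        assert any(
            (s.start, s.end) == (300, 308) for s in idx.small_container["g1"]
        )
        assert all((s.start, s.end) != (300, 308) for s in idx.segments["chr1"])

    def test_four_bp_exon_absent_everywhere(self):
        exons = {ex(100, 200), ex(300, 304)}
        idx = build_index(self.make_genome(), exons)
        all_intervals = [(s.start, s.end) for s in idx.segments["chr1"]]
        all_intervals += [
            (s.start, s.end) for segs in idx.small_container.values() for s in segs
        ]
        all_intervals += [(p.start, p.end) for p in idx.parts["chr1"]]
        assert (300, 304) not in all_intervals
        assert [(p.start, p.end) for p in idx.parts["chr1"]] == [(100, 200)]

    def test_missing_chromosome_is_hard_error(self):
        with pytest.raises(KeyError, match="chrMissing"):
            build_index(self.make_genome(), {ex(0, 50, chrom="chrMissing")})

    def test_serialization_round_trip(self, tmp_path):
        exons = {ex(100, 200), ex(300, 308), ex(400, 550)}
        idx = build_index(self.make_genome(), exons)
        save_index(idx, tmp_path / "idx")
        assert load_index(tmp_path / "idx") == idx

    def test_deterministic(self):
        exons = {ex(100, 200), ex(150, 260), ex(400, 550)}
        assert build_index(self.make_genome(), exons) == build_index(
            self.make_genome(), exons
        )


class TestInvariants:
    def random_annotation(self, rng):
        exons = set()
        n_genes = int(rng.integers(1, 6))
        pos = int(rng.integers(0, 500))
        for g in range(n_genes):
            for _ in range(int(rng.integers(1, 5))):
                length = int(rng.integers(5, 300))
                exons.add(
                    ex(pos, pos + length, genes=(f"g{g}",), txs=(f"t{g}",))
                )
                pos += length + int(rng.integers(0, 900))
            pos += int(rng.integers(100, 3000))
        return exons

    def test_disjointness_and_coverage_on_random_annotations(self):
        rng = np.random.default_rng(42)
        genome_len = 60_000
        genome = {"chr1": "A" * genome_len}
        cfg = IndexConfig(F=500)
        for _ in range(200):
            exons = {
                e for e in self.random_annotation(rng) if e.end <= genome_len
            }
            if not exons:
                continue
            idx = build_index(genome, exons, cfg)
            ivs = sorted(
                [(p.start, p.end) for p in idx.parts["chr1"]]
                + [(f.start, f.end) for f in idx.flanks["chr1"]]
            )
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2
            # coverage: every exon >= min_small_exon is in a part and is
            # either covered by regular segments or present in the container
            for e in exons:
                if e.length < cfg.min_small_exon:
                    continue
                assert any(
                    p.start <= e.start and e.end <= p.end for p in idx.parts["chr1"]
                )
                covered = _covered_by(
                    e, [s for s in idx.segments["chr1"]]
                )
                in_container = any(
                    (s.start, s.end) == (e.start, e.end)
                    for g in e.gene_ids
                    for s in idx.small_container.get(g, [])
                )
                assert covered or in_container
            for s in idx.segments["chr1"]:
                assert s.length >= cfg.X_seg


def _covered_by(exon, segments):
    ivs = sorted(
        (max(s.start, exon.start), min(s.end, exon.end))
        for s in segments
        if s.start < exon.end and exon.start < s.end
    )
    pos = exon.start
    for s, e in ivs:
        if s > pos:
            return False
        pos = max(pos, e)
    return pos >= exon.end
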
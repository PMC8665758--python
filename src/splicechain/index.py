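"""Genomic index construction: parts, flanks, segments and the small-exon container.

The index partitions the annotated portion of the genome into three kinds of
intervals:

* **parts** — smallest genomic regions fully covering a connected set of
  overlapping annotated exons; parts are pairwise disjoint;
* **flanks** — unannotated regions of at most ``F`` nt bordering parts,
  disjoint from all parts and from each other, which catch reads that
  slightly overrun annotated gene ends;
* **segments** — sub-intervals of a part delimited by exon start/end
  coordinates; the unit that is later aligned approximately into reads.

Exons and segments shorter than a threshold cannot reliably seed exact
matches, so they are kept out of the regular segment lists and stored in a
per-gene *small container* that is force-included whenever any seed hits the
gene. Exons of 4 bp or less are dropped entirely.

All internal coordinates are 0-based half-open; GTF input is converted from
1-based inclusive on read, SAM output converts back to 1-based on write.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

INDEX_FORMAT_VERSION = 1

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised for a malformed GTF line, naming the offending line number."""


@dataclass(frozen=True)
class Exon:
    """One annotated exon, deduplicated by coordinates across transcripts."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    gene_ids: frozenset[str]
    transcript_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"exon start {self.start} >= end {self.end}")
        if not self.gene_ids:
            raise ValueError("exon must carry at least one gene_id")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Part:
    """Smallest genomic region covering a connected set of overlapping exons."""

    chrom: str
    start: int
    end: int
    exon_coords: tuple[int, ...]  # sorted unique exon start/end coordinates
    gene_ids: frozenset[str]


@dataclass(frozen=True)
class Flank:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Segment:
    """Sub-interval of a part delimited by exon coordinates.

    ``is_small`` marks segments below the seeding-viable length that live in
    the small container instead of the regular per-part segment list.
    """

    chrom: str
    start: int
    end: int
    gene_ids: frozenset[str]
    is_small: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted by start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Ordered (donor, acceptor) intron intervals, 0-based half-open."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass
class IndexConfig:
    """Tunables of index construction.

    F : flank size in nt.
    X_seg : minimum length of a regular segment.
    small_threshold : below this length a segment/exon goes to the small
        container (defaults to X_seg).
    min_small_exon : exons shorter than this are ignored outright.
    """

    F: int = 1000
    X_seg: int = 25
    small_threshold: int | None = None
    min_small_exon: int = 5

    def __post_init__(self) -> None:
        if self.small_threshold is None:
            self.small_threshold = self.X_seg
        if min(self.F, self.X_seg, self.small_threshold, self.min_small_exon) <= 0:
            raise ValueError("all index parameters must be positive")
        if self.min_small_exon > self.small_threshold:
            raise ValueError("min_small_exon must be <= small_threshold")


@dataclass
class GenomeIndex:
    """Parts, flanks, segments, small container and transcript catalog."""

    config: IndexConfig
    chrom_lengths: dict[str, int]
    parts: dict[str, list[Part]]  # chrom -> sorted parts
    flanks: dict[str, list[Flank]]
    segments: dict[str, list[Segment]]  # regular (non-small) segments
    small_container: dict[str, list[Segment]]  # gene_id -> small segments/exons
    transcripts: dict[str, Transcript]
    part_sequences: dict[tuple[str, int], str] = field(default_factory=dict)
    flank_sequences: dict[tuple[str, int], str] = field(default_factory=dict)

    # -- sequence access -------------------------------------------------
    def segment_sequence(self, seg: Segment) -> str:
        """Genomic sequence of a segment, sliced from its containing part."""
        for part in self.parts[seg.chrom]:
            if part.start <= seg.start and seg.end <= part.end:
                s = self.part_sequences[(seg.chrom, part.start)]
                return s[seg.start - part.start : seg.end - part.start]
        raise KeyError(f"segment {seg} not contained in any part")

    def region_sequence(self, chrom: str, start: int, end: int) -> str:
        """Genomic sequence of [start, end), stitched from parts and flanks.

        Raises KeyError if the interval is not fully covered by indexed
        regions (parts and flanks are disjoint but mutually adjacent where
        they border).
        """
        pieces: list[tuple[int, int, str]] = []
        for p in self.parts.get(chrom, []):
            if p.start < end and start < p.end:
                pieces.append((p.start, p.end, self.part_sequences[(chrom, p.start)]))
        for f in self.flanks.get(chrom, []):
            if f.start < end and start < f.end:
                pieces.append((f.start, f.end, self.flank_sequences[(chrom, f.start)]))
        pieces.sort()
        out = []
        pos = start
        for s, e, seq in pieces:
            if s > pos:
                raise KeyError(f"{chrom}:{pos}-{s} not covered by indexed regions")
            if e <= pos:
                continue
            out.append(seq[pos - s : min(e, end) - s])
            pos = min(e, end)
            if pos >= end:
                break
        if pos < end:
            raise KeyError(f"{chrom}:{pos}-{end} not covered by indexed regions")
        return "".join(out)

    def region_tree(self, chrom: str) -> IntervalTree:
        """Interval tree over parts and flanks of one chromosome."""
        tree = IntervalTree()
        for p in self.parts.get(chrom, []):
            tree.addi(p.start, p.end, "part")
        for f in self.flanks.get(chrom, []):
            tree.addi(f.start, f.end, "flank")
        return tree

    def segment_tree(self, chrom: str) -> IntervalTree:
        tree = IntervalTree()
        for s in self.segments.get(chrom, []):
            tree.addi(s.start, s.end, s)
        return tree

    def genes_with_transcripts(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for t in self.transcripts.values():
            out.setdefault(t.gene_id, []).append(t)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeIndex):
            return NotImplemented
        return (
            self.config.__dict__ == other.config.__dict__
            and self.chrom_lengths == other.chrom_lengths
            and self.parts == other.parts
            and self.flanks == other.flanks
            and self.segments == other.segments
            and self.small_container == other.small_container
            and self.transcripts == other.transcripts
            and self.part_sequences == other.part_sequences
            and self.flank_sequences == other.flank_sequences
        )


# ---------------------------------------------------------------------------
# GTF reading
# ---------------------------------------------------------------------------

def _parse_gtf_exons(gtf_path):
    """Yield (chrom, start0, end0, gene_id, transcript_id, strand) per exon line."""
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: non-integer coordinates"
                ) from exc
            attrs = dict(_ATTR_RE.findall(fields[8]))
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: exon lacks gene_id/transcript_id"
                )
            yield (
                lineno,
                fields[0],
                start1 - 1,
                end1,
                attrs["gene_id"],
                attrs["transcript_id"],
                fields[6],
            )


def read_annotation(gtf_path) -> set[Exon]:
    """Read exon records from a GTF into deduplicated :class:`Exon` objects.

    Exons identical in (chrom, start, end) are merged, unioning their gene
    and transcript id sets. Exons with end <= start are rejected with a
    warning and skipped.
    """
    import logging

    by_coord: dict[tuple[str, int, int], tuple[set[str], set[str]]] = {}
    for lineno, chrom, start, end, gid, tid, _strand in _parse_gtf_exons(gtf_path):
        if end <= start:
            logging.getLogger(__name__).warning(
                "%s:%d: exon with end <= start rejected", gtf_path, lineno
            )
            continue
        gids, tids = by_coord.setdefault((chrom, start, end), (set(), set()))
        gids.add(gid)
        tids.add(tid)
    return {
        Exon(chrom, start, end, frozenset(g), frozenset(t))
        for (chrom, start, end), (g, t) in by_coord.items()
    }


def read_transcripts(gtf_path) -> dict[str, Transcript]:
    """Transcript catalog (ordered exon chains) from a GTF's exon lines."""
    acc: dict[str, dict] = {}
    for _lineno, chrom, start, end, gid, tid, strand in _parse_gtf_exons(gtf_path):
        if end <= start:
            continue
        rec = acc.setdefault(
            tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "exons": []}
        )
        rec["exons"].append((start, end))
    return {
        tid: Transcript(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
        )
        for tid, rec in acc.items()
    }


# ---------------------------------------------------------------------------
# Parts / flanks / segments
# ---------------------------------------------------------------------------

def build_parts(exons) -> list[Part]:
    """Connected components of the exon interval-overlap graph, one chromosome.

    Each part spans min exon start to max exon end of its component and
    records the sorted unique exon coordinates used later for segmenting.
    """
    exons = sorted(exons, key=lambda e: (e.start, e.end))
    if not exons:
        return []
    chroms = {e.chrom for e in exons}
    if len(chroms) > 1:
        raise ValueError(f"build_parts expects one chromosome, got {chroms}")
    chrom = exons[0].chrom

    parts: list[Part] = []
    cur: list[Exon] = [exons[0]]
    cur_end = exons[0].end
    for e in exons[1:]:
        if e.start < cur_end:  # overlap (touching exons do not merge)
            cur.append(e)
            cur_end = max(cur_end, e.end)
        else:
            parts.append(_make_part(chrom, cur))
            cur = [e]
            cur_end = e.end
    parts.append(_make_part(chrom, cur))
    return parts


def _make_part(chrom: str, members: list[Exon]) -> Part:
    coords = sorted({c for e in members for c in (e.start, e.end)})
    gene_ids = frozenset().union(*(e.gene_ids for e in members))
    return Part(chrom, coords[0], coords[-1], tuple(coords), gene_ids)


def build_flanks(parts: list[Part], F: int, chrom_length: int) -> list[Flank]:
    """Flanks of length <= F on each side of each part, never overlapping.

    A gap between two parts shorter than F becomes a single flank covering
    the whole gap; a gap in [F, 2F) is split at its midpoint into two
    flanks of length <= F; gaps >= 2F yield one F-flank per neighbouring
    part. Flanks are truncated at chromosome boundaries; zero-length flanks
    are dropped.
    """
    flanks: list[Flank] = []
    for i, part in enumerate(parts):
        chrom = part.chrom
        # left flank (inter-part gaps are emitted while handling the right
        # side of the preceding part)
        if i == 0:
            start = max(0, part.start - F)
            if start < part.start:
                flanks.append(Flank(chrom, start, part.start))
        # right side
        right_limit = parts[i + 1].start if i + 1 < len(parts) else chrom_length
        gap = right_limit - part.end
        if i + 1 < len(parts):
            if gap <= 0:
                continue
            if gap < F:
                flanks.append(Flank(chrom, part.end, right_limit))
            elif gap < 2 * F:
                mid = part.end + gap // 2
                flanks.append(Flank(chrom, part.end, mid))
                flanks.append(Flank(chrom, mid, right_limit))
            else:
                flanks.append(Flank(chrom, part.end, part.end + F))
                flanks.append(Flank(chrom, right_limit - F, right_limit))
        else:
            end = min(right_limit, part.end + F)
            if end > part.end:
                flanks.append(Flank(chrom, part.end, end))
    return flanks


def build_segments(part: Part, X_seg: int) -> list[Segment]:
    """Segments of one part from its sorted exon coordinate array.

    Adjacent coordinate pairs at distance >= X_seg become segments directly.
    For a short pair (x_i, x_{i+1}) the boundary is extended outwards in
    each direction independently — (x_{i-k}, x_{i+1}) and (x_i, x_{i+1+k})
    for k = 1, 2, ... — taking the first extension reaching X_seg on each
    side. If no extension in either direction can reach X_seg the whole
    part is emitted as a single small-flagged segment.
    """
    coords = part.exon_coords
    out: set[tuple[int, int]] = set()
    small: set[tuple[int, int]] = set()
    if part.end - part.start < X_seg:
        small.add((part.start, part.end))
    else:
        for i in range(len(coords) - 1):
            lo, hi = coords[i], coords[i + 1]
            if hi - lo >= X_seg:
                out.add((lo, hi))
                continue
            added = False
            for k in range(i - 1, -1, -1):  # extend downwards
                if hi - coords[k] >= X_seg:
                    out.add((coords[k], hi))
                    added = True
                    break
            for k in range(i + 2, len(coords)):  # extend upwards
                if coords[k] - lo >= X_seg:
                    out.add((lo, coords[k]))
                    added = True
                    break
            if not added:
                small.add((part.start, part.end))
    segs = [
        Segment(part.chrom, s, e, part.gene_ids, is_small=False)
        for s, e in sorted(out)
    ]
    segs += [
        Segment(part.chrom, s, e, part.gene_ids, is_small=True)
        for s, e in sorted(small)
    ]
    return segs


# ---------------------------------------------------------------------------
# Index building and persistence
# ---------------------------------------------------------------------------

def build_index(
    genome: dict[str, str],
    exons: set[Exon],
    config: IndexConfig | None = None,
    transcripts: dict[str, Transcript] | None = None,
) -> GenomeIndex:
    """Assemble the full genomic index from sequences and annotated exons.

    Exons shorter than ``config.min_small_exon`` are discarded. Exons and
    segments shorter than ``config.small_threshold`` are placed in the
    per-gene small container instead of the regular segment lists.
    """
    config = config or IndexConfig()
    missing = {e.chrom for e in exons} - set(genome)
    if missing:
        raise KeyError(
            "chromosomes in annotation absent from genome FASTA: "
            + ", ".join(sorted(missing))
        )

    exons = {e for e in exons if e.length >= config.min_small_exon}
    parts: dict[str, list[Part]] = {}
    flanks: dict[str, list[Flank]] = {}
    segments: dict[str, list[Segment]] = {}
    small: dict[str, list[Segment]] = {}
    part_seqs: dict[tuple[str, int], str] = {}
    flank_seqs: dict[tuple[str, int], str] = {}

    by_chrom: dict[str, set[Exon]] = {}
    for e in exons:
        by_chrom.setdefault(e.chrom, set()).add(e)

    for chrom in sorted(by_chrom):
        seq = genome[chrom].upper()
        chrom_parts = build_parts(by_chrom[chrom])
        parts[chrom] = chrom_parts
        flanks[chrom] = build_flanks(chrom_parts, config.F, len(seq))
        chrom_segments: list[Segment] = []
        for part in chrom_parts:
            part_seqs[(chrom, part.start)] = seq[part.start : part.end]
            for s in build_segments(part, config.X_seg):
                s = Segment(
                    s.chrom,
                    s.start,
                    s.end,
                    _segment_genes(s, by_chrom[chrom]),
                    is_small=s.is_small or s.length < config.small_threshold,
                )
                if s.is_small:
                    for gid in s.gene_ids:
                        small.setdefault(gid, []).append(s)
                else:
                    chrom_segments.append(s)
        segments[chrom] = sorted(chrom_segments, key=lambda s: (s.start, s.end))
        for f in flanks[chrom]:
            flank_seqs[(chrom, f.start)] = seq[f.start : f.end]
        # small exons go to the container as small-flagged segments
        for e in sorted(by_chrom[chrom], key=lambda e: (e.start, e.end)):
            if e.length < config.small_threshold:
                s = Segment(e.chrom, e.start, e.end, e.gene_ids, is_small=True)
                for gid in e.gene_ids:
                    if s not in small.get(gid, []):
                        small.setdefault(gid, []).append(s)

    for gid in small:
        small[gid] = sorted(set(small[gid]), key=lambda s: (s.chrom, s.start, s.end))

    return GenomeIndex(
        config=config,
        chrom_lengths={c: len(genome[c]) for c in genome},
        parts=parts,
        flanks=flanks,
        segments=segments,
        small_container=small,
        transcripts=transcripts or {},
        part_sequences=part_seqs,
        flank_sequences=flank_seqs,
    )


def _segment_genes(seg: Segment, exons: set[Exon]) -> frozenset[str]:
    gids = {
        gid
        for e in exons
        if e.start < seg.end and seg.start < e.end
        for gid in e.gene_ids
    }
    return frozenset(gids) if gids else seg.gene_ids


def build_index_from_files(
    fasta_path, gtf_path, config: IndexConfig | None = None
) -> GenomeIndex:
    from .io import read_fasta

    genome = read_fasta(fasta_path)
    return build_index(
        genome,
        read_annotation(gtf_path),
        config=config,
        transcripts=read_transcripts(gtf_path),
    )


# -- serialization -----------------------------------------------------------

def save_index(index: GenomeIndex, out_dir) -> None:
    """Serialize the index to a directory of JSON files (stable format)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "format_version": INDEX_FORMAT_VERSION,
        "config": index.config.__dict__,
        "chrom_lengths": index.chrom_lengths,
        "parts": {
            c: [[p.start, p.end, list(p.exon_coords), sorted(p.gene_ids)] for p in ps]
            for c, ps in index.parts.items()
        },
        "flanks": {
            c: [[f.start, f.end] for f in fs] for c, fs in index.flanks.items()
        },
        "segments": {
            c: [[s.start, s.end, sorted(s.gene_ids), s.is_small] for s in ss]
            for c, ss in index.segments.items()
        },
        "small_container": {
            g: [[s.chrom, s.start, s.end, sorted(s.gene_ids)] for s in ss]
            for g, ss in index.small_container.items()
        },
        "transcripts": {
            tid: [t.gene_id, t.chrom, t.strand, [list(e) for e in t.exons]]
            for tid, t in index.transcripts.items()
        },
        "part_sequences": {f"{c}:{s}": seq for (c, s), seq in index.part_sequences.items()},
        "flank_sequences": {f"{c}:{s}": seq for (c, s), seq in index.flank_sequences.items()},
    }
    (out / "index.json").write_text(json.dumps(doc))


def load_index(in_dir) -> GenomeIndex:
    doc = json.loads((Path(in_dir) / "index.json").read_text())
    if doc["format_version"] != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index format version {doc['format_version']}")
    cfg = IndexConfig(**doc["config"])

    def key(s):
        c, pos = s.rsplit(":", 1)
        return (c, int(pos))

    return GenomeIndex(
        config=cfg,
        chrom_lengths=doc["chrom_lengths"],
        parts={
            c: [Part(c, s, e, tuple(coords), frozenset(g)) for s, e, coords, g in ps]
            for c, ps in doc["parts"].items()
        },
        flanks={
            c: [Flank(c, s, e) for s, e in fs] for c, fs in doc["flanks"].items()
        },
        segments={
            c: [Segment(c, s, e, frozenset(g), sm) for s, e, g, sm in ss]
            for c, ss in doc["segments"].items()
        },
        small_container={
            g: [Segment(c, s, e, frozenset(gs), True) for c, s, e, gs in ss]
            for g, ss in doc["small_container"].items()
        },
        transcripts={
            tid: Transcript(tid, g, c, st, tuple(tuple(e) for e in ex))
            for tid, (g, c, st, ex) in doc["transcripts"].items()
        },
        part_sequences={key(k): v for k, v in doc["part_sequences"].items()},
        flank_sequences={key(k): v for k, v in doc["flank_sequences"].items()},
    )
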
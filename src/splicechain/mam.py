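"""Maximal approximate matches: semi-global placement of exon segments in reads.

Each candidate genome segment is aligned in its entirety into the read
(semi-global / infix mode, unit edit costs, via edlib). A placement whose
accuracy — matches divided by the segment's genomic length — reaches the
threshold becomes a MAM. A segment may place more than once in a read
(tandem gene copies, repeated exons): placements are enumerated by repeated
best-hit extraction, masking the read interval of each accepted placement
before searching again.

Very short exons are handled specially: 5–8 nt exons only match exactly
(every exact occurrence in the read is an accuracy-1 MAM) and exons of
4 nt or less are ignored entirely — a 60 %-accuracy criterion is
meaningless at those lengths and near-random matches would flood the
chaining stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .index import GenomeIndex, Segment
from .seeding import Instance

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class Mam:
    """Approximate match of genome segment [a, b) to read interval [c, d)."""

    chrom: str
    a: int
    b: int
    c: int
    d: int
    acc: float
    gene_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (self.c < self.d):
            raise ValueError("MAM read interval must be non-empty")
        if not (0.0 <= self.acc <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class MamConfig:
    """MAM filtering parameters.

    T : minimum accuracy as a percentage (matches / segment length).
    exact_band : inclusive exon-length range that requires an exact match.
    ignore_below : segments of this length or shorter are never aligned.
    max_placements : cap on enumerated placements per segment in one read.
    """

    T: float = 60.0
    exact_band: tuple[int, int] = (5, 8)
    ignore_below: int = 4
    max_placements: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.T <= 100):
            raise ValueError("T must be in (0, 100]")


def candidate_segments(
    mem_solution, index: GenomeIndex, instance: Instance | None = None
) -> list[Segment]:
    """Candidate segments for the MAM pass, given one MEM chaining solution.

    The set is the union of (i) regular segments overlapped by solution
    MEMs, (ii) every segment and small-container exon sharing a gene id
    with those, and (iii) flanks overlapped by solution MEMs (represented
    as gene-less segments so they can be MAM-aligned too).
    """
    mems = list(mem_solution.mems) if hasattr(mem_solution, "mems") else list(mem_solution)
    if not mems:
        return []
    chrom = mems[0].chrom
    seg_tree = index.segment_tree(chrom)

    hit_genes: set[str] = set()
    out: dict[tuple[int, int, bool], Segment] = {}
    for m in mems:
        for iv in seg_tree.overlap(m.a, m.b):
            seg: Segment = iv.data
            out[(seg.start, seg.end, False)] = seg
            hit_genes |= seg.gene_ids
    # all segments of the hit genes
    for seg in index.segments.get(chrom, []):
        if seg.gene_ids & hit_genes:
            out[(seg.start, seg.end, False)] = seg
    # small container per gene id
    for gid in sorted(hit_genes):
        for seg in index.small_container.get(gid, []):
            if seg.chrom == chrom:
                out[(seg.start, seg.end, True)] = seg
    # flanks overlapped by MEMs
    for f in index.flanks.get(chrom, []):
        if any(m.a < f.end and f.start < m.b for m in mems):
            out[(f.start, f.end, False)] = Segment(
                chrom, f.start, f.end, frozenset(), is_small=False
            )
    return sorted(out.values(), key=lambda s: (s.start, s.end, s.is_small))


def _cigar_matches(cigar: str) -> tuple[int, int]:
    """(#matches, target nt consumed) from an edlib extended cigar."""
    matches = 0
    consumed = 0
    for num, op in _CIG_RE.findall(cigar):
        n = int(num)
        if op == "=":
            matches += n
            consumed += n
        elif op in "XM":
            consumed += n
        elif op == "D":  # gap in query: target (read) consumed
            consumed += n
    return matches, consumed


def _exact_occurrences(segment_sequence: str, read: str) -> list[tuple[int, int]]:
    out = []
    start = 0
    while True:
        i = read.find(segment_sequence, start)
        if i < 0:
            return out
        out.append((i, i + len(segment_sequence)))
        start = i + 1


def compute_mams(
    segment: Segment,
    segment_sequence: str,
    read_sequence: str,
    config: MamConfig | None = None,
) -> list[Mam]:
    """All acceptable placements of one segment in a read.

    Regular segments use iterated edlib infix alignment with masking;
    exact-band segments (5–8 nt) use exact substring search. Accuracy is
    matches / segment length; placements below ``T``/100 are discarded.
    """
    config = config or MamConfig()
    seg_len = len(segment_sequence)
    if seg_len <= config.ignore_below:
        return []
    lo, hi = config.exact_band
    if lo <= seg_len <= hi:
        return [
            Mam(segment.chrom, segment.start, segment.end, c, d, 1.0, segment.gene_ids)
            for c, d in _exact_occurrences(segment_sequence, read_sequence)
        ][: config.max_placements]

    min_acc = config.T / 100.0
    read = read_sequence
    masked = list(read)
    out: list[Mam] = []
    for _ in range(config.max_placements):
        # edlib's first argument is the query (fully consumed): the segment
        # is placed into the read (target), infix mode.
        res = edlib.align(segment_sequence, "".join(masked), mode="HW", task="locations")
        if res["editDistance"] < 0 or not res["locations"]:
            break
        # among co-optimal (minimum edit distance) locations take the one
        # with the highest accuracy; ties resolve to the leftmost
        best: tuple[float, int, int] | None = None
        for s, e in res["locations"]:
            c, d = (s if s is not None else 0), e + 1
            if d <= c:
                continue
            window = "".join(masked[c:d])
            sub = edlib.align(segment_sequence, window, mode="NW", task="path")
            matches, _ = _cigar_matches(sub["cigar"])
            acc = matches / seg_len
            if best is None or acc > best[0]:
                best = (acc, c, d)
        if best is None or best[0] < min_acc:
            break
        acc, c, d = best
        out.append(
            Mam(segment.chrom, segment.start, segment.end, c, d, acc, segment.gene_ids)
        )
        for i in range(c, d):
            masked[i] = "#"
    return out


def mams_for_candidates(
    candidates: list[Segment],
    index: GenomeIndex,
    read_sequence: str,
    config: MamConfig | None = None,
) -> list[Mam]:
    """MAMs of every candidate segment against one (oriented) read."""
    config = config or MamConfig()
    out: list[Mam] = []
    for seg in candidates:
        if seg.gene_ids:
            seq = index.segment_sequence(seg)
        else:  # flank pseudo-segment
            seq = index.flank_sequences[(seg.chrom, seg.start)]
        out.extend(compute_mams(seg, seq, read_sequence, config))
    out.sort(key=lambda m: (m.a, m.c, m.b, m.d))
    return out
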
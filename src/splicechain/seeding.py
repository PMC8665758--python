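"""Maximal-exact-match seeding against indexed parts and flanks.

A MEM pairs a genome interval [a, b) with a read interval [c, d) such that
the sequences are identical and the match cannot be extended by one
nucleotide on either side in both sequences (a part/flank boundary counts
as non-extendable). MEMs are found against each indexed part and flank
sequence and lifted to chromosomal coordinates, then grouped into chaining
*instances*: candidate loci separated by large genomic gaps.

The finder seeds with a hash of all ``min_mem_length``-mers of the indexed
sequences: every maximal match of length >= L contains an L-mer at its left
end that is left-maximal, so extending right from left-maximal seed hits
enumerates the complete MEM set exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .index import GenomeIndex
from .io import reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Mem:
    """One maximal exact match: genome [a, b) equals read [c, d)."""

    chrom: str
    a: int
    b: int
    c: int
    d: int

    @property
    def length(self) -> int:
        return self.b - self.a

    def __post_init__(self) -> None:
        if self.b - self.a != self.d - self.c:
            raise ValueError("MEM genome and read intervals differ in length")


@dataclass
class SeedingConfig:
    min_mem_length: int = 20
    max_instance_gap: int = 500_000

    def __post_init__(self) -> None:
        if self.min_mem_length < 5:
            raise ValueError("min_mem_length must be >= 5")


@dataclass
class Instance:
    """One candidate locus: MEMs on a chromosome/orientation, sorted by a."""

    chrom: str
    mems: list[Mem]
    reverse: bool
    upper_bound: int = field(default=0)


def maximal_exact_matches(ref: str, read: str, min_length: int) -> list[Mem]:
    """All maximal exact matches >= min_length between two plain sequences.

    Coordinates are local: a/b in ``ref``, c/d in ``read``. A match is
    maximal when extending one position left or right breaks equality or
    runs off either sequence.
    """
    L = min_length
    if len(read) < L or len(ref) < L:
        return []
    seeds: dict[str, list[int]] = {}
    for j in range(len(ref) - L + 1):
        seeds.setdefault(ref[j : j + L], []).append(j)
    out: list[Mem] = []
    for i in range(len(read) - L + 1):
        hits = seeds.get(read[i : i + L])
        if not hits:
            continue
        for j in hits:
            if i > 0 and j > 0 and read[i - 1] == ref[j - 1]:
                continue  # not left-maximal; found from its leftmost L-mer
            m = L
            while i + m < len(read) and j + m < len(ref) and read[i + m] == ref[j + m]:
                m += 1
            out.append(Mem("", j, j + m, i, i + m))
    return out


class SeedIndex:
    """L-mer lookup over all part and flank sequences of a genome index."""

    def __init__(self, index: GenomeIndex, min_mem_length: int):
        self.L = min_mem_length
        self.blocks: list[tuple[str, int, str]] = []  # (chrom, genome start, seq)
        for chrom in sorted(index.parts):
            for p in index.parts[chrom]:
                self.blocks.append((chrom, p.start, index.part_sequences[(chrom, p.start)]))
        for chrom in sorted(index.flanks):
            for f in index.flanks[chrom]:
                self.blocks.append((chrom, f.start, index.flank_sequences[(chrom, f.start)]))
        self.seeds: dict[str, list[tuple[int, int]]] = {}
        for bi, (_c, _s, seq) in enumerate(self.blocks):
            for j in range(len(seq) - self.L + 1):
                self.seeds.setdefault(seq[j : j + self.L], []).append((bi, j))


def find_mems(
    read_sequence: str, index: GenomeIndex, config: SeedingConfig | None = None,
    seed_index: SeedIndex | None = None,
) -> list[Mem]:
    """All MEMs >= min_mem_length between a read and indexed parts/flanks.

    Genome coordinates are chromosomal (lifted from block-local). Passing a
    prebuilt :class:`SeedIndex` avoids rebuilding the seed table per read.
    """
    config = config or SeedingConfig()
    L = config.min_mem_length
    if len(read_sequence) < L:
        logger.info("read shorter than min_mem_length %d; no seeds", L)
        return []
    si = seed_index or SeedIndex(index, L)
    read = read_sequence.upper()
    out: list[Mem] = []
    for i in range(len(read) - L + 1):
        hits = si.seeds.get(read[i : i + L])
        if not hits:
            continue
        for bi, j in hits:
            chrom, bstart, seq = si.blocks[bi]
            if i > 0 and j > 0 and read[i - 1] == seq[j - 1]:
                continue
            m = L
            while i + m < len(read) and j + m < len(seq) and read[i + m] == seq[j + m]:
                m += 1
            out.append(Mem(chrom, bstart + j, bstart + j + m, i, i + m))
    out.sort(key=lambda x: (x.chrom, x.a, x.c))
    return out


def read_interval_union(mems) -> int:
    """Total read length covered by the union of MEM read intervals."""
    ivs = sorted((m.c, m.d) for m in mems)
    total = 0
    hi = -1
    for c, d in ivs:
        if c > hi:
            total += d - c
            hi = d
        elif d > hi:
            total += d - hi
            hi = d
    return total


def partition_instances(
    mems: list[Mem], config: SeedingConfig | None = None, reverse: bool = False
) -> list[Instance]:
    """Split MEMs into per-chromosome instances at large genomic gaps.

    MEMs are grouped per chromosome, sorted by a, and a new instance starts
    whenever the gap between consecutive genomic intervals exceeds
    ``max_instance_gap``. Each instance's upper bound is the union length
    of its MEMs' read intervals (the best coverage any chain could reach).
    """
    config = config or SeedingConfig()
    by_chrom: dict[str, list[Mem]] = {}
    for m in mems:
        by_chrom.setdefault(m.chrom, []).append(m)
    instances: list[Instance] = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: (m.a, m.c))
        group = [ms[0]]
        for m in ms[1:]:
            if m.a - group[-1].b > config.max_instance_gap:
                instances.append(Instance(chrom, group, reverse))
                group = [m]
            else:
                group.append(m)
        instances.append(Instance(chrom, group, reverse))
    for inst in instances:
        inst.upper_bound = read_interval_union(inst.mems)
    return instances


def seed_read(
    read_sequence: str,
    index: GenomeIndex,
    config: SeedingConfig | None = None,
    seed_index: SeedIndex | None = None,
) -> list[Instance]:
    """Seed both orientations of a read and return all chaining instances."""
    config = config or SeedingConfig()
    fwd = find_mems(read_sequence, index, config, seed_index)
    rev = find_mems(reverse_complement(read_sequence), index, config, seed_index)
    out: list[Instance] = []
    if fwd:
        out += partition_instances(fwd, config, reverse=False)
    if rev:
        out += partition_instances(rev, config, reverse=True)
    return out
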
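"""End-to-end read alignment: the two-pass chaining pipeline per read.

For each read (both orientations): find MEMs against indexed parts and
flanks, partition them into candidate-locus instances, chain MEMs for
coverage (with upper-bound ranking and drop-off pruning), retrieve the
candidate segments of the hit genes (small exons included), place them as
MAMs, chain the MAMs under the weighted objective, concatenate the chained
segments into an augmented reference, align the read to it with affine
semi-global scoring, and project back to genomic coordinates. The best
alignment becomes primary (score, then shortest genomic span, then
agreement with annotated splice sites); the unaligned threshold is applied
to the primary; every reported alignment gets a splice-category CN tag.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from .alignment import (
    AlignConfig,
    ReadAlignment,
    align_read,
    apply_unaligned_threshold,
    build_augmented_reference,
    project_to_genome,
    select_primary,
)
from .chaining import ChainConfig, chain_mams, rank_and_prune_instances
from .classify import JunctionCatalog, annotate_category
from .index import GenomeIndex
from .io import reverse_complement
from .mam import MamConfig, candidate_segments, mams_for_candidates
from .seeding import SeedIndex, SeedingConfig, find_mems, partition_instances


def unaligned_record(read_id: str, seq: str) -> ReadAlignment:
    return ReadAlignment(
        read_id=read_id,
        chrom="*",
        start=0,
        reverse=False,
        cigar=[],
        score=0.0,
        edit_distance=0,
        seq=seq,
        is_primary=True,
        is_unaligned=True,
    )


@dataclass
class Aligner:
    """Reusable aligner over one genome index."""

    index: GenomeIndex
    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    chaining: ChainConfig = field(default_factory=ChainConfig)
    mams: MamConfig = field(default_factory=MamConfig)
    scoring: AlignConfig = field(default_factory=AlignConfig)

    def __post_init__(self) -> None:
        self._seed_index = SeedIndex(self.index, self.seeding.min_mem_length)
        self._catalog = JunctionCatalog.from_index(self.index)
        self._annotated = self._catalog.annotated_set()

    @property
    def catalog(self) -> JunctionCatalog:
        return self._catalog

    def align(self, read_id: str, seq: str) -> list[ReadAlignment]:
        """All reported alignments for one read; exactly one is primary.

        An unalignable read yields a single unmapped record.
        """
        seq = seq.upper()
        candidates: list[ReadAlignment] = []
        for reverse in (False, True):
            oriented = reverse_complement(seq) if reverse else seq
            mems = find_mems(oriented, self.index, self.seeding, self._seed_index)
            if not mems:
                continue
            instances = partition_instances(mems, self.seeding, reverse=reverse)
            for inst, chains in rank_and_prune_instances(instances, self.chaining):
                for mem_chain in chains:
                    aln = self._align_solution(read_id, oriented, reverse, mem_chain, inst)
                    if aln is not None:
                        candidates.append(aln)
        candidates = _dedupe(candidates)
        if not candidates:
            return [unaligned_record(read_id, seq)]
        select_primary(candidates, self._annotated)
        candidates.sort(key=lambda a: (not a.is_primary, -a.score, a.chrom, a.start))
        candidates = candidates[: self.chaining.max_alignments]
        primary = candidates[0]
        apply_unaligned_threshold(primary, len(seq), self.scoring)
        if primary.is_unaligned:
            return [unaligned_record(read_id, seq)]
        for a in candidates:
            annotate_category(a, self._catalog)
        return candidates

    def _align_solution(self, read_id, oriented, reverse, mem_chain, instance):
        cands = candidate_segments(mem_chain, self.index, instance)
        if not cands:
            return None
        mam_list = mams_for_candidates(cands, self.index, oriented, self.mams)
        chain = chain_mams(mam_list, self.chaining)
        if not chain.mams:
            return None
        augref = build_augmented_reference(chain, self.index)
        score, blocks = align_read(oriented, augref, self.scoring)
        if len(blocks[0]) == 0:
            return None
        return project_to_genome(
            read_id, oriented, score, blocks, augref, reverse=reverse
        )

    def align_reads(self, reads, threads: int = 1) -> list[list[ReadAlignment]]:
        """Align (read_id, seq) pairs; output order follows input order."""
        reads = list(reads)
        if threads <= 1:
            return [self.align(rid, seq) for rid, seq in reads]
        with ThreadPoolExecutor(max_workers=threads) as ex:
            return list(ex.map(lambda rs: self.align(*rs), reads))


def _dedupe(alignments: list[ReadAlignment]) -> list[ReadAlignment]:
    seen = set()
    out = []
    for a in alignments:
        key = (a.chrom, a.start, a.reverse, a.cigar_string())
        if key not in seen:
            seen.add(key)
            out.append(a)
    return out


# ---------------------------------------------------------------------------
# SAM ingestion (for classify / evaluate / merge subcommands)
# ---------------------------------------------------------------------------

def read_sam(path) -> list[ReadAlignment]:
    """Parse SAM records into :class:`ReadAlignment` objects (pysam)."""
    import pysam

    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                out.append(unaligned_record(rec.query_name, rec.query_sequence or ""))
                continue
            cigar = [( "MIDNSHP=X"[op], n) for op, n in rec.cigartuples]
            junctions = []
            pos = rec.reference_start
            for op, n in cigar:
                if op in "MD=X":
                    pos += n
                elif op == "N":
                    junctions.append((pos, pos + n))
                    pos += n
            aln = ReadAlignment(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                reverse=rec.is_reverse,
                cigar=cigar,
                score=float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0,
                edit_distance=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                seq=rec.query_sequence or "",
                is_primary=not rec.is_secondary and not rec.is_supplementary,
                junctions=junctions,
                category=rec.get_tag("CN") if rec.has_tag("CN") else None,
            )
            out.append(aln)
    return out
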
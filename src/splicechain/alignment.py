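"""Final alignment: augmented reference, affine semi-global scoring, projection.

The exon segments of an optimal MAM chain are merged (genomically adjacent
or overlapping chained segments collapse into one block) and concatenated
into an *augmented reference*. The read is aligned to this reference with
affine gap penalties in semi-global mode — end gaps are free on both
sequences, so a reference extending past the read costs nothing and
unaligned read termini become soft clips. The concatenated-space alignment
is then projected to genome coordinates, inserting an N (intron skip)
operation of the recorded intron length at every junction the alignment
crosses.

A read whose best alignment scores below ``X_unaligned · m · r`` (match
score m, read length r) is reported unmapped; at the default scoring this
sits at roughly 25 % read errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .chaining import MamChain
from .index import GenomeIndex


@dataclass
class AlignConfig:
    """Affine-gap scoring and the unaligned threshold.

    A gap of length k costs ``gap_open + k * gap_extend`` (penalties are
    positive numbers here).
    """

    match: int = 2
    mismatch: int = 2
    gap_open: int = 3
    gap_extend: int = 1
    X_unaligned: float = 0.5

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if not (0.0 <= self.X_unaligned <= 1.0):
            raise ValueError("X_unaligned must lie in [0, 1]")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = -self.mismatch
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        a.end_insertion_score = 0  # free end gaps, both sequences
        a.end_deletion_score = 0
        return a


@dataclass
class AugmentedReference:
    """Concatenated merged segment blocks plus the genome breakpoint table."""

    chrom: str
    sequence: str
    # (concat offset, genomic start, genomic end) per block, in order
    blocks: list[tuple[int, int, int]]

    def to_genomic(self, concat_pos: int) -> int:
        for off, gstart, gend in reversed(self.blocks):
            if concat_pos >= off:
                return gstart + (concat_pos - off)
        raise IndexError(concat_pos)


@dataclass
class ReadAlignment:
    """One genomic alignment of a read, ready for SAM emission."""

    read_id: str
    chrom: str
    start: int  # genomic, 0-based
    reverse: bool
    cigar: list[tuple[str, int]]  # ops over {M, I, D, N, S}
    score: float
    edit_distance: int
    seq: str  # oriented (genome-forward) read sequence
    is_primary: bool = False
    is_unaligned: bool = False
    junctions: list[tuple[int, int]] = field(default_factory=list)
    category: str | None = None

    @property
    def genomic_end(self) -> int:
        pos = self.start
        for op, n in self.cigar:
            if op in "MDN":
                pos += n
        return pos

    @property
    def genomic_span(self) -> int:
        return self.genomic_end - self.start

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def build_augmented_reference(
    mam_chain: MamChain, index: GenomeIndex
) -> AugmentedReference:
    """Merge and concatenate the chained segments into one reference.

    Chained segments overlapping or abutting on the genome merge into a
    single block (a zero-length intron is not representable in a CIGAR);
    each remaining inter-block gap becomes a junction whose intron length
    is recorded via the block table.
    """
    if not mam_chain.mams:
        raise ValueError("cannot build a reference from an empty chain")
    chrom = mam_chain.mams[0].chrom
    ivs = sorted((m.a, m.b) for m in mam_chain.mams)
    merged: list[list[int]] = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    blocks = []
    seqs = []
    off = 0
    for s, e in merged:
        blocks.append((off, s, e))
        seq = index.region_sequence(chrom, s, e)
        seqs.append(seq)
        off += e - s
    return AugmentedReference(chrom, "".join(seqs), blocks)


def align_read(read: str, augref: AugmentedReference, config: AlignConfig | None = None):
    """Affine semi-global alignment of the read to the augmented reference.

    Returns (score, aligned_blocks) where aligned_blocks pairs reference
    and read coordinate ranges of the aligned (match/mismatch) runs, as
    produced by Biopython's PairwiseAligner.
    """
    if not read or not augref.sequence:
        raise ValueError("empty read or reference")
    config = config or AlignConfig()
    aln = config.aligner().align(augref.sequence, read)[0]
    return aln.score, aln.aligned


def project_to_genome(
    read_id: str,
    read: str,
    score: float,
    aligned_blocks,
    augref: AugmentedReference,
    reverse: bool = False,
) -> ReadAlignment:
    """Rewrite a concatenated-space alignment as a genomic CIGAR with introns.

    Unaligned read termini become soft clips; reference runs between
    aligned blocks become deletions; junction crossings become N
    operations of the recorded intron length, with deletions placed before
    the N. The edit distance counts mismatches plus inserted and deleted
    nucleotides (soft clips and introns excluded).
    """
    tgt_blocks, qry_blocks = aligned_blocks
    # junction table: concat breakpoint -> intron length
    junction_at = {}
    for i in range(len(augref.blocks) - 1):
        off_next, gstart_next, _ = augref.blocks[i + 1]
        junction_at[off_next] = gstart_next - augref.blocks[i][2]

    cigar: list[tuple[str, int]] = []
    junctions: list[tuple[int, int]] = []
    emitted_bps: set[int] = set()
    nm = 0

    def emit(op: str, n: int) -> None:
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    def emit_junction(bp: int) -> None:
        intron = junction_at[bp]
        g = augref.to_genomic(bp)  # genomic start of the later block
        junctions.append((g - intron, g))
        emit("N", intron)
        emitted_bps.add(bp)

    first_t = int(tgt_blocks[0][0])

    def consume_ref(op: str, t0: int, t1: int) -> None:
        """Emit a reference-consuming run [t0, t1), inserting N at junctions.

        A junction the cursor sits on from an earlier run (e.g. a deletion
        ending exactly at a breakpoint) is emitted before the new run, so
        deletions abutting a junction land before the N. A run ending
        exactly at a breakpoint defers the N to the next run, avoiding a
        dangling trailing intron.
        """
        nonlocal nm
        if t0 > first_t and t0 in junction_at and t0 not in emitted_bps:
            emit_junction(t0)
        pos = t0
        while pos < t1:
            nxt = min((bp for bp in junction_at if pos < bp < t1), default=None)
            run_end = nxt if nxt is not None else t1
            emit(op, run_end - pos)
            if op == "D":
                nm += run_end - pos
            pos = run_end
            if nxt is not None:
                emit_junction(nxt)

    start = augref.to_genomic(first_t)
    emit("S", int(qry_blocks[0][0]))  # leading unaligned read bases

    prev_t = first_t
    prev_q = int(qry_blocks[0][0])
    for (t0, t1), (q0, q1) in zip(
        (tuple(map(int, b)) for b in tgt_blocks),
        (tuple(map(int, b)) for b in qry_blocks),
    ):
        if t0 > prev_t:  # reference gap between aligned runs: deletion
            consume_ref("D", prev_t, t0)
        if q0 > prev_q:  # read gap: insertion
            emit("I", q0 - prev_q)
            nm += q0 - prev_q
        consume_ref("M", t0, t1)
        nm += sum(
            1 for k in range(t1 - t0) if augref.sequence[t0 + k] != read[q0 + k]
        )
        prev_t, prev_q = t1, q1
    emit("S", len(read) - prev_q)  # trailing unaligned read bases

    return ReadAlignment(
        read_id=read_id,
        chrom=augref.chrom,
        start=start,
        reverse=reverse,
        cigar=cigar,
        score=score,
        edit_distance=nm,
        seq=read,
        junctions=junctions,
    )


def select_primary(alignments: list[ReadAlignment], annotated_junctions=None):
    """Mark exactly one alignment primary.

    Order of preference: highest score; then shortest genomic span; then
    the most junctions matching annotated splice sites (if a catalog of
    annotated intron intervals is supplied).
    """
    if not alignments:
        return alignments
    ann = annotated_junctions or set()

    def matching(a: ReadAlignment) -> int:
        return sum(1 for j in a.junctions if (a.chrom, j[0], j[1]) in ann)

    ranked = sorted(
        range(len(alignments)),
        key=lambda i: (
            -alignments[i].score,
            alignments[i].genomic_span,
            -matching(alignments[i]),
            i,
        ),
    )
    for i, a in enumerate(alignments):
        a.is_primary = i == ranked[0]
    return alignments


def apply_unaligned_threshold(
    alignment: ReadAlignment, read_length: int, config: AlignConfig | None = None
) -> ReadAlignment:
    """Flag the alignment unaligned iff score < X_unaligned · match · r."""
    config = config or AlignConfig()
    if read_length == 0:
        alignment.is_unaligned = True
    elif config.X_unaligned > 0 and alignment.score < (
        config.X_unaligned * config.match * read_length
    ):
        alignment.is_unaligned = True
    return alignment


# ---------------------------------------------------------------------------
# SAM output
# ---------------------------------------------------------------------------

def sam_header(chrom_lengths: dict[str, int]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name in sorted(chrom_lengths):
        lines.append(f"@SQ\tSN:{name}\tLN:{chrom_lengths[name]}")
    lines.append("@PG\tID:splicechain\tPN:splicechain")
    return "\n".join(lines) + "\n"


def sam_record(a: ReadAlignment) -> str:
    """One SAM body line for an alignment (or unmapped record)."""
    if a.is_unaligned:
        flag = 4
        return "\t".join(
            [a.read_id, str(flag), "*", "0", "0", "*", "*", "0", "0", a.seq, "*"]
        )
    flag = 0
    if a.reverse:
        flag |= 16
    if not a.is_primary:
        flag |= 256
    fields = [
        a.read_id,
        str(flag),
        a.chrom,
        str(a.start + 1),
        "60" if a.is_primary else "0",
        a.cigar_string(),
        "*",
        "0",
        "0",
        a.seq,
        "*",
        f"NM:i:{a.edit_distance}",
        f"AS:i:{int(a.score)}",
    ]
    if a.category is not None:
        fields.append(f"CN:Z:{a.category}")
    return "\t".join(fields)


def write_sam(alignments: list[ReadAlignment], chrom_lengths: dict[str, int], path) -> None:
    """Write a SAM file (header + one line per alignment record)."""
    with open(path, "w") as fh:
        fh.write(sam_header(chrom_lengths))
        for a in alignments:
            fh.write(sam_record(a) + "\n")
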
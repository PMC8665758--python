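"""Splice-category annotation and truth-based evaluation of alignments.

Alignment junction chains (the intron intervals spelled by N operations)
are compared with the annotated transcript catalog:

* **FSM** — the junction chain equals some transcript's full chain;
* **ISM** — a contiguous sub-chain of some transcript's chain, truncated
  at the 3' and/or 5' end;
* **NIC** — every junction is annotated somewhere on the chromosome but no
  single transcript relationship above holds (novel combination);
* **NNC** — at least one junction is unannotated;
* **NO_SPLICE** — no junctions at all.

For simulated reads with known origin, alignments are graded *correct* /
*inexact* / *exon_difference* / *incorrect_location* / *unaligned* with a
configurable per-splice-site offset tolerance (default 15 nt, larger than
any plausible indel sequencing error, so misses beyond it indicate
alignment error).

The hybrid-mode helpers decide whether an externally produced alignment
lies outside the indexed gene regions (a *genomic* read, kept as-is) and
pick the better of two alignments of the same read by edit distance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import ReadAlignment
from .index import GenomeIndex, Transcript

CATEGORIES = ("FSM", "ISM", "NIC", "NNC", "NO_SPLICE")


@dataclass
class JunctionCatalog:
    """Annotated introns per chromosome and per transcript."""

    by_chrom: dict[str, set[tuple[int, int]]]
    transcript_chains: dict[str, tuple[str, tuple[tuple[int, int], ...]]]

    @classmethod
    def from_transcripts(cls, transcripts: dict[str, Transcript]) -> "JunctionCatalog":
        by_chrom: dict[str, set[tuple[int, int]]] = {}
        chains: dict[str, tuple[str, tuple[tuple[int, int], ...]]] = {}
        for tid, t in transcripts.items():
            introns = t.introns
            chains[tid] = (t.chrom, introns)
            by_chrom.setdefault(t.chrom, set()).update(introns)
        return cls(by_chrom, chains)

    @classmethod
    def from_index(cls, index: GenomeIndex) -> "JunctionCatalog":
        return cls.from_transcripts(index.transcripts)

    def annotated_set(self) -> set[tuple[str, int, int]]:
        return {
            (chrom, s, e)
            for chrom, introns in self.by_chrom.items()
            for s, e in introns
        }


@dataclass
class EvalConfig:
    splice_offset_tolerance: int = 15

    def __post_init__(self) -> None:
        if self.splice_offset_tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class HybridConfig:
    genomic_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.genomic_fraction <= 1.0):
            raise ValueError("genomic_fraction must lie in [0, 1]")


def _is_contiguous_subchain(sub, full) -> bool:
    n, m = len(sub), len(full)
    if n == 0 or n >= m:
        return False
    return any(tuple(full[i : i + n]) == tuple(sub) for i in range(m - n + 1))


def classify_splice_category(
    alignment: ReadAlignment, catalog: JunctionCatalog
) -> str:
    """CN-tag category of one alignment from its junction chain."""
    chain = tuple(alignment.junctions)
    if not chain:
        return "NO_SPLICE"
    chrom = alignment.chrom
    for tid, (t_chrom, t_chain) in catalog.transcript_chains.items():
        if t_chrom == chrom and t_chain == chain:
            return "FSM"
    for tid, (t_chrom, t_chain) in catalog.transcript_chains.items():
        if t_chrom == chrom and _is_contiguous_subchain(chain, t_chain):
            return "ISM"
    annotated = catalog.by_chrom.get(chrom, set())
    if all(j in annotated for j in chain):
        return "NIC"
    return "NNC"


def annotate_category(alignment: ReadAlignment, catalog: JunctionCatalog) -> ReadAlignment:
    alignment.category = classify_splice_category(alignment, catalog)
    return alignment


# ---------------------------------------------------------------------------
# Truth-based evaluation (simulated reads)
# ---------------------------------------------------------------------------

EVAL_CATEGORIES = (
    "correct",
    "inexact",
    "exon_difference",
    "incorrect_location",
    "unaligned",
)


def evaluate_against_truth(
    alignment: ReadAlignment | None,
    true_chrom: str,
    true_exons: list[tuple[int, int]],
    config: EvalConfig | None = None,
) -> str:
    """Grade one alignment against the read's true exon structure.

    correct : same locus, same junction count, every splice site within
        tolerance of its true counterpart.
    inexact : same locus and junction count, some site off by more.
    exon_difference : locus overlaps the truth but junction counts differ.
    incorrect_location : no overlap with the true locus.
    unaligned : flagged unaligned (or absent).
    """
    config = config or EvalConfig()
    if alignment is None or alignment.is_unaligned:
        return "unaligned"
    true_introns = [
        (true_exons[i][1], true_exons[i + 1][0]) for i in range(len(true_exons) - 1)
    ]
    locus = (true_exons[0][0], true_exons[-1][1])
    overlaps = (
        alignment.chrom == true_chrom
        and alignment.start < locus[1]
        and locus[0] < alignment.genomic_end
    )
    if not overlaps:
        return "incorrect_location"
    if len(alignment.junctions) != len(true_introns):
        return "exon_difference"
    tol = config.splice_offset_tolerance
    for (s, e), (ts, te) in zip(alignment.junctions, true_introns):
        if abs(s - ts) > tol or abs(e - te) > tol:
            return "inexact"
    return "correct"


def internal_exon_hits(
    alignment: ReadAlignment | None,
    true_exons: list[tuple[int, int]],
    config: EvalConfig | None = None,
) -> list[tuple[int, bool]]:
    """(length, correctly aligned) per *internal* true exon of one read.

    An internal exon is correctly aligned when both of its flanking splice
    sites appear in the alignment's junction chain within the tolerance:
    some junction ends within tol of the exon start and some junction
    starts within tol of the exon end. Terminal exons have no two flanking
    junctions and are excluded; this is the per-exon accuracy measure used
    for the small-exon analysis.
    """
    config = config or EvalConfig()
    tol = config.splice_offset_tolerance
    out: list[tuple[int, bool]] = []
    junctions = [] if alignment is None or alignment.is_unaligned else alignment.junctions
    for i in range(1, len(true_exons) - 1):
        s, e = true_exons[i]
        acceptor_ok = any(abs(j_end - s) <= tol for _, j_end in junctions)
        donor_ok = any(abs(j_start - e) <= tol for j_start, _ in junctions)
        out.append((e - s, acceptor_ok and donor_ok))
    return out


# ---------------------------------------------------------------------------
# Hybrid mode: genomic-read test and best-of-two selection
# ---------------------------------------------------------------------------

def aligned_reference_intervals(alignment: ReadAlignment) -> list[tuple[int, int]]:
    """Reference intervals consumed by M/D operations (introns excluded)."""
    out = []
    pos = alignment.start
    for op, n in alignment.cigar:
        if op in "MD":
            out.append((pos, pos + n))
            pos += n
        elif op == "N":
            pos += n
    return out


def classify_genomic(
    alignment: ReadAlignment, index: GenomeIndex, config: HybridConfig | None = None
) -> str:
    """'genomic' if too much of the alignment lies outside indexed regions.

    The fraction of aligned reference nucleotides outside all parts and
    flanks is compared with ``genomic_fraction``; genomic reads are kept as
    externally aligned rather than realigned.
    """
    config = config or HybridConfig()
    tree = index.region_tree(alignment.chrom)
    total = 0
    inside = 0
    for s, e in aligned_reference_intervals(alignment):
        total += e - s
        for iv in tree.overlap(s, e):
            inside += min(e, iv.end) - max(s, iv.begin)
    if total == 0:
        return "genomic"
    outside_frac = (total - inside) / total
    return "genomic" if outside_frac > config.genomic_fraction else "in_region"


def select_best_of_two(
    own: ReadAlignment, external: ReadAlignment | None
) -> ReadAlignment:
    """Pick the alignment with the smaller edit distance; ties keep our own.

    A missing, unmapped or malformed external record falls back to our own
    alignment.
    """
    import logging

    if external is None or external.is_unaligned:
        return own
    try:
        ext_nm = external.edit_distance
    except Exception:  # malformed record
        logging.getLogger(__name__).warning(
            "malformed external alignment for %s; keeping own", own.read_id
        )
        return own
    if own.is_unaligned:
        return external
    return external if ext_nm < own.edit_distance else own
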
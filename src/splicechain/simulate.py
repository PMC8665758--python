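"""Seeded synthetic data: genomes, multi-isoform annotations, noisy reads.

The generator emulates the structure an annotation-guided spliced aligner
must handle: multi-exon genes on both strands with a controlled share of
small internal exons (the hard case for seeding), multiple annotated
isoforms per gene, withheld novel-in-catalog isoforms that recombine
annotated junctions, and long reads sampled from transcripts with i.i.d.
substitution/insertion/deletion errors and random orientation.

It deliberately does not emulate platform error profiles (homopolymer
bias, quality-dependent errors) — reads here are an idealised long-read
cDNA model. Ground truth (source transcript, true exon chain, realized
error counts) is emitted as a TSV with a stable header.

Withheld novel isoforms are built by double exon skipping: the annotation
carries the full isoform and both single-skip isoforms, so every junction
of the withheld double-skip transcript is annotated, but the combination
is not — exactly the novel-in-catalog situation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .index import Transcript
from .io import reverse_complement

TRUTH_COLUMNS = [
    "read_id",
    "transcript_id",
    "chrom",
    "orientation",
    "exons",
    "n_sub",
    "n_ins",
    "n_del",
    "novel",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions of the synthetic dataset.

    Exon lengths are a two-band mixture: with probability
    ``small_exon_prob`` an *internal* exon is drawn from
    ``small_exon_range`` (the small-exon band), otherwise from
    ``exon_length_range``. Terminal exons always use the regular band so
    every transcript has seedable ends. Error rates are i.i.d. per base.
    """

    seed: int = 1
    genome_length: int = 100_000
    chrom_name: str = "chr1"
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (30, 300)
    small_exon_range: tuple[int, int] = (6, 25)
    small_exon_prob: float = 0.2
    intron_length_range: tuple[int, int] = (60, 600)
    intergenic_range: tuple[int, int] = (1200, 2500)
    isoforms_per_gene: tuple[int, int] = (1, 3)
    sub_rate: float = 0.04
    ins_rate: float = 0.015
    del_rate: float = 0.015
    reads_per_transcript: int = 5
    reverse_prob: float = 0.5

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        if not (0.0 <= self.reverse_prob <= 1.0):
            raise ValueError("reverse_prob must lie in [0, 1]")
        for lo, hi in (
            self.exons_per_gene,
            self.exon_length_range,
            self.small_exon_range,
            self.intron_length_range,
            self.intergenic_range,
            self.isoforms_per_gene,
        ):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive and ordered")


@dataclass
class TruthRecord:
    read_id: str
    transcript_id: str
    chrom: str
    orientation: str  # expected SAM orientation, '+' or '-'
    exons: list[tuple[int, int]]  # sorted, disjoint, genomic
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0
    novel: bool = False

    def to_tsv_row(self) -> str:
        exons = ";".join(f"{s}-{e}" for s, e in self.exons)
        return "\t".join(
            [
                self.read_id,
                self.transcript_id,
                self.chrom,
                self.orientation,
                exons,
                str(self.n_sub),
                str(self.n_ins),
                str(self.n_del),
                "1" if self.novel else "0",
            ]
        )


@dataclass
class Simulation:
    """In-memory result of a simulation run."""

    genome: dict[str, str]
    transcripts: dict[str, Transcript]  # annotated
    novel_transcripts: dict[str, Transcript]  # withheld from the GTF
    gtf_text: str
    config: SimConfig
    reads: list[tuple[str, str]] = field(default_factory=list)
    truth: list[TruthRecord] = field(default_factory=list)


class ConfigError(ValueError):
    pass


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _draw_exon_lengths(rng: np.random.Generator, n: int, cfg: SimConfig) -> list[int]:
    lengths = []
    for i in range(n):
        internal = 0 < i < n - 1
        if internal and rng.random() < cfg.small_exon_prob:
            lo, hi = cfg.small_exon_range
        else:
            lo, hi = cfg.exon_length_range
        lengths.append(int(rng.integers(lo, hi + 1)))
    return lengths


def _skip_variant(exons: list[tuple[int, int]], drop: set[int]):
    return tuple(e for i, e in enumerate(exons) if i not in drop)


def generate_genome_and_annotation(config: SimConfig) -> Simulation:
    """Random genome plus gene models; deterministic under the seed.

    Genes are laid left to right with intergenic gaps; a configuration
    whose genes cannot fit in ``genome_length`` raises :class:`ConfigError`.
    Each gene gets a full-length isoform; genes with at least five exons
    may additionally get single-skip isoforms and one withheld double-skip
    (novel-in-catalog) isoform.
    """
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom_name
    transcripts: dict[str, Transcript] = {}
    novel: dict[str, Transcript] = {}
    gtf_lines: list[str] = []

    pos = int(rng.integers(*config.intergenic_range))
    for g in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        lengths = _draw_exon_lengths(rng, n_exons, config)
        introns = [
            int(rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1))
            for _ in range(n_exons - 1)
        ]
        exons: list[tuple[int, int]] = []
        p = pos
        for i, L in enumerate(lengths):
            exons.append((p, p + L))
            p += L
            if i < n_exons - 1:
                p += introns[i]
        gene_end = p
        if gene_end > config.genome_length:
            raise ConfigError(
                f"gene {g} ends at {gene_end} > genome_length {config.genome_length}; "
                "introns/exons do not fit"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{g}"
        chains: list[tuple[str, tuple[tuple[int, int], ...]]] = [
            (f"{gid}t0", tuple(exons))
        ]
        n_iso = int(rng.integers(config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1))
        if n_exons >= 5 and n_iso >= 2:
            internal = list(range(1, n_exons - 1))
            i_skip = int(rng.choice(internal[:-2])) if len(internal) > 2 else internal[0]
            j_choices = [j for j in internal if j >= i_skip + 2]
            j_skip = int(rng.choice(j_choices)) if j_choices else None
            chains.append((f"{gid}t1", _skip_variant(exons, {i_skip})))
            if j_skip is not None:
                chains.append((f"{gid}t2", _skip_variant(exons, {j_skip})))
                novel_chain = _skip_variant(exons, {i_skip, j_skip})
                novel[f"{gid}n0"] = Transcript(
                    f"{gid}n0", gid, chrom, strand, novel_chain
                )
        for tid, chain in chains:
            transcripts[tid] = Transcript(tid, gid, chrom, strand, chain)
            gtf_lines.append(
                f"{chrom}\tsim\ttranscript\t{chain[0][0] + 1}\t{chain[-1][1]}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; transcript_id "{tid}";'
            )
            for s, e in chain:
                gtf_lines.append(
                    f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f'gene_id "{gid}"; transcript_id "{tid}";'
                )
        pos = gene_end + int(rng.integers(*config.intergenic_range))

    genome = {chrom: _random_seq(rng, config.genome_length)}
    return Simulation(
        genome=genome,
        transcripts=transcripts,
        novel_transcripts=novel,
        gtf_text="\n".join(gtf_lines) + ("\n" if gtf_lines else ""),
        config=config,
    )


def transcript_sequence(t: Transcript, genome: dict[str, str]) -> str:
    seq = "".join(genome[t.chrom][s:e] for s, e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


def _mutate(rng: np.random.Generator, seq: str, cfg: SimConfig):
    """Apply i.i.d. per-base errors; returns (read, n_sub, n_ins, n_del)."""
    out: list[str] = []
    n_sub = n_ins = n_del = 0
    for ch in seq:
        if rng.random() < cfg.del_rate:
            n_del += 1
            continue
        if rng.random() < cfg.sub_rate:
            alt = "ACGT".replace(ch, "") if ch in "ACGT" else "ACGT"
            out.append(alt[int(rng.integers(0, len(alt)))])
            n_sub += 1
        else:
            out.append(ch)
        if rng.random() < cfg.ins_rate:
            out.append("ACGT"[int(rng.integers(0, 4))])
            n_ins += 1
    return "".join(out), n_sub, n_ins, n_del


def generate_reads(
    sim: Simulation,
    transcripts: dict[str, Transcript] | None = None,
    n_reads: int | None = None,
    novel: bool = False,
    seed_offset: int = 1,
) -> None:
    """Sample reads from transcripts into ``sim.reads`` / ``sim.truth``.

    By default every annotated transcript yields ``reads_per_transcript``
    reads; alternatively ``n_reads`` reads are drawn uniformly at random
    over the given transcripts. Orientation flips with probability
    ``reverse_prob``; the truth records the expected genomic orientation
    (gene strand combined with the flip).
    """
    cfg = sim.config
    rng = np.random.default_rng(cfg.seed + seed_offset)
    source = transcripts if transcripts is not None else sim.transcripts
    tids = sorted(source)
    if not tids:
        return
    if n_reads is None:
        picks = [tid for tid in tids for _ in range(cfg.reads_per_transcript)]
    else:
        picks = [tids[int(rng.integers(0, len(tids)))] for _ in range(n_reads)]
    for k, tid in enumerate(picks):
        t = source[tid]
        seq = transcript_sequence(t, sim.genome)
        read, n_sub, n_ins, n_del = _mutate(rng, seq, cfg)
        flip = rng.random() < cfg.reverse_prob
        if flip:
            read = reverse_complement(read)
        # orientation of the read relative to the genome forward strand
        sense = (t.strand == "-") ^ flip
        rid = f"{tid}_r{k}"
        sim.reads.append((rid, read))
        sim.truth.append(
            TruthRecord(
                read_id=rid,
                transcript_id=tid,
                chrom=t.chrom,
                orientation="-" if sense else "+",
                exons=list(t.exons),
                n_sub=n_sub,
                n_ins=n_ins,
                n_del=n_del,
                novel=novel,
            )
        )


def generate_novel_isoforms(sim: Simulation) -> dict[str, Transcript]:
    """The withheld novel-in-catalog transcripts of a simulation.

    Emits a warning if the configuration produced none (no eligible genes
    with enough exons/isoforms).
    """
    import logging

    if not sim.novel_transcripts:
        logging.getLogger(__name__).warning(
            "no eligible genes for novel isoforms under this configuration"
        )
    return sim.novel_transcripts


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for rec in truth:
            fh.write(rec.to_tsv_row() + "\n")


def read_truth(path) -> dict[str, TruthRecord]:
    out: dict[str, TruthRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            exons = [
                (int(s), int(e))
                for s, e in (iv.split("-") for iv in f[4].split(";"))
            ]
            out[f[0]] = TruthRecord(
                f[0], f[1], f[2], f[3], exons, int(f[5]), int(f[6]), int(f[7]), f[8] == "1"
            )
    return out


def write_simulation(sim: Simulation, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "gtf": out / "annotation.gtf",
        "reads": out / "reads.fq",
        "truth": out / "truth.tsv",
    }
    write_fasta(sim.genome, paths["genome"])
    paths["gtf"].write_text(sim.gtf_text)
    write_fastq(sim.reads, paths["reads"])
    write_truth(sim.truth, paths["truth"])
    return paths
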
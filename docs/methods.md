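# Methods

## Model and assumptions

splicechain treats spliced alignment as two nested chaining problems over
an exon annotation rather than as free-form split alignment. The core
assumptions are:

* the annotation's exon boundaries are (mostly) the boundaries present in
  the sample — reads from *novel combinations* of annotated exons are
  handled (NIC), reads using unannotated splice sites are not the target
  (they surface as NNC or lower-scoring alignments);
* sequencing errors are frequent but unstructured enough that a 60 %
  accuracy floor separates a true exon placement from noise for segments
  above ~10 nt, while 5–8 nt exons carry too little signal for approximate
  matching and are required to match exactly; exons ≤ 4 bp are ignored —
  at that length near-random hits would flood the chaining stage;
* no splice-site motif scoring. Junction placement comes entirely from the
  chaining objective and the affine alignment; this deliberately avoids
  overfitting to canonical GT–AG junctions.

## Index construction

Parts are connected components of the exon interval-overlap graph
(touching-but-not-overlapping exons do not merge). Flanks catch reads
overrunning annotated gene ends: the rule is one flank of up to F per part
side; a gap between parts shorter than F becomes a single whole-gap flank;
a gap in [F, 2F) is split at its midpoint so that flanks stay ≤ F and
disjoint. F defaults to 1000 nt — the scale of a typical UTR overrun — and
is a flag.

Segments partition each part at every exon start/end coordinate. Adjacent
coordinates closer than X_seg = 25 nt trigger the iterative extension rule
(extend to the next coordinate outward in each direction independently,
first success wins); if no extension can reach X_seg the whole part is
emitted as one small-flagged segment. Segments and exons shorter than the
small threshold (equal to X_seg by default) live only in the per-gene
small container; they are excluded from regular segment lists but are
force-included as MAM candidates whenever a seed hits their gene — this is
the device that makes small exons alignable at all.

## Seeding

The MEM finder hashes all L-mers (L = `min_mem_length`, default 20) of the
part/flank sequences; every maximal match of length ≥ L contains a
left-maximal L-mer at its start, so extending right from left-maximal seed
hits enumerates the complete MEM set exactly once. The contract (the full
set of maximal exact matches ≥ L, block boundaries count as maximality) is
what the tests assert, against an equality-matrix diagonal-scan oracle; the
hash-based finder is an implementation choice, not part of the contract.
Both read orientations are seeded; orientation is carried through chaining
and the final score decides. Instances split at genomic gaps above
`max_instance_gap` (default 500 kb, a generous intron-span bound).

## Chaining

**MEM pass.** Coverage of a chain counts each read nucleotide once: the
first anchor contributes its full read interval, each successor only the
part beyond the predecessor's read end (clamped at zero). This pairwise
form makes the objective decompose over consecutive anchors, so the
quadratic DP is exact; the test oracle applies the identical chain-scoring
formula to every enumerated subset, so the oracle checks the optimisation,
not the formula. Genome overlap between chained MEMs is forbidden; chains
require strictly increasing genome and read starts (weak precedence).
Tracebacks resolve ties toward the highest-index (closest) predecessor,
and all co-optimal end points are traced (duplicated genes commonly
produce several), capped at `max_alignments` (default 5). Instances are
solved in decreasing upper-bound order; once an upper bound falls below
`dropoff` (default 0.95) times the best coverage found, the rest are
skipped.

**MAM pass.** The weight of appending MAM *y* after *x* is
`(v(y) − o(x,y))·y.acc − λ·o(x,y) − δ·d(x,y)` with `o` the read overlap
and `d` the read gap (both clamped at zero; the sentinel start has
`o = d = 0`). λ = 0.5 and δ = 0.1 by default: overlap is penalised harder
than distance because overlapping MAMs indicate conflicting exon
placements while read gaps may simply be error runs. Both are flags. The
DP enforces weak precedence strictly on both coordinates — two anchors
sharing a genome or read start cannot be chained — and is quadratic;
per-locus instances are small enough that a sub-quadratic structure is not
needed.

## MAM discovery

Segments are placed into the read with edlib in infix (semi-global) mode:
the segment is consumed in full, read end-gaps are free. Accuracy is
matches divided by the segment's genomic length, computed from the
extended CIGAR. Multiple placements per segment (tandem copies, repeated
exons) are enumerated by repeated best-hit extraction: take the best
placement, mask its read interval, search again, up to 8 placements (flag).
Among co-optimal minimum-edit-distance locations the highest-accuracy one
is taken (ties leftmost). Exact-band exons (5–8 nt) are located by exact
substring search; every occurrence is an accuracy-1 MAM.

## Final alignment and reporting

Chained segments that overlap or abut on the genome are merged before
concatenation (a zero-length intron is not representable), then the read
is aligned to the concatenation with Biopython's PairwiseAligner: affine
gaps (a gap of length k costs `gap_open + k·gap_extend`; defaults 3 + k),
free end gaps on both sequences. Defaults (match +2, mismatch −2) are
chosen so the unaligned threshold `score < X·m·r` with X = 0.5 sits at
exactly 25 % substitution errors; only the match score is structural, the
rest are flags. X = 0 disables the filter entirely (the limit case).

Projection walks the aligned blocks with a single reference cursor:
junction breakpoints inside a reference-consuming run insert an `N` of the
recorded intron length; a deletion ending exactly at a breakpoint defers
the `N` to the next run, so deletions abutting a junction land before the
`N` (deterministic, left-normalised). Unaligned read termini become soft
clips; `M + I + S` always sums to the read length. The reported edit
distance (NM) counts mismatches plus inserted and deleted bases, excluding
clips and introns.

Primary selection: highest score, then shortest genomic span, then most
junctions matching annotated splice sites. Splice categories (CN tag)
compare the alignment's junction chain with the transcript catalog; the
FSM/ISM comparison uses junction chains only, ignoring transcript
start/end coordinates.

## Truth-based evaluation

For simulated reads, an alignment is *correct* when it overlaps the true
locus, has the true number of junctions, and every splice site is within
the tolerance (default 15 nt — larger than plausible indel sequencing
error, so misses beyond it indicate alignment error; strict mode uses 0).
Same locus and junction count with a site off by more is *inexact*;
differing junction counts is *exon_difference*; no locus overlap is
*incorrect_location*. Terminal exon boundaries are deliberately not
constrained — long-read protocols truncate transcript ends for reasons
unrelated to alignment quality. Per-exon accuracy (the small-exon
analysis) asks, for each *internal* true exon, whether both flanking
splice sites appear in the alignment within tolerance.

## Synthetic data

The generator emulates: multi-exon genes on both strands laid left to
right on a random-sequence genome; internal exon lengths from a two-band
mixture (small band 6–25 nt with probability 0.2, regular band 30–300 nt;
terminal exons always regular so reads have seedable ends); introns
60–600 nt; up to three isoforms per gene. Withheld novel-in-catalog
isoforms are built by double exon skipping with both single-skip isoforms
annotated, so every junction of the withheld transcript is annotated but
the combination is not. Error model: i.i.d. per-base substitutions,
insertions and deletions (defaults 0.04 / 0.015 / 0.015, 7 % total), read
orientation flipped with probability 0.5.

What it does **not** emulate — and hence what passing tests do not show:
homopolymer-biased errors, platform-specific error profiles, genomic
repeats and paralogy (the genome is random sequence, so placements are
almost always unique), incomplete annotations, intra-priming artifacts,
and expression-weighted sampling. Results on real data depend on exactly
these features; the synthetic results demonstrate the algorithmic
machinery, not field performance.

## Problem sizes

The default study runs on a 20-gene, ~100 kb single-chromosome genome with
2000 noisy reads, two error-free reads per annotated transcript and 200
novel-isoform reads; oracle agreement uses 300–1000 random chaining
instances, 100–300 random sequence pairs. These sizes keep the whole suite
and the acceptance script at desk scale (about a minute each) while every
gene structure class (small exons, multiple isoforms, both strands) is
exercised.

## Known limitations

* Chaining imposes no genomic-distance penalty between MAMs, so a
  same-instance chain can in principle bridge two similar genes; instance
  partitioning (500 kb) is the only guard.
* MAM placement picks the best location among minimum-edit-distance
  placements; a placement with strictly larger edit distance but higher
  accuracy (more read insertions, fewer mismatches) is not found.
* The O(n log n) search-tree formulation of the coverage chaining exists;
  this implementation uses the quadratic DP throughout, which is ample at
  per-locus instance sizes but would not scale to whole-genome instances.
* Hybrid mode ingests an external SAM; it does not spawn the external
  aligner itself.
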
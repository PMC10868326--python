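# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `phasekit` at the level of detail a maintainer or careful
user needs. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem statement and model

For a single diploid sample we are given called variants (small, structural
and tandem-repeat classes, possibly multi-allelic), coordinate-sorted
aligned long reads, and the reference. Phasing is solved per *phase block*
as a weighted minimum error correction (wMEC) instance: the block's reads
form a matrix with one row per read and one column per heterozygous site,
each entry an observed allele index with a non-negative integer weight (the
cost of ignoring or altering that observation). The objective is a pair of
haplotypes (h1, h2) — each an allele index per site, constrained at every
site to the two called genotype alleles — minimising
`Σ_reads min(cost(row→h1), cost(row→h2))`.

Assumptions: the sample is diploid; genotypes are taken as called (phasing
never re-genotypes); homozygous sites carry no phase information and are
used only as re-alignment context; blocks are independent once formed.

### Coordinates, weights, sentinels

All internal coordinates are 0-based half-open; VCF's 1-based convention is
confined to the file boundary. Weights are integers on a phred-like scale
capped at 60, so solver costs are exact integers and oracle comparisons are
bit-stable. Two zero-weight sentinels are distinguished and reported
separately in statistics: AMBIGUOUS (conflicting evidence, e.g. an
edit-distance tie or a collapsed conflict) and UNKNOWN (no evidence, e.g. a
site outside the mapping).

## Phase block generation

Heterozygous sites are swept in order. The block is extended when a
mapping with MAPQ ≥ `min_mapq` (default 5) fully contains both the new
site's reference span `[pos, pos + len(ref))` and at least one block site's
span, or when two distinct same-name mappings — at least one flagged
supplementary — cover the new site and a block site respectively. Full
containment (not partial overlap) is required so that abutting reads do not
create phantom connectivity; a single spanning or bridging mapping
suffices (configurable in principle, but one is the default and the tested
contract). The supplementary rule is what lets blocks span coverage gaps at
large homozygous deletions and reference gaps, because split reads share a
name across the gap.

## Allele assignment

### Local mode

For each site fully contained in a mapping, the query subsequence projected
(via CIGAR) onto `[pos − w, end + w)` with `w = window_pad = 25` bp is
scored by edit distance (edlib) against each allele's windowed sequence.
The argmin allele wins; a tie yields AMBIGUOUS. The weight is the minimum
base quality inside the projected window, capped at 60 — tying the weight
to the local evidence quality. 25 bp exceeds typical homopolymer/indel
context while keeping windows cheap; it is deliberately too small to
discriminate structural or tandem-repeat alleles, which is the role of
global mode.

### Alt-aware graph and global mode

A block's reference segment (padded 50 bp beyond the outermost site spans)
becomes a DAG: linear reference pieces interleaved with branch clusters,
one cluster per maximal group of overlapping site spans. A cluster's
branches enumerate the joint allele combinations of its sites, each combo
spelled by applying alleles left-to-right with a cursor; combinations whose
edits collide (a non-reference allele starting inside a span consumed by an
earlier deletion) are excluded, so every source-to-sink path spells a
consistent local haplotype and the all-reference path spells the reference.

A mapping is aligned to the sub-graph clipped to its reference span
(clusters only partially covered are excluded and their sites reported
UNKNOWN). The alignment is an exact unit-cost edit-distance DP propagated
column-wise over the DAG, vectorised over the query with a prefix-min scan;
a forward and a backward pass plus per-branch rescoring give, for every
site and allele, the optimal alignment cost attainable through that allele.
The chosen allele minimises this cost; the weight is the margin to the best
alternative (capped at 60), and a zero margin is AMBIGUOUS — so weight 0
exactly when forcing the other allele costs nothing. A read whose optimal
cost exceeds 0.3 per aligned base is reported all-UNKNOWN as likely
mismapped. Wavefront-style acceleration would be output-equivalent by
construction and is intentionally not implemented; instances at this scale
do not need it.

### Dual mode and the fallback budget

Global alignment cost grows with read length × graph length. Dual mode
(the pipeline default) computes each block's projected DP work as
`Σ_mappings overlap(mapping, graph)²` cells and falls back to local mode
for the whole block when it exceeds `global_budget` (default 10⁹ cells).
Counting projected cells rather than elapsed time makes the decision
deterministic and machine-independent; because the estimate is available
before aligning, no work is discarded on fallback. The decision is strictly
per-block — outputs always match one of the two pure modes per block — and
fallback blocks are flagged in the statistics.

### Collapsing

Same-name mappings merge into one condensed read per name: UNKNOWN entries
drop; conflicting concrete alleles at a shared site become AMBIGUOUS
(weight 0); an AMBIGUOUS call also dominates a concrete one (the conflict
has already been witnessed); agreeing duplicates keep the larger weight.
The result is independent of mapping order.

## Diplotype solving

### A* search

The search assigns sites left to right; a depth-j node fixes the
orientation of sites `< j`. Site 0 is symmetry-fixed (smaller genotype
allele on h1), every other site contributes two children (which called
allele goes to h1). `g` is the partial wMEC cost — per straddling read the
pair of accumulated costs against h1 and h2, summed as `min(c1, c2)`;
finished reads fold into a scalar. Nodes pop in ascending `f = g + h` with
a deterministic tie-break (deeper first, then lexicographically smallest
partial h1), which fixes the returned optimum among ties independently of
the heap implementation.

**Heuristic.** Columns are partitioned once into consecutive chunks of
`chunk_size = 8`; each chunk's wMEC optimum is solved exhaustively
(2⁷ orientations) on reads restricted to its columns. `h(j)` is the sum of
optima of chunks starting at or after `j`. This is admissible — per read,
minima over disjoint column subsets sum to at most the minimum over all
remaining columns, and chunk optima ignore cross-chunk consistency — and
consistent, because the cost accrued while traversing a chunk's columns is
at least that chunk's optimum. Consistency means the first goal popped is
optimal and no node is ever reopened.

**Pruning.** Two frontier states at the same depth that agree on all
*active* sites (assigned sites still covered by a read reaching past the
frontier) have identical completion costs, since every partial read cost is
determined by active sites; duplicates are pruned keeping the smaller `g`.

Every condensed read participates — there is no down-sampling and no node
budget; the search is exact by construction and verified against exhaustive
enumeration (≤ 10 sites) in the test suite.

### Post-split

After solving, a junction between consecutive sites that no collapsed read
supports — no read with concrete alleles on both sides matching one of the
two solved haplotypes on both sides — starts a new phase set. Splitting
only moves boundaries; within-block assignments are untouched. This is how
the putative blocks' lower-bound property is realised.

### Single-site blocks

Solvable in principle, but a one-site block carries no phase information;
the pipeline reports them in statistics and leaves their site unphased in
the VCF.

## Metrics

*Switch/flip*: per solved block, the agreement sequence between predicted
h1 and truth h1 is formed over sites phased in both; transitions are
classified greedily left-to-right — two adjacent transitions bounding a
single-site run are one flip, any remaining transition is one switch
(`switches + 2·flips` equals the raw transition count). Complementing the
sequence leaves transitions unchanged, so per-block orientation cannot
affect totals. *NG50* uses a fixed reference length as denominator (the
FASTA total by default, configurable). *Phased counts* tally het sites in
solved multi-site blocks by variant class. *Gene phasing*: a gene is fully
phased iff all het sites in its interval belong to one solved multi-site
block; genes with no het sites count as (vacuously) phased, and a stricter
block-must-span-the-gene reading is available via a flag.

## Synthetic data

The generator emulates the full input triad. Defaults model a HiFi-like
study condition: SNV rate 10⁻³/bp (75% het 0/1, 15% hom-alt, 10%
multi-allelic 1/2), short-indel rate 2×10⁻⁴/bp (1–10 bp), heterozygous SVs
(insertions/deletions 50–200 bp), tandem-repeat sites as motif
copy-number differences between haplotypes (motifs 2–4 bp, ±1–3 copies),
read length 18 kb at 30× coverage, Poisson read counts, uniform starts,
flat base quality 30 and MAPQ 60. Reads are drawn at the allele level from
one truth haplotype, with optional per-site corruption; sequence + CIGAR
rendering splices the observed alleles into the reference so re-alignment
sees realistic queries. Homozygous deletions split crossing reads into
primary + supplementary records sharing a name.

Not modelled: base-level sequencing-error profiles, mapping/reference bias,
read-length variation, non-uniform coverage. Passing tests therefore
demonstrate algorithmic correctness under the stated generative model, not
end-to-end accuracy on real sequencing data, where allele assignment (not
the solver) would absorb most of the extra noise.

The end-to-end test and acceptance conditions use a 200 kb genome — large
enough for hundreds of sites, multi-block structure and all three variant
classes, while keeping a full pipeline run in seconds.

## Numerical and degenerate-input choices

- Integer weights capped at 60; sentinel observations always weight 0.
- Canonical diplotype orientation `h1[0] ≤ h2[0]`; brute-force ties break
  to the lexicographically smallest h1; the A* tie-break is as above.
- Empty site lists are an error to the solver; empty chromosomes are
  skipped with a log line; a mapping without sequence/CIGAR degrades to
  all-UNKNOWN rather than failing.
- Variant records failing filters (non-PASS), non-diploid or half-called
  genotypes are excluded at read time; identical records across input
  files deduplicate preferring the small-variant file.
- The parallel unit is the putative block; results are collected in
  genomic order, so output bytes are identical for any worker count.

## Known limitations

- Polyploid genotypes and multi-sample VCFs are out of scope.
- Inversions and copy-number variants are not phased.
- The DP-cell fallback proxy tracks alignment *work*, not wall-clock; a
  pathological machine-specific slowdown cannot trigger fallback.
- Graph clusters enumerate joint allele combinations exhaustively; dozens
  of mutually overlapping sites in one cluster would blow up
  combinatorially (not reachable under the generator, which separates
  variant spans).
- A* worst-case node count is exponential; the chained heuristic keeps
  realistic instances (hundreds of sites, 2% corruption at 30×) fast, but
  adversarial weight patterns could be slow — by design there is no
  approximation fallback.
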
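# Methods

## The model

svresolve resolves genomic rearrangements "top down": instead of mapping
particular patterns of aberrant read pairs onto presupposed variant types,
it proposes candidate structures for a region and asks how well each
explains the observed sequencing data. A region is defined by a cluster of
n breakpoints (BPs); the n−1 blocks between adjacent BPs are the units of
rearrangement. An allele is a sequence of oriented blocks; a diploid
structure is a pair of alleles. The reference structure is the identity
ordering with all blocks forward.

### Null models

Everything is scored against null models fitted on copy-neutral (CN2)
regions:

* **Insert size** f_IS — normal N(μ_IS, σ_IS²) by default; optionally a
  two-component normal mixture fitted by EM for libraries with bimodal
  insert distributions. Fitted on proper forward–reverse pairs; duplicates,
  secondary/supplementary alignments and MQ0 reads are excluded.
* **Read depth** f_RD and **physical coverage** f_PC — per 100 bp window
  (configurable). RD counts reads whose leftmost aligned base falls in the
  window; PC counts fragments (leftmost read start to rightmost read end)
  spanning the window midpoint. Both normal by default; a negative-binomial
  option derives (r, p) from the sample moments as r = μ²/(σ²−μ),
  p = 1 − μ/σ², which requires overdispersion (σ² > μ) and fails loudly
  otherwise. The counting conventions are fixed choices made for
  determinism; any consistent convention works because the same convention
  is used at fit and at scoring time.

Log densities are floored at −50 per observation so that a proposal that
cannot explain a read at all contributes a large but finite penalty;
without a floor a single unexplained observation would veto every
structure, including the truth in noisy data.

Excluded regions (reference N-runs merged with user-supplied excludable
BEDs such as mappability blacklists) are masked from breakpoint discovery.
Without a CN2 annotation the fitter falls back to random mask-free windows,
which is adequate for synthetic genomes; for real genomes a curated CN2 BED
should be supplied.

### Breakpoint discovery

A read pair is aberrant if its insert lies outside μ_IS ± s·σ_IS (s = 3 by
default), if its orientation is not forward–reverse, or if a read carries a
soft clip of ≥ 10 % of the read at mean base quality ≥ 20. Same-orientation
discordant anchors within μ_IS + 2σ_IS are single-linkage clustered.
Within a cluster's directional window (rightward of a forward cluster,
mirrored for reverse) clip positions are collated; the modal clip position
becomes the breakpoint, falling back to the cluster's extreme coordinate
when no splits exist. A breakpoint is kept when split reads exceed 20 % of
the local read depth or all aberrant reads exceed 30 %. Additional
well-supported clip positions in the same window (each individually passing
the 20 % rule) are also emitted, because one discordant cluster can
legitimately front two junctions (e.g. a short inversion). Local read depth
is the 100 bp window start count at the candidate position scaled to
per-base depth. Breakpoints are deduplicated within 10 bp, breakpoints
paired by mates of their supporting reads plus proximity (< 1 kb) edges are
joined, and connected components with ≥ 2 breakpoints become clusters.
Clusters beyond 8 breakpoints are split at their widest adjacent gaps
(ties resolved toward the most central gap) to cap the structure space.

### Structure scoring

For structure j with n read pairs in the region (the region is the cluster
span padded by μ_IS + 3σ_IS on both sides):

    S_j = Σᵢ Score_IS_ij · (1 + Σᵢ Score_PO_ij / n)
          + τ · Σ Score_RD · (1 − Σ Score_PC)

* Score_IS_ij = log f_IS(implied insert of pair i under structure j).
* Score_PO_ij = 1 if the implied pair orientation is forward–reverse, else 0.
* Score_RD = log f_RD per 100 bp window, summed over the region's windows.
* Score_PC = log f_PC per novel junction of the structure.
* τ = log f_IS(μ_IS) / log f_RD(μ_RD) puts the two halves on one scale.

**Read projection.** Each read end is located in a layout element (left
flank, block, right flank, with flanks extended linearly beyond the region
so outside mates remain projectable) and relocated to the element's
position in the candidate layout; inverted occurrences mirror the offset
and flip strand. When a block occurs multiple times, the placement
maximizing agreement with the insert-size null (with a strong penalty for
non-FR placements) is chosen; on a diploid structure each pair is assigned
to the allele that explains it better. A pair whose block is absent from
both alleles is unexplained: it scores the floor and counts as non-FR,
while still being counted in n.

**Count expectations.** RD and PC are scored as deviations from
copy-number-scaled expectations by evaluating the null at
(μ + observed − expected): a window in a block with total copy number c
across the two alleles has expectation μ_RD·c/ploidy, and a junction
present on m alleles has expectation μ_PC·κ·m/ploidy. This keeps the
null's mode exactly at "structure explains the data" for any copy number,
including zero, without refitting per-CN distributions. The factor
κ = 1 − read_len/μ_IS discounts junction coverage for fragments whose read
straddles the junction: such reads are soft-clipped at the junction, so
their fragment interval abuts rather than spans it, for any aligner.

The literal formula couples the RD and PC sums multiplicatively: a
structure with a poorly supported junction amplifies its whole read-depth
penalty. On all planted fixtures the truth structure outscores both the
reference and single-edit alternatives under this literal form, so it is
implemented exactly as stated.

### The search

One iteration draws a rearrangement type (deletion, inversion, insertion)
and applies it at every block position of the active allele, producing a
candidate set that always includes the unchanged structure; in diploid mode
the active allele alternates per iteration (heterozygous mode keeps the
second allele fixed at the reference; homozygous mode mirrors it). The
next structure is drawn by softmax over candidate scores. Because S_j is a
sum over reads and windows, its magnitude grows with region size, so the
softmax unit is a fraction (5 %) of the best candidate's magnitude rather
than a fixed temperature — a scale-free selection under which near-ties
genuinely mix, clearly better structures almost always win, and moderately
worse intermediates are occasionally accepted, which is what lets the chain
cross the score valleys that separate the reference from multi-edit
structures.

Every structure must keep each block's total copy number within
[max(0, ĉ−1), ĉ+1], where ĉ = round(ploidy · block depth / μ_RD) from
local RD. The bounds constrain the diploid total (not the per-allele
count — a per-allele floor of ĉ−1 would forbid heterozygous deletions).

Termination: the first pass ends when the incumbent best structure has not
improved for 100 consecutive iterations (or at 100 000 iterations); the
search then restarts from the reference for another 100 iterations during
which any proposal equal to the converged structure is excluded from the
candidate set; the best-scoring structure seen anywhere is returned. The
stall counter tracks "no new best" rather than "no change", because the
scale-free softmax keeps the chain jittering around an optimum it will not
leave. A deterministic hill-climbing variant (best single-move neighbor
until a local optimum) and an exhaustive enumeration within the CN bounds
(the oracle for small clusters, refused above a candidate cap) are
provided alongside.

### Interpretation

The converged allele is tokenized into maximal collinear runs; a weighted
ordered-subset match against the reference marks the tokens that are "in
place". Uncovered blocks are deletions; kept inverted tokens are
inversions; unkept tokens are duplication copies (tandem when a
neighbouring symbol repeats the same block, else dispersed with an
insertion point) when their blocks occur elsewhere, otherwise moved blocks
(intra-chromosomal translocations). One edit kind in a cluster yields
simple calls, homozygous when both alleles carry the identical edit;
co-occurring kinds collapse to one complex (CSV) call labelled by the kind
set (DEL+INV, INV+DUP, DEL+DUP, DEL+DUP+INV, otherwise "other"). Calls are
written as VCFv4.1 — symbolic ALTs for deletions, tandem duplications and
inversions; breakend pairs plus a BLOCKS INFO tag for dispersed
duplications, translocations and CSVs — and as a custom one-line-per-
cluster text format (chromosome, breakpoints, both allele structure
strings, score) that round-trips through its parser.

### Long-read validation

A predicted SV is tested against long reads by recurrence scoring: slide a
10 bp window along the read, record every exact match position against the
local reference (both strands, as in a dot plot — an inverted segment then
appears as off-diagonal points instead of vanishing) and sum the vertical
deviations |x−y|. Each read is scored against the original local sequence
and an altered one implementing the call; S_j = S_orig/S_alt − 1 is
positive when the read favours the altered structure (a read matching the
altered sequence perfectly, S_alt = 0 with S_orig > 0, gets a large
positive constant). The validation score S_val is the fraction of
informative reads (both-zero reads are excluded) with S_j > 0; an SV
validates at S_val > 0.5 (haploid) or > 0.3 (diploid). Regions whose
self-recurrence deviation exceeds 100 per base are non-assessable, the
guard against repeat-driven inflation; the threshold suits windows up to a
few kilobases (expected spurious deviation grows roughly with L²/4^k).
SVs over 5 kb are validated junction by junction on ± 500 bp flank windows
— the original window spans both reference loci of the junction so distal
read content still registers — and every junction must validate
(conjunction); one non-assessable junction makes the SV non-assessable.
Reads are hard-clipped to the window start using their alignment start
coordinate and dropped if they cover less than half of the junction
neighbourhood. Read orientation is canonicalized against the local
reference by forward k-mer count before scoring.

## The synthetic generator

`plant_svs` edits a reference into two haplotypes carrying DEL, INV,
tandem/dispersed DUP, TRA and the complex classes (inverted duplication,
deletion-inversion, deletion-duplication, deletion-inversion-duplication),
homozygous (both haplotypes) or heterozygous (haplotype 0). Novel
junctions are decorated with probability 0.3 each with either a 0–10 bp
micro-insertion or a 2–6 bp STR unit repeated 2–5 times, mimicking
breakpoint micro-homology artifacts; reported values lacking a published
number (the decoration rates) were chosen once as plausible and are
configurable. `simulate_reads` draws fragments uniformly per haplotype at
half the total depth each, with insert N(500, 50²), 101 bp reads,
forward–reverse orientation and optional uniform substitution errors —
the standard study conditions throughout (10–50X supported, 30X default).

Simulated reads are placed into a BAM by an internal projection aligner
that uses the known haplotype-to-reference segment map: a read is anchored
on the reference segment holding its longest part, bases beyond that
segment are soft-clipped, reads in inverted segments flip strand, and
anchors under 20 bp are dropped. This is a design choice for determinism
and hermetic tests; an external simulator/aligner (wgsim + bwa) can be
swapped in behind the same FASTQ contract. What the generator does *not*
emulate: alignment ambiguity in repeats (every read has MAPQ 60), indel
sequencing errors, GC and coverage bias, chimeric fragments, and reference
N-regions. Passing the benchmark therefore demonstrates correctness of the
models, search and interpretation under idealized alignments, not
robustness to real-genome mapping artifacts — the mask and MQ filters
exist for the latter but are exercised only lightly here.

## Benchmark protocol and problem sizes

The standard studies (all at 30X, events ≥ 20 kb apart, CN2 windows taken
from the gaps between events; all reproducible through
`scripts/acceptance.py`):

* **Formula fidelity** — a five-pair hand-written region; the composite
  score must match an independent transcription of the formula to 1e-9,
  and the negative-binomial moment mapping must round-trip to 1e-12.
* **Search vs enumeration** — 50 heterozygous 2–3-block complex events on
  a 1 Mb contig; the randomized search must reach the enumerated global
  maximum (single-altered-allele module, where full enumeration is
  tractable) in ≥ 95 % of clusters.
* **Simple recovery** — 20 planted deletions of 500 bp–10 kb, homozygous
  and heterozygous runs; sensitivity and FDR by strict > 50 % reciprocal
  overlap with type match; genotype accuracy on the heterozygous run.
* **Complex recovery** — 10 deletion-inversions and 10 inverted
  duplications; junction-level sensitivity (50 bp tolerance on both
  junction coordinates, matching exit/entry directions) and the fraction
  of events whose full block structure is reproduced exactly.
* **Long-read validation** — error-free 8 kb reads from an altered
  haplotype; S_val must be 1.0 for the true call, 0.0 for a fabricated
  call on unaltered sequence, and an (AC)₅₀₀ repeat must be flagged
  non-assessable.
* **Null control** — 5 Mb unaltered genome at 30X; at most one call, and
  the emitted VCF must parse.

## Numerical choices and degenerate inputs

* Log-density floor −50; softmax scale 5 % of |best| at temperature 1.
* Zero-variance insert samples, underdispersed counts in
  negative-binomial mode, a single coverage window, an empty region
  (n = 0), and unfitted models all raise errors rather than degrade.
* Proposal ties and equal candidate scores break deterministically
  (first-listed candidate; leftmost modal clip position).
* All randomness flows from explicit integer seeds; per-cluster seeds are
  derived arithmetically from the run seed, and identical (seed, input)
  pairs give identical output.

## Known limitations

* Inter-chromosomal rearrangements are detected as evidence but not
  resolved; translocation calls are intra-chromosomal moved blocks.
* Clusters whose blocks exceed 50 kb are left unresolved (dispersed
  duplications with very distal insertion points fall here).
* The diploid search assumes ploidy 2 everywhere; aneuploidy and mosaic or
  tumor-heterogeneous samples are out of scope.
* Insertion content is not reconstructed; novel insertions appear at best
  as unexplained coverage.
* The recurrence validator relies on exact k-mers; at realistic long-read
  error rates many windows simply do not match, which the score tolerates
  (only matched points contribute) but power drops with error rate, and
  the fixed assessability threshold is calibrated for windows up to a few
  kilobases.
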
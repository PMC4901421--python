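# svresolve

Resolve simple **and complex** structural variants (SVs) from paired-end
short-read alignments by randomized iterative rearrangement of the blocks
between breakpoints — plus a long-read recurrence-plot validator and a
synthetic benchmark suite.

Most short-read SV callers work bottom-up: they look for a particular
signature (long inserts ⇒ deletion, everted pairs ⇒ tandem duplication, …)
and therefore mis-read regions where several rearrangements overlap — the
common complex classes such as inverted duplications and
deletion-inversions. svresolve works top-down. It finds clusters of
breakpoints from discordant read pairs and split reads, then **virtually
rearranges** the n−1 blocks between the n clustered breakpoints on one or
two alleles, scoring every candidate structure against null models of the
library and keeping the structure that best explains the data. It is aimed
at researchers analysing whole-genome paired-end data who need correctly
*resolved* rearrangement structures (with haplotype separation and
genotypes), not just breakpoint lists.

## The score

For a candidate structure *j* and the *n* read pairs in the region, with
fitted nulls f_IS (insert size), f_RD (read depth / 100 bp window) and
f_PC (physical coverage through a junction):

```
S_j = Σᵢ Score_IS_ij · (1 + Σᵢ Score_PO_ij / n) + τ · Σ Score_RD · (1 − Σ Score_PC)

Score_IS_ij = log f_IS(IS_ij)        Score_PO_ij = 1 if FR else 0
Score_RD    = log f_RD(RD per window) Score_PC   = log f_PC(PC per junction)
τ           = log f_IS(μ_IS) / log f_RD(μ_RD)
```

where IS_ij, PO_ij are the insert and orientation *implied* for pair *i*
after projecting its ends onto structure *j*. Structures are proposed by
random simple rearrangements (deletion, inversion, insertion of a block),
selected by softmax over scores, constrained to local-depth-derived copy
number bounds (CN−1 … CN+1), and converged with a two-pass protocol (stall
after 100 unimproved iterations, then 100 more avoiding the converged
structure, best overall wins). Low-coverage data can switch the nulls to a
bimodal insert mixture and negative-binomial counts with
r = μ²/(σ²−μ), p = 1 − μ/σ².

See `docs/methods.md` for the full model, the projection contract, and
every default.

## Worked example

The package can build its own study: plant events in a random reference,
simulate 30X paired-end reads (101 bp, insert 500 ± 50), and call them.

```python
import svresolve as sv

ref = sv.random_reference("ref.fa", {"chr1": 300000}, seed=11)
events = [
    sv.PlantedSV("DEL",     "chr1", {"span": (60000, 61500)},  zygosity="het"),
    sv.PlantedSV("DEL_INV", "chr1", {"a": (180000, 181000),
                                     "b": (181000, 182500)},   zygosity="hom"),
    sv.PlantedSV("INV_DUP", "chr1", {"span": (240000, 241000),
                                     "insert_at": 243000},     zygosity="hom"),
]
haps, truth = sv.plant_svs(ref, events, seed=2)
bam = sv.simulate_to_bam(haps, ref, depth=30, out_bam="sim.bam", seed=3)

lib, cov, mask = sv.fit_null_models(bam, ref,
                                    neutral_regions=[("chr1", 5000, 55000)])
calls, clusters = sv.call_variants(bam, ref, lib, cov, mask,
                                   mode="diploid", seed=5)
for c in calls:
    print(c.type, c.csv_subtype, c.start, c.end, c.genotype,
          c.allele_a, "/", c.allele_b)
```

prints

```
DEL  60000 61500 het a / -
CSV DEL+INV 180000 182500 hom b^ / b^
CSV INV+DUP 240000 243000 hom aba^ / aba^
```

Reading the structure strings: blocks between adjacent cluster breakpoints
are labelled `a`, `b`, …, `^` marks inversion, `-` is the empty allele.
The heterozygous deletion keeps one reference allele (`a`); the
deletion-inversion converged to a single inverted block with the first
block deleted (`b^`) on both alleles; the inverted duplication to
`a b a⁻` — the source block, the spacer, and an inverted extra copy —
classified as INV+DUP with its insertion point.

The same pipeline is exposed as a command-line tool:

```
svresolve simulate --ref ref.fa --spec events.json --depth 30 --seed 4 --out-prefix sim
svresolve null     --bam sim.bam --ref ref.fa --out model.json
svresolve call     --bam sim.bam --ref ref.fa --model model.json --out-prefix out --seed 7
svresolve evaluate --calls out.vcf --truth sim.truth.json
svresolve validate --reads pacbio.bam --ref ref.fa --calls out.calls.tsv --ploidy 2
```

`call` writes VCFv4.1 (symbolic ALTs for DEL/DUP/INV, breakend pairs for
dispersed duplications, translocations and complex calls) and a custom
one-line-per-cluster format with both allele structure strings.
`validate` scores each call against long reads with the recurrence
(dot-plot) deviation score: a read supports the call when its summed
diagonal deviation against the rearranged local reference is smaller than
against the original (S_j = S_orig/S_alt − 1 > 0); a call validates when
the supportive fraction exceeds 0.5 (haploid) / 0.3 (diploid).

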
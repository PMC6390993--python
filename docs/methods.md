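# Methods

This note documents the models behind `snreadthrough`: what the simulator
emulates, how each estimator is defined, the defaults that matter, and what
the package's passing tests do and do not establish about real data.

## The simulator

### Genome and annotation

`build_toy_genome` lays snRNA loci and multi-exon genes onto random sequence
at a configurable GC content (default 0.36, nematode-like). Coordinates are
0-based half-open internally; GFF3 output is 1-based closed and BED12 output
0-based half-open. Each locus records its mature span, the 3′ cleavage
coordinate (`mature_end`) and its downstream partner; mature snRNA lengths
are constrained to the canonical 60–200 nt. Two sequence features are
planted deterministically because the translation analysis depends on them:

- every gene gets an ATG at its annotated translation start;
- SL-like snRNA bodies and their intergenic regions are made ATG-free
  (each ATG's G is substituted by C, which can never create a new start
  codon), while U1-/U2-like bodies receive planted ATGs at fixed offsets.

This mirrors the sequence property that decides whether a chimeric
transcript translates the downstream protein: SL-derived chimeras do, U1/U2
chimeras open upstream ORFs instead. snRNA secondary structure, which also
suppresses translation in reality, is deliberately not modelled; the
classifier is a pure function of sequence and offset.

### Transcript pool

Per locus, `Binomial(snRNA_copies, f)` transcripts fail 3′ processing, where
`f` is the planted unprocessed fraction (scalar or per-class). Sense-oriented
failures become chimeric sn-mRNAs running from the snRNA 5′ end to the
downstream gene's annotated end, with each intron independently retained
with probability `ir_prob` (default 0.165) and spliced out otherwise;
antisense-oriented failures become single-block antisense chimeras covering
the gene on the locus strand. Remaining copies are mature snRNAs ending
exactly at the cleavage point. Every gene also emits `mRNA_copies` native
mRNAs with per-intron retention `ir_prob_native` (default 0.01). A locus
with no downstream partner emits an unprocessed primary transcript extending
`primary_extension` (default 600 bp — a free parameter, since the length
distribution of uncleaved transcripts is not otherwise constrained) past the
cleavage point.

### Fragmentation model

Reads are simulated directly from transcripts — ground-truth placement
instead of an external aligner — under a forward stranded protocol (read
strand = transcript strand). Fragment *starts* are uniform over the whole
transcript; a fragment extends `read_length` (default 50) bases 3′-ward and
is truncated at the transcript end. Two consequences drive the design:

1. no read ever crosses a transcript boundary, so a fully processed locus
   shows *exactly* zero depth past its cleavage point (the null is exact,
   not approximate);
2. expected depth at any base ≥ `read_length` from the 5′ end equals
   `fragments_per_kb/1000 × read_length` regardless of transcript length,
   which makes the coverage-ratio read-through estimator unbiased. (Drawing
   starts uniformly over `[0, L − read_length]` instead would deflate
   coverage of short transcripts relative to long ones by `L/(L−rl+1)` and
   bias the estimator ~30% downward for a 150-nt snRNA against a ~2-kb
   chimera.)

The price is a tail of sub-`read_length` reads near transcript 3′ ends;
no error model, quality scores, duplicates or paired ends are simulated.
Reads spanning a spliced-out intron are emitted as split (multi-block) BED12
records and counted once per junction.

### Count matrices

`simulate_count_matrix` draws gamma-Poisson (negative-binomial) counts with
per-gene lognormal base means (median `base_mean`, log-sd 1.0) and
dispersion `dispersion`; planted genes are multiplied/divided by
`fold_change` in their group's samples. `default_cohort` reproduces the
study-like design: three groups (control, holder-like, catalytic-like), a
catalytic upregulation response of 600 genes overlapped 90% by the holder
response, and kinase-like (438 genes) / phosphatase-like (206 genes)
catalogs overlapping the planted-up set in 101 and 78 genes (23% and 38% of
each catalog).

## Estimators

### Read-through index

For a catalog entry, the body window is the central mature-snRNA portion,
excluding `read_length` bases at each edge where the body allows (the edges
are coverage-deflated by the fragmentation geometry); the downstream window
is `[mature_end + δ, mature_end + δ + w)` strand-aware, defaults δ = 20 and
w = 50, chosen to clear the cleavage point while staying inside typical
intergenic gaps. `rt_index` is the ratio of mean depths, clipped to [0, 1].
Under the simulator both windows have expected depth proportional to the
transcript counts covering them, so E[rt_index] = f. The confidence interval
is a Wilson interval treating the body read count as the binomial n — a
coverage-style approximation, not an exact likelihood. A locus with zero
body depth is reported missing (`no-expression`), never as 0. The
`affected` flag defaults to rt_index ≥ 0.005 with ≥ 50 body reads; both are
reporting conventions, not biological constants, and are recorded in output.
Pooled estimates are depth-weighted (total downstream / total body depth).

### Chimera and antisense calls

Contiguity is covered-base fraction ≥ 0.8 (configurable) at depth ≥ 1 rather
than strict gap-free coverage, to tolerate sampling zeros at desk-scale
depth. Sense calls require both the intergenic region and the downstream
exonic bases to clear the threshold on the locus strand; antisense calls
require the gene-body fraction on the locus strand (the gene's antisense).
`spliced_fraction` is the share of annotated introns with ≥ 1 junction read;
an intronless gene is vacuously 1.0.

### Intron retention

`ir_ratio` counts a read as intronic when **any** of its blocks overlaps an
annotated intron ("any-overlap"); a fully-contained mode is available by
flag. Any-overlap is the default because retention signal legitimately
includes exon–intron boundary reads; the choice raises the expected ratio by
roughly `(read_length − 1)` per retained intron relative to the contained
rule. Reads are assigned strand-specifically so antisense chimeras cannot
inflate a sense gene's retention. Group comparisons use a two-sided Welch
t-test on per-gene ratios.

### Expression and clustering

Normalization is median-of-ratios over genes with all-positive counts
(falling back, with a logged warning, to total-count scaling), and the
working matrix is `log2(normalized + 1)` — a pragmatic stand-in for a
regularized log transform, adequate here because the matrix only feeds
distances, clustering and PCA, not variance-stabilized inference. The DE
test is a per-gene two-sample t-test on log counts with BH control at
q < 0.05; the dual-engine intersection of real pipelines is emulated by
intersecting its Welch and pooled-variance variants (externally produced DE
tables with the same columns can be intersected instead). Genes constant and
equal in both groups get p = 1. Hierarchical clustering uses average linkage
by default (the linkage is not otherwise determined; it is configurable),
cut into k groups; PCA retains all components so variance-explained sums
to 1.

### Enrichment

`RF = (k·N)/(K·n)` with the upper-tail convention `p = P(X ≥ k)` of the
standard over-representation calculators, evaluated via the hypergeometric
survival function (log-space internally). The universe N is a required,
always-printed input — enrichment numbers are meaningless without it.
BH adjustment is the order-preserving step-up `q_(i) = min_{j≥i} p_(j)·m/j`
capped at 1. Overlap tables report both inclusive counts (in all named sets)
and exclusive counts (in exactly those sets); exclusive counts partition the
union.

## Problem sizes and determinism

Validation simulations are desk-scale by design: read-through recovery uses
20 loci × 4,000 snRNA copies at 30 fragments/kb (~10⁴ body reads per
locus), retention uses 10 genes × ~3,000 overlapping reads, cohorts use
2,000–8,000 genes × 9 samples. At these sizes the binomial/Poisson sampling
error of the planted quantities is a few tenths of a percentage point, which
is the tolerance the tests assert (3 SE). Every random draw flows from a
single integer seed through `numpy.random.default_rng`; identical seeds give
byte-identical FASTA/GFF3/BED/TSV outputs, and the pipeline manifest records
config hash and per-file checksums.

## What passing tests do and do not show

The simulator's uniform-fragmentation, error-free, single-isoform world makes
estimator properties (unbiasedness, exact nulls, monotonicity) provable and
testable. Real libraries add 5′/3′ coverage bias, sequencing error,
multi-mapping around the highly repetitive snRNA families, trans-spliced SL
leaders that alias mature SL sequence onto mRNAs, and annotation error —
none of which are modelled. Passing tests therefore establish that the
estimators are correct *given* clean strand-specific alignments and a
faithful annotation, not that those inputs are easy to obtain for snRNA loci.
The downstream-gene pairing cap (default 5 kb) and all window/threshold
defaults are recorded in outputs precisely because they are conventions a
real analysis would need to revisit.
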
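# Methods

This note documents the models behind crspipe, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where the procedure was genuinely open.

## Coordinate and overlap conventions

All coordinates are 0-based, half-open (BED convention); GFF-like gene
models (1-based, closed) are converted at the I/O boundary. The gap between
two intervals is `start2 − end1`; intervals merge when the gap is **at most**
`max_gap` (so a 30-nt gap merges under the default `max_gap = 30`, a 31-nt
gap does not). Distance between half-open intervals is
`max(0, start2 − end1, start1 − end2)`, 0 iff overlapping. Ties in
closest-feature queries are all returned; downstream consumers decide how to
treat them (the synteny tests accept any tie member satisfying a criterion).
Interval operations are sweep-line over sorted arrays and are checked against
per-base brute-force oracles in the test suite.

## Binned false discovery rate

The shuffled companion screen preserves composition and gap structure but
destroys covariation, so its predictions estimate the false-positive process.
Because the false-positive rate varies strongly with GC content and sequence
identity, FDR is estimated per bin of an 8×8 marginal-quantile grid built on
the native motifs (the bin counts are then comparable by construction;
whether the original binning was marginal or joint is not determinable, and
marginal quantiles are the simpler reproducible choice). Shuffled motifs and
alignment blocks are mapped onto the same edges; values outside the edge
range clamp to edge bins rather than being dropped. Per bin and pscore
cutoff (default scan 50..150 in steps of 10, strict `>` comparisons):

* `FDR = min(1, shuffled / native)`, undefined (NaN) when `native = 0`;
  motifs in undefined bins are excluded from selection (conservative);
* bins backed by fewer than 100 alignment blocks are logged as
  low-reliability but kept.

Selection keeps motifs with `pscore > 80` whose bin FDR at that cutoff is
`<= 0.1`, annotating each motif with its bin FDR.

## Locus construction

Selected motifs merge strand-independently with `max_gap = 30` nt into CRS
loci (RNA structure is nearly strand-symmetric, and genome alignments
fragment single elements across blocks separated by small holes). Loci carry
their member ids, best member pscore and minimum member FDR, and receive
ids `DC0000001, ...` in (chromosome, start) order, so the id set is a pure
function of the selected motif set.

## Unified annotation and enrichment

Gene models plus annotated ncRNA features are flattened so each nucleotide
has exactly one label, with priority coding exon > ncRNA exon > both-UTR
exon > single-UTR exon > intron > intergenic. UTR type comes from position
relative to the gene's merged CDS span in transcript orientation; positions
where 5'- and 3'-UTR exons of any genes overlap become "both-UTR". The
partition is computed on per-chromosome label arrays, which is exact and
fast at simulated genome sizes (a few hundred kb per chromosome).

Each locus splits one unit of weight equally over the distinct unified
elements it overlaps by >=1 bp, so category counts sum exactly to the locus
count; rounding (half-up) happens only at report time. Fold enrichment is
the overlap rate divided by the target's share of the background, where the
background is the total alignment-block length and a category's target size
is the length of its elements touching any block. Significance uses a normal
approximation to the binomial null with mean `n·f` and standard deviation
`sqrt(n·f·(1−f))`; the source description fixes only the mean, and binomial
variance is the natural completion. When a category's target share reaches
or exceeds 1 (possible on small synthetic genomes whose elements are much
larger than blocks), the p-value is undefined and reported as NaN.

ncRNA recovery statistics first filter features to those assessable by the
screen: base-pair content >= 30%, at least half the feature inside input
alignment blocks, and repeat coverage strictly below half. A feature counts
as recovered when a locus covers at least half of the locus *or* of the
feature. Screen-vs-screen comparison counts, per ordered pair, predictions
of screen A overlapping any prediction of screen B by >=1 bp; the expected
overlap of independent surveys is the product of their sensitivities.

## Expression

A feature is *expressed* in an experiment when the experiment's merged
transcript regions (merged with gap 0, hence "merged transcript region")
cover at least half the feature; a strict 100%-coverage variant exists for
case studies. The CRS-vs-expression association test tiles the genome into
100-bp windows, samples (without replacement) as many windows as there are
loci, builds the 2×2 table expressed × CRS-overlapping, and reports the
worst one-sided Fisher p over 10 sub-seeded replicates, for "expressed in at
least k" with k = 1..4; a variant excludes windows and loci touching coding
or UTR exons. The Fisher implementation is the hypergeometric tail and is
verified against an exact integer-arithmetic enumeration oracle for every
2×2 table with n <= 50, and against an independent library implementation on
random tables.

## Co-expression and synteny

For each intergenic locus expressed in >= 3 experiments, the closest gene
element (UTR exon or ncRNA exon, distance unrestricted) defines the pair;
`E_co = E_cg/E_c − E_g¬c/E_¬c` with inclusive classification thresholds
(positive >= 0.5, negative <= −0.5). When the CRS is expressed everywhere
(`E_¬c = 0`), the second ratio is defined as 0 — the gene is never observed
without the CRS, which is what that ratio measures. Synteny evaluates, per
species with an ortholog and a mapped CRS: (a) the ortholog is (one of) the
closest gene(s); (b) it lies on the same side of the CRS as in the focal
species; (c) same side within 20,000 nt. Each criterion passes overall when
it holds in at least ceil(2/3 × available species); species without data
drop out of the denominator.

## Stage specificity and differential expression

Biotype instances (unified exon/intron segments plus annotated ncRNA
features) enter the analysis when expressed in >= 3 experiments and at least
half-contained in input alignment blocks. For biotype B and experiment l,
the stratum ratio is the count expressed in l over the summed counts
expressed in the other experiments ("share" reading; the alternative "number
of instances expressed in >= 1 other experiment" is available via
`denominator="any"` — the share reading makes ratios comparable across
experiments, which the test requires). `R_d` is the CRS-stratum ratio minus
the CRS-free one. Significance follows the described protocol: a one-sided
one-sample test of the non-CRS ratio sample against the observed `R_CRS`
(Student's t for coding-exon and 5'-UTR biotypes, Wilcoxon signed-rank
otherwise; a constant sample under t falls back to a sign test), with the
alternative chosen from the sign of `R_d` and Bonferroni correction over the
tests actually performed. Non-CRS instances for the intergenic biotype come
from 100-bp windows sampled to match the per-(GC, identity)-bin counts of
the CRS predictions.

`E_diff(i,j) = D_H(CRS) · |D_H(CRS) − D_H(¬CRS)|` uses length-normalized
Hamming distances between the boolean expression columns of experiments i
and j within each stratum; matrices are symmetric with zero diagonal and
values in [0, 1]. Introns differentially expressed between a pair of
experiments are further classified as independently expressed at two tiers:
flanking exons unexpressed in the same experiment, and no exon of the host
gene expressed (the predicates differ, so neither tier contains the other by
construction).

**Known limitation.** The significance protocol treats the observed
`R_CRS` as a fixed constant, but it is itself an estimate whose sampling
noise is of the same order as the spread of the non-CRS reference sample
whenever the two strata have comparable instance counts. A location test
then interprets that noise as a real shift, making the procedure
anti-conservative under a random-label null; simulations in the acceptance
suite quantify this (the null-calibration check fails by a wide margin for
every location-test variant, while the only calibrated alternative — a rank
placement of `R_CRS` among the non-CRS ratios — has a minimum p of
1/(n_experiments+1) and can never reach Bonferroni significance).
Significant cells should therefore be read as a ranking of candidate
(biotype, stage) pairs, not as calibrated error control.

## Synthetic data

The generator emulates the statistical structure of the real inputs, not
their content: genes with exon/intron/UTR architecture packed along a few
hundred-kb chromosomes (default 3 × 200 kb, 48 genes, 15% non-coding);
annotated ncRNA features of 13 classes, ~5% of UTR-exon nucleotides
overlapped by ncRNA features; repeats covering 5%; alignment blocks covering
half the genome with GC drawn from a scaled Beta concentrated in 0.30–0.60
and identity in 0.40–0.80, species counts centred near 20 of 27, and a small
(5%) fraction of blocks deliberately violating the input filters. False
motifs arise from one Poisson process run with independent random streams on
the native and shuffled screens (pscore = 50 + Exp(12)); true motifs (native
only, pscore = 80.01 + Exp(40), preferentially in blocks overlapping ncRNA
features) are added at an intensity chosen so the FDR at the selection
cutoff equals the planted value (default 0.10). Expression assigns each
feature a pattern — ubiquitous (1/6 of features), stage-specific within one
of the groups embryo 30 / larva 12 / prepupa 6 / adult 12 / cell-line 20
(80 experiments total), or background — and realizes planted co-expressed
pairs exactly (+1, −1, or 0 at zero noise). Noise is *detection dropout*:
an expressed cell is missed with probability `noise`, and unexpressed cells
never turn on — the dominant failure mode of tiling arrays, which under-call
structured and low-GC transcripts rather than inventing signal; symmetric
flip noise would systematically bias `E_co` toward 0 by ~4× the flip rate.
Orthology copies each CRS–gene pair into each of 11 species on its own
scaffold, with configurable insertion, side-flip, distance-inflation and
missing-ortholog events plus a far decoy gene so the closest-gene question
is non-trivial.

Not emulated: nucleotide sequences and secondary structures, real chromosome
sizes, the joint distribution of pscore with GC/identity (only its
marginals' qualitative behaviour), probe-level array artefacts, and
alignment construction itself. Passing tests therefore demonstrate that the
*pipeline arithmetic and statistics* behave as specified on data with known
truth, not that the upstream motif finder's predictions are correct.

## Problem sizes and reproducibility

All randomness derives from one integer seed through named
`numpy.random.SeedSequence` children; every generator and sampling stage is
byte-reproducible for a fixed seed, and the test suite verifies this on
serialized artifacts. Test and acceptance simulations use reduced sizes
chosen to exercise every code path with comfortable statistical margins: two
or three chromosomes of 100–250 kb, ~1,600 alignment blocks, ~2,500–4,400
motif predictions, 16–80 experiments; the planted-FDR recovery check uses a
single bin with >= 500 native predictions per seed over 50 seeds.
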
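# Methods

`crossvar` re-implements, as a reusable and fully testable pipeline, the
integration-and-evaluation layer of a single-genome resequencing study:
several SNP/indel callers, two genotyping arrays and three CNV platforms
are run on the same individual, and the interesting science lies in how
the call sets are reconciled, how error rates are estimated without a
truth set, and how the different variant classes are summarized.  The
package does not align reads or run the underlying calling engines; it
consumes their outputs (VCF, genotype tables, interval sets, window read
counts) and performs everything downstream.

## Coordinate and identity conventions

All internal coordinates are 0-based half-open; VCF (1-based) and the
1-based-inclusive TSV dialects are converted at the I/O boundary.  A SNP
site is identified by `(chrom, pos)`; allele and zygosity agreement are
evaluated separately by the concordance operations, so a "shared site"
in a Venn partition does not imply genotype agreement.  Indels are
left-normalized (common-base trimming, then leftward rotation of the
varied unit through the reference context) before any set intersection,
because callers that emit the same event at different offsets would
otherwise never intersect.  Without reference context the normalizer can
only trim; callers being intersected should therefore be read with the
same reference.

## Multi-caller consensus and concordance

The Venn partition assigns every site in the union of call sets to the
exact subset of callers reporting it, with separate heterozygous and
homozygous stratifications that use each caller's own zygosity at the
site.  Chip-vs-sequencing comparison classifies each array marker into
one of six categories (consistent, het under-called as hom, hom
over-called as het, reported as indel, allele-inconsistent, not
detected).  Two conventions matter:

* Percentage denominators exclude `not_detected`: the detection rate
  (detected / all chip SNPs) is reported separately, which is how the
  published per-pipeline consistency percentages are constructed.
* A zygosity flip is only labelled `het_to_hom`/`hom_to_het` when the
  two calls share at least one allele; fully allele-disjoint pairs are
  `inconsistent`.  The borderline case (e.g. chip A/G vs sequenced C/C)
  is vanishingly rare in practice and is the package's own choice.

Allele comparison is strand-naive; chips reported on the opposite strand
must be flipped upstream.

For a male sample, heterozygous calls on the sex chromosomes (haploid X)
are excluded before all summaries — they can only arise from error or
the pseudoautosomal region.

The mutation-rate estimator converts a count of new heterozygotes
observed in an identical-by-descent region into a per-bp per-generation
rate: `mu = n_new_het / (det_rate * ploidy * generations * length)`.
The heterozygote detection rate is an input, not something the package
derives; it depends on the array and sequencing depth of the study.

## ROH / IBD analysis

ROH detection slides a 1 Mb window in 200 kb steps (both configurable)
and a window qualifies when it contains at least `min_snps_per_window`
(default 20) SNPs and `n_het <= 0.1 * n_hom`.  The multiplicative form
keeps fully homozygous windows well-defined (a het/hom ratio would be
0/0-prone); sparse windows never qualify.  Chromosome-end partial
windows are evaluated only if at least half a window remains — both
choices are the package's own, since thin windows otherwise produce edge
artifacts.  Qualifying windows that overlap are merged into maximal
intervals, so every reported ROH is at least one window long.

Inside a trusted IBD region every true genotype is homozygous, so the
fraction of calls there that are heterozygous estimates the caller's
false-positive het rate directly (`fpr_het = het / (het + hom)`; a
per-Mb variant is available by flag, since the region's SNP yield
differs between callers).  The homozygous false-positive rate requires
sub-intervals known to be identical to the reference sequence and is
computed only when such intervals are supplied.

The minimum allele percentage (MAP) of a heterozygote is
`min(allele_depths) / sum(allele_depths)`.  False hets created by
misaligned paralogous reads carry systematically low MAP, which
motivates the post-hoc filter: keep het calls with coverage > 2 and
non-reference read fraction > 0.35 ("variant frequency" is interpreted
as the non-reference read fraction, the sense used by NQS-style
callers).

## Indels and region statistics

Candidate intra-read indels are the exact-match intersection
(chrom, pos, ref, alt after normalization) of two callers, then passed
through a post-filter: non-reference support on both strands, base
quality >= 20, depth in [4, 30], and no overlap with assembly N runs.
The mapping-quality downgrade coefficient used during calling cannot be
reapplied post hoc; it is carried as upstream metadata only.  The filter
is idempotent and equals the intersection of its single-criterion
filters (tested).

Coding indels are classified by frame effect (`size % 3 == 0`) with a
2x2 chi-square (1 df, no continuity correction by default) against the
genome-wide size distribution.  Relative protein position is the index
of the first affected codon divided by protein length; for an anchored
indel the first affected base is the one after the anchor, and
minus-strand genes walk the CDS from its 3' genomic end.  First-codon
is a deterministic convention; last-codon or midpoint would shift every
value by less than one codon's width.

`region_density_enrichment` is a single generic operation reused for
every density contrast (CNV duplications vs deletions, CpG islands,
X vs autosomes, imprinted genes): variant density inside vs outside a
merged region set per 10 kb, the fold ratio, and a chi-square of the
observed in/out split against the split expected from base fractions
alone.  The SNP-indel density correlation uses fixed non-overlapping
20 kb windows and plain Pearson correlation.

## Read-depth CNV calling

Windowed read counts of a test and a reference sample on an identical
grid are compared as `log2(((c_t + q)/N_t) / ((c_r + q)/N_r))` with
library sizes `N` summed over the table and pseudocount `q = 0.5` for
zero-safety.  Windows whose combined count falls below
`min_total_reads_per_window` are ignored.  Runs of at least 5
consecutive qualifying windows (|log2| > 1, both configurable) of
consistent sign become one call; a duplication run is never joined to an
adjacent deletion run.  Windows are fixed-size and non-overlapping —
significance-adaptive window sizing used by some read-depth tools is
deliberately not reproduced, since only the log2 and run-length
thresholds are essential to the rule.  The implied copy number of a call
is `2 * 2^mean_log2`.

One consequence worth stating: a copy-number-4 segment in a diploid test
sample against a diploid reference has an expected log2 of exactly 1.0,
i.e. *on* the default cut, so with any window noise roughly half its
windows fail the default threshold.  Tests and the acceptance script
therefore measure recovery of planted CN∈{1,3,4} events with a lower
qualifying cut (0.5 for boundary recovery — halfway between the null and
the planted effect — and 0.2 for copy-number estimation, which is itself
threshold-free); the default cut of 1.0 is kept for production use,
matching the published rule.

Cross-platform comparison declares two CNVs overlapping at >= 1 bp of
shared span; the consensus set merges (interval union) calls supported
by at least two platforms, flagging but not resolving
duplication/deletion label conflicts.  The cross-assembly SV filter
keeps an event only when both breakpoints map, via a user-supplied
4-column position map, onto one and the same chromosome of the second
assembly; unmapped breakpoints are counted separately from discordant
ones.  Gene enrichment is permutation-based: each CNV is re-placed
uniformly at random (chromosome chosen length-weighted among those that
can hold it) `n_perm` times, fold = observed genes hit / null mean, and
the empirical p-value uses the standard +1 correction.

## Pedigree inbreeding

Wright's F of an individual equals the kinship of its parents, computed
by the recursive tabular method with memoization: phi(x,x) = (1 +
phi(sire, dam))/2 and phi(x,y) recursing on the parents of the
individual further from the founders.  Unknown parents are unique
unrelated founders.  This is numerically identical to path counting but
robust to looped pedigrees; it is validated in the tests against a
vectorized gene-dropping Monte-Carlo oracle (10^6 allele drops).

## Synthetic data: what it emulates, and what it does not

The generator builds an abstract diploid genome (default 3 autosomes +
X, ~12 Mb) with planted truth: SNPs at 1 per kb, indels at 7 per 100 kb,
60% of autosomal variants heterozygous, one 1.6 Mb IBD interval (13.3%
of the genome, in the range reported for inbred cattle), three CNVs
(CN 4, 3 and 1), 300 single-CDS gene models, and a male haploid X (true
X genotypes homozygous).  Four caller profiles mirror the structure of
real multi-pipeline data: two "mapping-quality-aware" callers with a
low misalignment false-het rate and two "unique-mapping" callers with
an 8x higher rate, concentrated (5x) inside copy-number duplications,
with false hets drawing their variant-read fraction from Beta(1,6) so
their MAP sits well below the 0.5 of a real heterozygote.  Per-site
depth is negative-binomial (k = 5) around 15x; true hets are
under-called as homozygous (or missed) when binomial read sampling
covers only one allele.  Array genotypes sit on a subset of true SNP
sites and flip with probability 5.52e-4 per chip, the error rate
deducible from a two-chip comparison.  Window read counts are
Gamma-Poisson with k = 100: the residual overdispersion of a
*ratio-based* design in which the two samples share platform, read
length and aligner, so most GC/mappability bias cancels.  (This k was
revised from an initial guess of 10, which implies a variance index of
~11 at 500 reads/window — far beyond what same-platform comparisons
show.)

What the generator does *not* emulate: raw reads and alignment, linkage
disequilibrium, realistic allele-frequency spectra, repeat-driven indel
clustering, array probe chemistry, or batch effects.  Passing recovery
tests therefore demonstrates the correctness of the estimators under
the stated error model, not the end-to-end accuracy of any wet-lab
pipeline.

Three named profiles ship with the package: `clean` (all error rates
zero; every caller's output equals the truth exactly), `paperlike` (the
defaults above) and `adversarial` (doubled misalignment load, Beta(1,8)
MAP, 2e-3 chip errors) used to stress the post-hoc het filter.  All
outputs are deterministic given the seed, byte-for-byte.

## Numerical choices and degenerate inputs

Chi-square tests use 1 df without Yates correction (flag available).
Fractions with empty denominators (no detected sites, no calls in an
IBD region, zero count variance) are flagged rather than silently
returned as 0.  The empty CNV set yields zeroed summaries with an
`empty` flag.  Duplicate sites within one call set are an error, not a
silent de-duplication.  Permutation and simulation functions take
explicit seeds and are bit-reproducible.

## Problem sizes

Test-suite and acceptance-script problem sizes are chosen so each
property is statistically decisive at desk scale: the synthetic genome
is ~12 Mb with ~12,000 SNP sites; permutation enrichment uses 150
intervals against 2,000 genes with 1,000 permutations; the
gene-dropping oracle uses 10^6 drops; the mutation-rate Monte-Carlo
uses 500 replicates of a 90 Mb region.

## Known limitations

* Genome-scale headline counts of the original study (millions of SNPs,
  71 ROH, 520 CNVs) require the original reads and are out of desk-scale
  reach; the package reproduces the study's *arithmetic* exactly and its
  *estimators* on synthetic truth.
* The concordance operations assume bi-allelic markers.
* `cross_assembly_filter` requires exact breakpoint entries in the
  position map; no interpolation or chain-file lifting is performed.
* The ROH detector is single-sample; cross-individual IBD inference is
  out of scope.
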
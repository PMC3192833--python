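# Methods

## Problem setting

Dog breeds are recently founded, closed populations. Artificial selection
at breed creation fixed long haplotypes carrying trait variants, leaving
two signatures that this package detects in multi-breed SNP-array panels:
extended runs of reduced heterozygosity in single breeds, and localized
allele-frequency divergence between breeds. Because strong drift in small
breed populations produces qualitatively similar patterns, every scan is
calibrated against neutral coalescent simulations of the breed history
rather than against an analytic null.

## Scan statistics

All statistics treat each breed as one subpopulation.

**Relative heterozygosity.** For breeds *i, j* and a genomic window,
θ_ij = h_i / (h_i + h_j), where h is the count of SNPs segregating in the
breed within the window. θ_ij + θ_ji = 1 whenever defined; θ is undefined
(and the pair skipped) when h_i + h_j = 0.

**S_i.** Per window, S_i = Σ_{j≠i} (θ_ij − E[θ_ij]) / sd[θ_ij]. E[θ_ij]
is taken from pooled genome-wide polymorphic-site totals H_i/(H_i + H_j);
sd[θ_ij] is the sample standard deviation (ddof = 1) of the pair's
per-window θ values. The alternative E[θ_ij] = mean of window θ values is
available via `e_theta_mode="window_mean"`. The sum runs over the pairs
defined in that window and is not rescaled by pair count; a per-window
defined-pair count is reported. Strongly negative S_i marks loss of
variation in breed *i*.

**d_i.** Per SNP, d_i = Σ_{j≠i} (F_ST^ij − E[F_ST^ij]) / sd[F_ST^ij],
with moments over all SNPs of the chromosome-class group; the window value
is the mean over member SNPs. Large positive d_i marks breed-specific
divergence.

**F_ST.** Weir & Cockerham (1984) θ computed from allele counts (each
called allele a haploid observation), with the n_c unequal-sample-size
correction — chosen because breed sample sizes vary (10–26 in the kind of
panel emulated here). A Hudson-style estimator is available via
`estimator="hudson"` for sensitivity checks. Negative estimates are kept
for moment computation (clipping would bias the d_i standardization) and
clipped to [0, 1] only for reporting and thresholding.

**Chromosome classes.** Autosomes plus the pseudo-autosomal region form
one standardization group; the non-recombining X forms another with its
own moments and its own null lengths, since its effective size differs.
On the non-recombining X, male genotypes are treated as haploid (one
allele counted; heterozygous male calls treated as missing), and a
females-only filter is available for X GWAS.

## From windows to significant regions

Windows are 150 kb advancing by 25 kb, anchored at position 0 of each
chromosome; windows with fewer than 5 array SNPs (counted before any
per-breed restriction) are dropped. Per breed, the ⌈0.01·N⌉ most extreme
windows are flagged (bottom tail for S_i, top for d_i), separately per
chromosome-class group; values tied with the threshold are all included —
a conservative superset, relevant because fully drift-fixed windows tie
exactly. Overlapping or exactly abutting flagged windows merge into
candidate regions.

Each region's marginal p-value is the add-one proportion
(1 + #longer)/(1 + n) of null regions *of the same breed and statistic*
that are strictly longer ("as long as" counts as not longer); the add-one
rule keeps p away from 0 before FDR correction, and the plain proportion
is available via `add_one=False`. Benjamini–Hochberg correction is
applied jointly over all regions of one statistic across breeds;
significance is q ≤ 0.05.

The single-SNP screen (F_ST > 0.55 and pooled MAF > 0.15, chaining
passing SNPs within 500 kb) targets variants under parallel selection in
many breeds and needs no simulation null: the thresholds are calibrated
so that neutral panels produce zero passing SNPs.

## Breed-permutation GWAS

Every dog carries its breed's phenotype, so single-SNP tests are
confounded by breed structure. Genome-wide significance comes from max-T
permutation of the phenotype values *among breeds* (values permuted as a
multiset; every dog of a breed always shares one value). The per-SNP test
is OLS of phenotype on B-allele dosage (statistic = squared t);
dichotomous traits use the same regression on 0/1 values, equivalent to
an allelic trend test up to a monotone transform. P_genome =
(1 + #perm max ≥ observed) / (1 + n_perm); with breed counts small enough
that the factorial space fits in n_perm, the space is enumerated
exhaustively and the exact proportion reported. Permutations that tie the
observed statistic exactly (labelings equivalent at the top SNP) are
counted as ≥, with a 1e-9 relative tolerance so that mathematically exact
ties are not lost to rounding. A consequence worth knowing: the 1/(1+n_perm)
floor is attained only when the causal locus has all-distinct breed
dosage means and the largest breed-structure ceiling in the panel; on
drift-heavy panels, loci whose breed pattern a permuted phenotype can
align with keep the best attainable P_genome slightly above the floor.

## Shared IBS cores and XP-EHH

Within significant S_i regions, a breed's homozygous cores are maximal
SNP runs with no heterozygote and a single allele present; missing calls
are compatible (and reported as a per-core fraction) because array
missingness would otherwise shatter cores arbitrarily. Cores cluster by
single-linkage physical overlap (≥1 bp) across breeds; each multi-breed
cluster is narrowed to the longest run where all breeds are fixed for
identical alleles (ties resolved leftmost). Phase is not needed: complete
fixation makes it irrelevant.

XP-EHH validates regions using phased haplotypes. Pooled EHH between two
SNPs is the probability that two random haplotypes are identical over the
closed interval. For each anchor SNP (pooled MAF ≥ 0.05) the nearest
partner in each direction where pooled EHH first drops into [0.03, 0.05]
is retained; a decay that skips the band yields no pair on that side. Per
breed, EHH is integrated from anchor to partner by the trapezoid rule
over physical distance (a genetic map is not assumed at scan time); the
raw score is ln(iHH_breed / mean iHH of the other breeds), normalized to
mean 0, sd 1 within breed × chromosome, then globally sign-flipped so
that breeds carrying a long fixed haplotype score negative — the
orientation under which sweep-region means are negative while the
genome-wide mean is 0 by construction.

## Synthetic panels

`synthetic_data` generates the panels every stage is tested on. The
demographic program (built on the msprime coalescent engine): an
ancestral wolf population of diploid Ne 22,600 shrinks instantaneously to
a domesticated-dog population of Ne 5,650 at 5,000 generations ago, which
splits simultaneously 100 generations ago into isolated breed populations
of size f·Ne_wolf, sampled at present. Defaults: mutation rate 1e-8
/bp/generation, generation time 3 years, uniform recombination 1e-8
/bp/generation (~1 cM/Mb, the canine genome-average scale; a piecewise
map can be supplied instead of inferring one). The per-breed bottleneck
fraction f spans the 59-point grid 0.001–0.03 in steps of 0.0005; f = 0.01
(breed Ne 226) is the mid-grid working default. Non-recombining-X
segments scale all population sizes by 3/4 × (9134/7752), the X-to-
autosome ratio of dog effective-size estimates.

Array ascertainment is emulated post hoc: sites are rejection-sampled so
the pooled-MAF histogram matches a target spectrum (default: uniform over
ten equal MAF bins on (0, 0.5], the flattened-towards-common shape array
design induces), then thinned to one marker per 13,046 bp on average.
Bottleneck fitting simulates the 59-point grid under a shared curve
protocol (single-breed panel, MAF ≥ 0.05, within-breed haplotype r² in
10-kb bins to 500 kb) and minimizes the summed squared bin differences
against the observed curve, ties toward smaller f.

What the generator does **not** emulate: missing genotypes and phasing
error (panels are complete and perfectly phased), breed relatedness
structure (all breeds split simultaneously and independently), variable
recombination, selection (the null is neutral by design), and the exact
discovery-panel composition behind real array ascertainment. Passing
tests therefore demonstrate correctness of the statistics and calibration
machinery under the stated model, not robustness to real-data artifacts
such as genotyping error or phasing switch errors.

## Numerical and design choices

- Coordinates are 0-based half-open internally; 1-based only in VCF/tped
  I/O. BED output is 0-based.
- PLINK transposed text carries no REF designation, so the tped reader
  orients the minor allele as the counted B allele (ties: later sort
  order); round-trips through tped are exact up to that orientation.
- Standard deviations in standardization use ddof = 1 throughout, making
  the mean-0/sd-1 identities exact for the same ddof.
- Pairs with zero or undefined sd are excluded from S_i/d_i with a
  warning; windows where a pair has h_i + h_j = 0 skip that pair without
  rescaling the sum.
- Monomorphic loci get association statistic 0; all-missing loci are
  excluded. Perfect collinearity reports the analytic maximum (infinity).
- Region length for a single flagged window equals the window length;
  degenerate single-SNP F_ST regions have zero span.
- All randomness flows from a single integer seed through
  numpy's `default_rng`; msprime segment seeds are drawn below 2^31.
  Identical inputs give byte-identical region tables.

## Problem sizes used in the test suite and acceptance script

Simulation-backed checks run at reduced scale, chosen once as a balance
of statistical resolution and desk-scale runtime: the neutral F_ST screen
uses a 30-breed × 10-dog panel over eight (suite) or twenty (script) 5-Mb
autosomal segments at f = 0.01; null calibration and sweep recovery use
5 breeds × 10 dogs over four 2.5-Mb segments, with a null catalogue of
150 (suite) or 120 (script) neutral replicates — sized so the marginal-p
floor sits safely below the BH threshold for the ~10 regions such a scan
yields, the same power consideration that drives the size of any
simulated null; bottleneck recovery fits the full 59-point grid with
single-breed panels of 12 dogs over eight 2-Mb segments. The planted
sweep is a 1-Mb fixed haplotype, large relative to drift-fixed runs under
f = 0.01 but far from the whole segment.

## Known limitations

- The S_i/d_i length null assumes exchangeability between the analysis
  panel and the simulated panels; mis-specified demography (especially
  recombination-rate variation) shifts the null length distribution.
- With tail fraction 0.01, breeds with a large tie class of fully fixed
  windows can have many more than 1% of windows flagged; this is the
  documented tie rule, not a bug.
- d_i regions are rarely FDR-significant against a length null — drift
  produces comparably long divergence blocks — mirroring the behaviour of
  the statistic this design reproduces.
- The XP-EHH score uses a single log-ratio per SNP pair rather than
  allele-stratified (core-allele) EHH; it validates fixation contrast,
  not direction of selection on a specific allele.
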
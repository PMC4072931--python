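# Methods

## Accessibility model

Accessibility of meta-peak *j* in sample *i* is the tag enrichment relative
to genome background, `A[j,i] = (c/L_j)/(R_i/G)`. The implementation
computes it as `(c/R_i) · (G/L_j)` so that scaling a sample's counts (and
hence its total) cancels in a single correctly-rounded division — depth
invariance holds bit-exactly, not just to rounding error.

Quantile normalization maps every column onto the reference distribution
(the row-wise mean of sorted columns). Tied values within a column receive
the mean of the reference values at their tied ranks; a constant column
therefore collapses to the grand mean of the reference. Consequence worth
knowing: with ties present, a normalized column's sorted values are *not*
the reference vector — the "all columns share one distribution" identity is
exact only for tie-free (continuous) input. The transform is idempotent in
both cases.

Within-pair discordance is reported both as `D_abs = |X1 − X2|` and as
`D_norm = |X1 − X2|/(X1 + X2)`. `D_norm` is bounded in [0, 1], zero iff the
siblings are equal, and undefined-as-missing (NaN) when `X1 + X2 = 0`.
Discordant-site calling offers two rules: per (peak, pair) fold change
`(max + c)/(min + c) > 4` with pseudocount `c = 1` on the
quantile-normalized scale (the pseudocount bounds the ratio at
zero-accessibility sites), and a per-peak variance rule flagging peaks
whose within-pair variance (mean of `(X1 − X2)²/2` over pairs) exceeds the
between-pair variance (variance of pair means, ddof = 1).

## Variant calling

The somatic-mutation test is the two-sided Fisher exact test
(minimum-likelihood definition) on the siblings' ref/alt read counts. The
2×2 table is canonicalized (row/column ordering) before evaluation so that
relabeling siblings gives bit-identical p-values. Calls additionally
require ≥ 10 high-quality reads per strand in both siblings ("high
quality" is operationalized as the `hq_fwd`/`hq_rev` per-strand totals in
the allele table, emulating base quality ≥ 20/30 tallies) and the variant
allele on both strands of the carrier with ≥ 2 reads per strand — our
testable proxy for a caller's "high-confidence" notion. The carrier is the
sibling with the larger alternate-allele fraction; ties carry no
information and cannot be called. The base change is typed (strand-collapsed
into six classes anchored on the C/A strand) only when the co-twin is
reference-homozygous (alternate fraction ≤ 0.15); otherwise the call is
kept with direction unclassified.

Polymorphisms require coverage ≥ 1 read in every sample, exclusion of
positions already called somatic in any pair, pooled alternate-read
fraction (read-weighted across all samples) ≥ 1%, and survival of the
strand-artifact filter: a candidate is removed only when *every* carrier
sample has > 90% of its variant reads on one strand — the per-carrier
reading of the filter; a single strand-balanced carrier rescues the site.
The filter's `>` is strict, so exactly 90% on one strand is not an
artifact. Pooled MAF of 0.01 exactly is retained (`≥` threshold).

SNP-accessibility association encodes per-sample dosage 0/1/2 from the
alternate-read fraction (< 0.25, < 0.75, else), fits ordinary least squares
of host-peak accessibility on dosage, and adjusts over all tested SNPs by
step-up FDR at 0.05.

## Dinucleotide spectra

The 16 dinucleotides collapse onto 10 strand-symmetric classes (canonical
label = lexicographically smaller of the 2-mer and its reverse complement).
The four palindromic classes have one member where the others have two, so
their counts are doubled everywhere — in sequence windows and in variant
contexts alike — which cancels in every enrichment ratio. Each variant
contributes the two dinucleotides of its *reference* trinucleotide context
(−1pV and Vp+1); variants at contig edges contribute only the available
side. "Surrounding open chromatin" is defined as the host peaks minus
their TFBS sub-intervals, making foreground and background disjoint.

Observed/expected ratios: base-change O/E compares class frequencies among
TFBS calls to open-chromatin calls; dinucleotide relative enrichment is
`(n_d^TFBS/n_d^bg)/(N^TFBS/N^bg)` (background either the surrounding open
chromatin or the whole genome); substituted-dinucleotide O/E divides the
variants' relative enrichment by the sequence's. Any zero denominator
flags the class as missing (NaN) rather than inventing a ratio. The
CpG-specific mode restricts to calls whose reference context contains the
CpG and types them as CpG>TpG / CpG>ApG / CpG>GpG, strand-collapsed.

ChIP peak filtering takes the summit as the leftmost position of maximal
tag depth and keeps a peak iff ≥ 80% of its tags overlap the summit (a
7/10 peak is discarded, an 8/10 peak kept).

## Variability-QTL mapping

The pair trait is `y = D_norm` — genotypes shared by a pair are associated
with how different the siblings are, not with the level. Because most
within-pair differences are tiny, only the `ceil(0.01·m)` peaks with the
largest between-pair variance of `y` are mapped (ties at the boundary break
by peak order, deterministically). Every (SNP, peak) pair with a gap below
1 Mb (0 if the SNP is inside the peak) is tested by simple OLS of `y` on
dosage across pairs; SNPs are pre-filtered at minor allele frequency ≥ 1%
(folded from the dosage mean) and at non-zero dosage variance; pairs with a
missing trait are dropped listwise per test. q-values are step-up FDR over
all tested cis pairs, significant at q < 0.01. For binary dosage the t and
p reduce exactly to the equal-variance two-sample t-test (verified in
tests). Results are emitted in a canonical sort order, so they are
invariant to the order of input SNPs and peaks. One step-up FDR procedure
is used package-wide (QTLs at 0.01, SNP associations at 0.05).

## Expression and methylation integration

Within-pair differential expression is `|Δlog2|` per gene per pair; missing
values propagate. Genes link to the nearest peak within ±2 kb of the TSS
(one link per gene; equidistant ties to the lower-coordinate peak; the
window is a parameter since "proximal" has no canonical value). The
coupling test pools (gene, pair) observations, bins discordance into
tertiles by rank, and uses the Spearman correlation between tertile index
(1/2/3) and differential expression; the null permutes the
differential-expression values across observations,
`p = (b + 1)/(n_perm + 1)`. Because the statistic depends on the
differential expression only through ranks, the p-value is invariant to any
monotone transform of it. Permutation is vectorized: under permutation only
the cross term of the correlation changes, so each permutation is one dot
product.

Methylation contrast: per TFBS CpG, `Δ = |methylation_lymphocyte −
methylation_other|` for other ∈ {ESC, HPC, neutrophil}; CpGs are classed
mutated / polymorphic / non-substituted by whether a called variant hits
either base of the CpG; groups are compared by two-sided rank-sum (as all
group comparisons in the package). A TFBS-averaged mode first averages Δ
per TFBS, a TFBS counting as substituted when any of its CpGs is.

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the *structure* of a deep-sequenced MZ twin study:

- **Genome** — contigs of uniform random sequence with CpG suppression
  (two passes breaking ~75% of CpGs, leaving a CpG-depleted background as
  in real genomes); open peaks covering ~2% of the genome (lengths
  50–90 bp so a 1 Mb genome yields ~290 peaks); one TFBS nested per peak,
  rewritten from CG-blocks so the measured CpG frequency inside TFBSs
  exceeds the surrounding open chromatin by at least the requested boost
  (default 4×, with a 2.5× construction margin); regulatory-state domains
  (peak ± 100 bp) labeled active/poised promoter, enhancers, etc.; TSSs
  near ~60% of peaks.
- **Counts** — negative binomial (gamma–Poisson) per peak and sample,
  mean `depth` = 300 reads/peak, with a pair-level lognormal random effect
  (σ = 0.3) shared by siblings: twin correlation exceeds unrelated-sample
  correlation by construction. Sibling-level overdispersion is
  near-technical (0.005): the biological covariance lives in the pair
  effect, and the within-pair *difference* channel must not be swamped by
  sibling-independent noise, since that channel is the study's trait.
- **Discordance heterogeneity** — each peak has its own asymmetry scale
  σ_j ~ U(0.01, 0.08); per pair, the sibling means are `μ(1 ± a)` with
  `a ~ N(0, σ_j)`. Loci differ in how labile they are, which is what makes
  tertile contrasts and top-variance selection meaningful.
- **Planted signals** — somatic mutations (default 30) at TFBS positions,
  VAF 0.5 in one sibling, strand-balanced, with an accessibility effect of
  ±60% on the carrier's host-peak mean (decreases drawn at 70%,
  emulating the predominance of accessibility-loss mutations); variability
  QTLs (default 3) shifting `a` by 0.4 per dosage unit at MAF ∈ [0.1, 0.5]
  (0.4 is the trait-level β = 0.2 / sd = 0.05 power condition re-expressed
  after quantile-normalization attenuation and count noise); cohort
  polymorphisms (default 24, half in TFBSs) with pair-shared dosages;
  expression coupled to promoter accessibility (slope 0.1 log2 units per
  accessibility unit, noise sd 0.3); methylation baselines Beta(0.5, 0.5)
  (bimodal, as real methylomes are), with differentiation-regulated CpGs
  shifting the lymphocyte level by δ toward the side with head-room.
- **Allele tables** — per tracked position and sample: Poisson depth
  (default 60, emulating deep targeted sequencing), binomial alternate
  reads at the sample's VAF or the error rate (0.002), strands split
  Binomial(n, 1/2), high-quality totals thinned at 0.92 per strand.

Not emulated: read-level artifacts (mappability, GC bias, PCR duplicates),
linkage disequilibrium, sex chromosomes, cell-population heterogeneity, and
any coupling between mutation spectra and mutational processes (planted
alternate alleles are uniform over non-reference bases). Passing tests
therefore demonstrate the *pipeline's* correctness and calibration under a
faithful statistical structure — not robustness to alignment-level
artifacts in real data.

All randomness flows from one explicit `numpy.random.Generator` seed; the
one-call `simulate_cohort` derives stage sub-seeds from the master seed.
Identical seeds give byte-identical output files.

## Numerical choices

- Fisher tables are canonicalized before evaluation (two-sided p is
  invariant under row/column swaps) for exact sibling-relabeling symmetry.
- Normalization order: `(c/R) · (G/L)` for exact depth invariance (above).
- Top-variance ties: stable sort, peak order preserved. Summit ties:
  leftmost. Gene-peak distance ties: lower-coordinate peak.
- Degenerate inputs: all-zero Fisher table → p = 1; zero-total sample →
  error; `X1 + X2 = 0` → missing discordance; constant dosage → test
  skipped with a warning; constant discordance → tertile test refuses.
- Intervals are 0-based half-open throughout; book-ended intervals merge.
  A point at coordinate `end` is outside the interval (gap 1).

## Default problem sizes

The default study is 36 twin pairs on a 1 Mb single-contig genome
(~290 peaks, ~2% coverage), 30 planted mutations, 3 planted QTLs, 10,000
permutations for the coupling test. A full run takes a few seconds on one
CPU; calibration studies in the test suite use 20 replicate cohorts of
10,000 positions (caller null), 20 × 10,000 cis tests (QTL null), and 200
datasets (permutation-p uniformity). These sizes give the calibration
estimates stated in the tests while keeping any single study small enough
to iterate on.

## Known limitations

- The per-carrier strand filter and the ±2 kb promoter window are
  parameterized choices where the underlying procedures have no canonical
  value; both are config-exposed.
- The mutation caller's sensitivity depends strongly on depth through the
  ≥ 10 hq-reads-per-strand filter: at ~30 reads total per sibling the
  filter itself caps sensitivity well below 1 (about 15 reads/strand × 0.92
  high-quality leaves frequent sub-10 strands); near-complete recovery
  needs ≥ ~50–60 reads per sibling, which is what targeted deep sequencing
  of open chromatin provides.
- Polymorphic sites can occasionally yield a spurious somatic call
  (het-vs-het read-count fluctuation passing p < 1e-3 under many tests);
  the pipeline reports false-call counts against ground truth.
- With only 3 top-1% selection slots on ~290 peaks, planted-QTL recovery
  requires the planted variance to dominate mutation-driven and background
  discordance variance; the defaults are calibrated so that it does.
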
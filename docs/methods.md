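# Methods

## The problem

In an F1 hybrid cell line the two haplotypes differ at millions of SNPs, so
RNA-seq reads overlapping a SNP can be assigned to their parental allele.
Comparing knockout (KO) to wild-type (WT) cells three ways — on total
counts, on each allele's counts, and on the allele x condition interaction —
separates genes that lose expression from both alleles from genes that
silence exactly one allele while the other is untouched.  The package
implements that analysis end to end: simulation of allele-resolved counts
with known truth, the three-mode negative-binomial GLM, the category
decision tree (bi-to-mono, mono-to-none, bi-to-bi-down), cross-clone and
parent-of-origin classification, X-inactivation escapee detection, allelic
methylation integration, aggregate contact analysis and allelic copy-number
QC.

## Count model and differential expression

Counts are modelled as negative binomial with variance `mu + alpha * mu^2`.
The fitting stack is deliberately simple and fully specified here rather
than delegated to a heavyweight DE framework, because the downstream
decision tree needs its exact behaviour to be testable:

* **Size factors** — median-of-ratios: for each column, the median over
  reference genes (rows with strictly positive geometric mean) of
  count / gene geometric mean, rescaled so the factors have geometric
  mean 1.  Allelic and interaction tests estimate factors on the
  sample x allele column layout by default, which absorbs differences in
  SNP-assignment rate between alleles; a `totals` mode reuses the
  per-sample factors instead (the choice is exposed because either
  convention is defensible).
* **Dispersion** — gene-wise method of moments on normalized counts:
  `alpha = max(1e-8, (s^2 - m) / m^2)` with `m` the grand mean and `s^2`
  the pooled within-group variance (group means centred out).  No
  empirical-Bayes shrinkage: at six replicates per condition the estimator
  is serviceable, and keeping it closed-form makes the Poisson-limit and
  calibration tests exact.
* **GLM** — IRLS maximization of the NB log-likelihood with log link and
  `log(size factor)` offsets; a ridge penalty of 1e-6 on non-intercept
  coefficients keeps all-zero groups finite.  Convergence tolerance 1e-10
  on the max coefficient step, 200 iterations; non-convergence is flagged
  and the gene's p set to 1.
* **Wald tests** — `z = beta / SE` from the observed information.
  p-values use a Student-t reference with residual degrees of freedom
  (observations minus coefficients).  With 6+6 replicates and a plug-in
  gene-wise dispersion the normal reference is measurably liberal (about
  0.06 empirical at nominal 0.05 on null simulations); the t reference is
  the standard small-sample correction and restores near-nominal type-I
  control without shrinkage machinery.
* **Multiple testing** — Benjamini-Hochberg step-up with monotonicity
  enforcement, computed per analysis mode over tested genes; NaN p
  propagates NaN q.

The allele-level design is `~ allele + condition + allele:condition`.
Because this design is saturated in the four group means, the maximum
likelihood estimates of the per-allele condition effects from the joint fit
coincide with separate per-allele fits (property-tested).  All three
allelic results are therefore read off one fit per gene as contrasts:
allele 1 = condition effect, allele 2 = condition + interaction,
allele-specific = interaction.  This makes the identity
`log2FC_AS = log2FC_a2 - log2FC_a1` hold to machine precision, and it is
kept exact under truncation by capping the two per-allele effects at
|log2FC| = 12 first and deriving the interaction as their difference.  The
cap (with the ridge) is what represents "complete silencing" without
infinities; 12 log2 units is far beyond any observable effect at realistic
depth.

Genes are pre-filtered to mean normalized total count >= 1 across samples;
filtered genes carry NaN statistics and are excluded from BH.

## Categorization decision tree

Gates (all thresholds are `Thresholds` fields):

1. **Monoallelic candidates**: allele-specific p < 0.05 and |log2FC| > 0.5,
   supported by standard q < 0.01 or either allele's p < 0.01.
2. **Mono-to-none before bi-to-mono** (the WT ratio bounds make them
   disjoint): mono^A2-to-none requires WT log2(a2/a1) > 1 and allele-2
   log2FC < 0; mono^A1-to-none mirrors it below -1.
3. **bi-to-mono^A2**: WT log2(a2/a1) > -1, WT a1 fraction > 0.1, allele-1
   log2FC < 0.  **bi-to-mono^A1**: WT log2(a2/a1) < 1, WT a2 fraction >
   0.1, allele-2 log2FC < 0.  The A1 gate has no lower ratio bound; the
   asymmetry is kept verbatim from the source procedure rather than
   "fixed", and in practice the mono gates have already removed the genes
   it would misplace.  If both bi gates pass, the gene is assigned to the
   side whose allele fell harder (more negative allelic log2FC).
4. **bi-to-bi-down**: any non-allelic downregulation (standard q < 0.01
   with negative log2FC, or either allele p < 0.01 with negative log2FC)
   not already captured above.
5. A **strict** flag marks bi-to-mono genes whose silenced allele shows
   log2FC < -2 (near-complete loss); downstream cross-clone analyses use
   this stricter set.

The WT allelic ratio uses a pseudocount of 1 inside the log only; the
allelic fraction uses raw means and is NaN when both means are zero, in
which case the gene is unclassified with a reason code.  Upregulated genes
are never categorized.  Controls are a seeded uniform sample (default 300)
from genes with standard q > 0.5, |standard log2FC| < 0.1 and
allele-specific p > 0.5 — a conservative "no change" pool, since the source
procedure specifies only "no gene expression changes".

## Cross-clone, parent of origin, escapees

The deterministic consistency rule takes genes called bi-to-mono in two
clones, defines the lost allele as the one with allelic p < 0.01 and
log2FC < -2, and labels the pair `same_allele` or `reversed_allele` by
strain identity.  Parental origin follows from the cross (allele 2 is CAST
by convention, so a lost a2 is maternal exactly when CAST is the mother).
For reciprocal crosses, a reversed-allele change with consistent parental
origin is imprinting-like; between clones of the same cross a reversed
change is random-monoallelic-like.  A k-means clustering of the
clone x allele log2FC matrix (k = 14 for the four-clone panel, Lloyd,
seeded restarts) is provided as the exploratory counterpart.

Escapees are called per female clone from the WT inactive-X allele:
normalized Xi counts > 10 and Xi fraction strictly between 0.1 and 0.9
(both statistics WT-only; the count gate's condition is not spelled out in
the source and WT-only is used for both, consistently with the fraction).
An escapee is knockout-regulated when its Xi-allele log2FC < -2.

Set enrichment (e.g. haploinsufficiency of bi-to-mono genes) uses the
two-sided Fisher exact test — the sum of hypergeometric probabilities no
larger than the observed table's — with a 0.5 Haldane correction applied to
the sample odds ratio only when a cell is zero.

## Methylation and contacts

Methylation frequency is methylated / (methylated + unmethylated) calls per
CpG.  Differential methylation pools replicate counts per CpG and applies a
two-sided Fisher exact test WT vs KO (or allele 2 vs allele 1), BH-adjusted,
with `is_dml` at q < 1e-5 and a minimum pooled coverage of 10 per side.
This replaces a smoothed-dispersion DML caller with an exact,
oracle-testable test at the same decision threshold; it ignores local
smoothing and biological replicate variance beyond binomial, which is the
price of exactness.  Promoter region classes merge consecutive same-band
CpGs (coverage > 10; bands: fully > 0.95, low 0.10-0.50, un < 0.10; merge
gap 200 bp), keep regions spanning 350-2000 bp, and intersect them with
TSS +/- 100 bp windows; frequencies between 0.50 and 0.95 belong to no band
by construction.  The TF-binding/methylation join selects peaks with
allelic |log2FC| > 1 and CpGs with allelic |delta f| > 0.25 and scores a
pair concordant when the two biases point to opposite alleles.

Aggregate contact analysis takes bin pairs where both bins contain a peak,
extracts (2w+1)^2 submatrices (w = 5 bins) centred on each pair, and
compares their mean centre to an equal number of peak-free pairs sampled
per foreground distance (nearest-distance fallback with a warning);
enrichment is the ratio of centre means and is invariant to global matrix
scaling.

## Copy-number QC and single cells

The coverage rule CPM-normalizes each allele's per-chromosome counts and
flags chromosomes with a2/a1 ratio strictly below 0.8 or above 1.2
(boundaries exclusive, following the quoted inequalities); a zero a1 CPM
yields an infinite-ratio sentinel.  A uniform genome-wide allelic imbalance
is invisible to this rule by construction (CPM renormalizes it away).  The
RNA-based rule counts allele-biased genes per chromosome (p < 0.01 and
|log2FC| > 0.5 — the "allele-biased" operationalization is this package's
choice) and flags |log2((n_a2 + 1)/(n_a1 + 1))| > 1.  Single-cell allele
frequency is detection-based: cells detecting allele 1 over cells detecting
either allele (a union, not a sum), undefined below 10 expressing cells.

## The synthetic experiment

The generator emulates the hybrid NPC experiment's statistical structure,
not its sequences: four clonal lines (reciprocal male crosses; two female
lines with reciprocal X inactivation), six replicates per condition, NB
counts with dispersion 0.05 around a WT total mean of 500, an allelic
assignment rate of 0.25 (the fraction of reads overlapping informative
SNPs; a free parameter of the simulation, chosen as a typical hybrid
value — the study does not report its own), and planted categories:
silencing log2FC -3 on the affected allele of bi-to-mono and mono-to-none
genes (beyond the -2 "complete loss" threshold), -0.7 per allele for
bi-to-bi-down.  Totals are allelic counts plus independently drawn
unassigned counts, so the allelic sum never exceeds the total.  Monoallelic
genes keep 3% of their allelic signal on the minor allele — real
monoallelic genes retain assignable background, and an exactly zero allele
would make the interaction contrast inestimable.  Escapees express the Xi
allele at a fraction drawn uniformly from (0.15, 0.45); the regulated
subset additionally silences Xi in the KO.  Imprinted-like and
random-monoallelic-like genes resolve their silenced allele per clone from
the cross (or a per-gene coin flip).

Two realism choices matter for interpretation.  First, the panel includes
8,000 unchanged background genes by default: the motivating experiment
found ~2,500 differential genes among >20,000 quantified, and
median-of-ratios normalization relies on that unchanged majority — with the
planted categories alone, the global knockout shift leaks into every fold
change (a residual ~0.1 log2 shift remains even at the default background,
as it would in real data with this much downregulation).  Second,
methylation is simulated as two bisulfite libraries per condition at
coverage 50 and pooled by the DML caller, matching the replicated design it
models.

What passing tests show — and do not.  The generator draws independent NB
counts per gene: no gene-gene correlation, no GC/length bias, no outlier
samples, no mapping bias between alleles, and its per-gene effects are
exactly the planted ones.  Recovery and calibration results therefore
validate the decision logic and its thresholds, not robustness to the
artifacts an aligner-level pipeline must handle (those are explicitly
upstream of this package: alignment, N-masking, SNP splitting, peak
calling).

## Numerical and interface choices

All intervals are 0-based half-open; the TSS of a minus-strand interval is
`end - 1`.  All randomness flows through explicitly seeded NumPy
generators; the count simulator gives every gene a counter-based substream
(seed, gene index, clone index), so extending the panel never perturbs
existing genes, and the pipeline manifest (seeds, thresholds, output
checksums) reproduces a run byte-identically.  Ties in k-means are handled
by seeded restarts with best inertia.  Long-format TSV is the canonical
counts dialect; a wide three-matrix dialect plus sample sheet is also read.

## Known limitations

* Dispersion is not moderated; very low counts (mean < ~5) give unstable
  gene-wise estimates, partially mitigated by the mean >= 1 filter and the
  t reference.
* The DML test treats pooled replicates as one binomial draw and will be
  anticonservative if replicate-level biological variance is large.
* The bi-to-mono^A1 gate's missing lower ratio bound is reproduced as
  specified, not corrected.
* The consistency classifier requires a gene to pass the strict lost-allele
  gate in both clones; borderline genes (silencing near -2) drop out rather
  than being guessed.
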
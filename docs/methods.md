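# Methods

This note documents the models, parameter choices and numerical
decisions behind each pipeline stage, what the synthetic generators do
and do not emulate, and the known limitations.

## Differential-expression catalog

**Model.** Counts for gene *i*, sample *j* are treated as negative
binomial with Var = μ + φμ². Samples are normalized by median-of-ratios
size factors computed over genes with all-positive counts. The per-gene
dispersion is estimated by method of moments within each condition,
(s² − m)/m², averaged across the two conditions and floored at 1e-8.

**Moderation.** With three replicates per condition the raw
method-of-moments dispersion has only ~4 residual degrees of freedom and
is far too noisy to support a calibrated Wald test: referred to a normal
the test is anticonservative (≈11% of null genes at p < 0.05 in our
simulations), referred to a t(4) it loses most of its power (≈25%
detection of 4-fold planted changes at BH 0.05). We therefore shrink the
per-gene estimate toward the across-genes median dispersion with
`prior_df = 20` pseudo-observations — the empirical-Bayes structure that
limma and DESeq2 use — and refer the Wald statistic on the log2 ratio of
normalized condition means (pseudo-count 0.5) to a t distribution with
residual + prior df. Under the null simulation (10,000 genes, 3+3) this
gives a 4.5% raw-p fraction at the 5% level and ≈99% power for |log2FC|
= 2 planted genes, with BH FDR controlled. The prior df trades per-gene
adaptivity against stability; 20 is deliberately conservative relative
to limma's typical fitted values on real data.

**Consensus.** The multi-algorithm integration is a generic operator: a
gene enters the consensus iff it is significant (BH-adjusted p < α) in
at least `min_methods` tables (default: all provided) with the same
fold-change sign everywhere it is significant. Intersection is the
default because the catalog is meant as a single high-confidence list.

**Filters.** lncRNA biotypes are antisense, lincRNA,
processed_transcript, sense_intronic and sense_overlapping;
protein-coding genes, pseudogenes and unknown biotypes are dropped
(unknowns conservatively, since they cannot be confirmed non-coding).
The length rule keeps genes whose longest transcript (sum of exon
lengths) is ≥ 200 bp — the defining lncRNA threshold. The blacklist
handles annotations reported as discordant between databases.

**Time-point combination.** For multi-time-point designs a gene is
called responsive when any time point has p < 0.05; fold changes are
averaged and p-values combined by Fisher's method (X = −2Σln pᵢ ~
χ²(2k)); zero p-values are clamped at 1e-300.

## TSS-to-binding-site distances

Distance is |TSS − summit| on the same chromosome, unsigned and
strand-agnostic, with 1,000 kb as the maximum threshold; genes with no
summit within the cap are censored and, by default, rank above every
finite distance in the rank-sum test (dropping them is available). The
summit defaults to the interval midpoint, floored on ties, when the
peak file carries no explicit summit column.

The null is built from 1,000 random gene sets drawn without replacement
within biotype strata from the annotated lncRNA pool, excluding the
observed genes, with the observed biotype composition matched exactly.
The one-sided Wilcoxon rank-sum test compares observed distances with
the pooled null; the empirical p compares set medians with the +1
correction, counting ties at half weight so that a fully exchangeable
configuration yields p ≈ 0.5. Down- and up-regulated genes are tested
separately. One caveat the test suite quantifies: because observed
genes are excluded from the resampling pool, a pool only a few times
larger than the observed set couples the observed and null medians and
distorts the null p distribution; with the observed set at ≤ a few
percent of the pool the p-values are uniform.

## ChIP signal matrices

Each tag is extended to 200 bp from its 5′ end in its strand direction;
a tag increments every 50 bp bin it overlaps within ±1 kb of the
anchor, and counts are scaled to CPM with the track's total tag count.
Matrix rows are oriented 5′→3′ of the anchor's strand. The
promoter/enhancer call uses (mean CPM_A + 1)/(mean CPM_B + 1) with
promoter-like requiring a ratio strictly above 1; the unit pseudo-count
makes the zero-signal case well-defined (ratio 1, enhancer-like).

## Chi-squared merit and signature

Genes are discretized into four equal-frequency bins computed on the
training fold only; the cut-points are the upper-edge values of the
provisional rank bins and final bins are assigned through them, so tied
values always share a bin (a constant gene collapses to one bin and has
merit exactly 0); held-out samples map through the training cut-points.
On each of ten stratified folds the χ² of the bin × subtype contingency
is computed over non-empty margins, and the merit is the fold mean. The
signature keeps genes with merit strictly above 15, ordered by merit
(ties by gene id). Note that χ² grows with table size: with 4 bins and
4 classes the null expectation is ≈ 9, so the merit>15 rule's false
admission rate depends on how many candidate genes are screened; the
pipeline therefore evaluates merit over the catalog genes, not the
whole lncRNA universe.

Classification uses a single-hidden-layer MLP (default units =
⌈(features + classes)/2⌉, lbfgs, seeded), with abundances
log10(x + 0.01)-transformed and z-scored on the training fold. The
log-transform matters: on raw FPKM-like scales the planted shifts
become extreme outliers and the network's accuracy degrades. Clustering
is Ward on log10(x + 0.01) over Euclidean sample distances — scipy's
`ward`, which is the Ward.D2 variant (squared distances inside the
Lance–Williams update, heights reported on the distance scale) — with
purity = Σ_c max_class |c ∩ class| / N. PCA is SVD on per-gene-centered
values with the largest-magnitude loading of each component made
positive.

## Co-expression screen

Pearson r of every gene against the focal gene, computed on
log10(x + 0.01) by default (raw scale available); p from the t
transform t = r√((n−2)/(1−r²)) with n−2 df, two-sided. Hits require
|r| ≥ 0.7 and p < 0.001 jointly and are sorted by |r|. Constant genes
are skipped (detected by exact zero range, which is robust to
floating-point residue after the log transform); a constant focal gene
is an error.

## qRT-PCR harmonization

ΔCt defaults to the reference/target cycle ratio, with 2^(reference −
target) as the conventional alternative; the convention is recorded in
the output. Both are monotone in transcript abundance.

Harmonization pairs the sorted log values of run 2 with type-7
quantiles of run 1 at run-2's plotting positions and fits
log-q2 = a + b·log-q1 by geometric-mean (standardized major axis)
regression — both axes are order statistics carrying sampling noise of
the same relative size, and ordinary least squares attenuates the slope
noticeably at n ≈ 20 (measured ≈ 1.14 for a true scale of 1.2, vs
≈ 1.21 for the sd-ratio slope). A 200-iteration bootstrap refits the
paired quantiles and keeps the fit with the smallest out-of-bag MSE
(coefficient averaging available). Run 2 is adjusted by inverting the
fitted line, exp((log x − a)/b), which preserves run-2 rank order
exactly and maps identical inputs to an exact identity model.

The per-seed spread of the fitted scale is substantial (sd ≈ 0.27 at
n = (22, 20)) — an intrinsic limit of estimating a scale from 20
points — so parameter-recovery statements are about averages over many
simulated run pairs, and single-run estimates should be read with that
uncertainty in mind. For the same reason the procedure is only a
near-identity *on average* when no batch effect exists: per-sample
adjusted values deviate from the originals by roughly the quantile
sampling error (≈ 10% relative at these run sizes).

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (config, seed) and return their
planted truth. Default study conditions: 2,000 genes on 5 chromosomes
(Gencode-like biotype mixture, ~41% lncRNA); knockdown experiment with
3 replicates per condition, NB dispersion 0.05, 20M expected
reads/sample, 10% of lncRNAs planted at |log2FC| = 2 with 65% down
(echoing the down/up imbalance of ERα depletion); binding sites 200 bp
wide with exponential TSS offsets of mean 10 kb for regulated genes
plus 1,000 uniform background sites; a 55-sample panel split
luminal/basal/claudin-low/normal-like 14/14/14/13 with a 29-gene
signature shifted 3 within-group sd in luminal samples (a quarter
negatively) and per-subtype centroid offsets (1 sd) so non-luminal
subtypes are mutually distinguishable; promoter tag profiles at 4:1
H3K4me3:H3K4me1 (enhancer 1:4), Gaussian sd 300 bp, both tracks padded
with uniform background tags to equal library sizes (CPM comparisons
between two marks presuppose comparable sequencing depth); qRT-PCR runs
of 22 and 20 samples, log-ΔCt sd 0.35, ER+ − ER− effect 0.7 on the log
scale, run-2 batch transform (0.5, 1.2).

Not emulated: read-level sequencing artifacts (GC bias, mapping
ambiguity), gene–gene expression correlation outside the planted
structures, overdispersion heterogeneity across genes, annotation
errors, or peak-width variation. Passing recovery tests therefore shows
the *procedures* are correct and calibrated under their stated
assumptions, not that real data meet those assumptions.

## Problem sizes in the test suite

The recovery and calibration tests run at the scales above: 100-seed
recovery runs for distance enrichment, merit, co-expression and
harmonization; 200-run null calibrations; a 3,000-gene universe for the
distance-null uniformity check (see the pool-coupling caveat);
10,000-gene DE calibration; 1,000 random instances for the interval
oracles. These sizes keep each stage's statistical claims at the
reliability stated while completing in minutes on one CPU.

## Known limitations

- The DE test is a minimal two-group NB Wald test: no GLM covariates,
  no outlier refitting, no fold-change shrinkage.
- The merit>15 threshold is screen-size dependent (see above); the
  top-k merit ranking is the screen-size-free statement.
- The harmonization model assumes the two runs share a distribution up
  to a log-linear location/scale change; non-linear batch distortions
  are outside the model.
- Equal-frequency discretization is the only binning implemented for
  the merit statistic; entropy-based (MDL) binning would change merit
  values but not the ranking behavior the tests assert.
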
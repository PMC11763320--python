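# Methods

`cfmethdx` implements a serum cell-free DNA (cf-DNA) diagnostic workflow for
endometriosis-style case/control studies: absolute cf-DNA quantification by
qPCR standard curve, targeted bisulfite amplicon methylation calling over a
nine-gene panel, per-gene differential methylation testing, and a composite
elastic-net INDEX classifier validated by repeated hold-out splits. A
synthetic-study generator with known ground truth makes every stage testable
without sequencing data.

## Synthetic study generator

The generator emulates the study conditions the pipeline targets.

**Cohort.** 38 cases and 40 controls by default. Total cf-DNA abundance is
modeled as the copy number of a single-copy housekeeping gene (RPP30) per
qPCR reaction, drawn log-normally per group. Default natural-log locations
are ln(8602) for cases and ln(2224) for controls with scale 1.0 on both, so
the planted case/control median ratio is ~3.9 with heavy right tails; the
scale 1.0 was chosen so that sample extremes at n≈40 span roughly the three
decades a serum cf-DNA cohort shows. Per-sample, per-gene methylation levels
are beta-distributed around group means with concentration 50 (between-
subject SD ≈ 7 percentage points at a 50% mean), a typical magnitude for
blood-derived methylation markers. Four panel genes (DIP2C, DNMT1, RRP1,
USP1) are hypomethylated in cases by 15 percentage points by default; the
other five are null. Group means for the null genes (0.35–0.70) spread over
the informative mid-range.

**Amplicons.** Nine random amplicons of 170–270 nt carrying at least 4 CpGs
each, named for the panel genes. The length range keeps every amplicon
reconstructable from one overlapping 2×150 read pair (overlap ≥ 30 nt).
Amplicons model the bisulfite-converted top strand only, as amplicon
bisulfite PCR primers fix one strand.

**Reads.** Per molecule, each CpG cytosine is methylated with the sample's
gene-level probability; a methylated C is emitted as C with probability
`methylated_protection` (default 0.995) and an unmethylated C as T with
probability `conversion_efficiency` (default 0.99). All non-CpG cytosines
are treated as unmethylated — the basis of conversion-rate QC. Substitution
errors are uniform (default 0.001/base); there are no indels, chimeras, PCR
duplicates, or instrument-specific quality models (qualities are constant
Q30 with an optional low-quality tail), so passing tests demonstrate
correctness of the accounting, not robustness to indel-rich or
quality-degraded real libraries. Default coverage is 1000 read pairs per
amplicon (the depth is a free design choice; tests state theirs explicitly).
R1 is the 5′ read, R2 the reverse complement of the 3′ end. FASTQ.gz output
is written with a zeroed gzip timestamp so identical seeds give
byte-identical files.

**qPCR.** Cq = intercept + slope·log10(copies) + N(0, σ). Default slope
−3.3219 = −1/log10(2) (perfect doubling), intercept 38 cycles at one copy,
σ = 0.15 cycles, and a ten-fold standard dilution series from 200,000 down
to 2 copies per reaction (five decades), three replicates throughout.

## qPCR quantification

The standard curve is ordinary least squares of Cq on log10(copies);
amplification efficiency is E = 10^(−1/slope) − 1. Samples are quantified by
back-transforming each Cq replicate through the curve and averaging the
per-replicate copy numbers (not back-transforming the mean Cq — with
triplicates the two differ by a Jensen term; averaging concentrations
matches reporting concentration as the mean of the triplicate). Replicate
CVs above a threshold (default 0.35) raise a QC flag, never a rejection.
Copies per mL serum apply the volume chain 1 mL serum → 50 µL eluate → 5 µL
per reaction (×10); group summaries use per-reaction copies, and every ratio
reported is scale-invariant, so the choice of unit does not affect the
two-group factors.

Group comparison reports per-group mean/median/max/min, differences and
case/control ratios of means and medians (ratios rounded half-up to one
decimal only at report time), and a one-way ANOVA on raw copy numbers
(df 1, n−2). Raw-scale ANOVA on log-normal data is deliberately mirrored
from common practice in this assay class despite its heavy-tail
sensitivity; a log-scale option exists but is off by default.

## Methylation calling

All alignment-free steps are ungapped: amplicons are short, primer-anchored
and the dominant error mode is substitution. This is a documented limitation
for indel-rich real data.

- **Merging.** R2 is reverse-complemented and slid ungapped along R1; the
  accepted overlap is the candidate with the lowest mismatch fraction
  (ties: larger overlap, then smaller shift) subject to `min_overlap` = 20 nt
  and `max_mismatch_frac` = 0.1. Disagreements take the higher-Phred base
  (tie → R1), quality the maximum of the two.
- **Assignment.** Each merged read is compared in both orientations against
  each amplicon's bisulfite-expected reference: non-CpG C positions expect T
  (an unconverted C counts as mismatch), CpG C positions accept C or T, all
  other positions exact. The read is assigned to the unique gene minimizing
  the mismatch fraction at the best ungapped offset, at most 0.1 (a free
  threshold choice); ties are unassigned. The batched pipeline path
  restricts offsets to ±4 nt around the anchored position since merged
  amplicon reads start at the primer; the single-read API scans all offsets by
  default.
- **Counting.** At every panel CpG offset covered by an assigned read, C
  increments the methylated count, T the unmethylated count, anything else
  `other`. The per-site methylation rate is C/(C+T). Bisulfite conversion
  efficiency is estimated per sample as the T fraction at non-CpG cytosine
  positions; it is reported as QC and never used to correct rates.
- **Filtering.** A site is dropped if any sample covers it with fewer than 8
  reads (the chi-square stage pools across samples and needs the site
  defined in everyone) or if its pooled rate across samples is exactly 0 or
  1 (constant methylation carries no group information). Counts are never
  deleted; a boolean mask is kept.
- **Normalization.** Library-size factors are mean(total)/total_i from per-
  sample assigned read totals; zero-count samples are excluded with a QC
  flag. Normalized (fractional) counts feed reporting only — the chi-square
  stage uses raw integers, and rates are scale-invariant either way.
- **Gene level.** Gene methylation percent is the coverage-weighted pool
  100·Σc/Σ(c+t) over retained sites (robust at uneven coverage); an
  unweighted mean of site rates is available as an option.

## Differential methylation

One pooled 2×2 table per gene — C and T counts summed over the gene's
retained sites and over samples within group — tested with Pearson's
chi-square test of homogeneity, df = 1, no continuity correction (pooled
amplicon counts are large), at per-gene α = 0.05 with no multiplicity
correction by default (Benjamini–Hochberg behind a flag; a per-site 2×k
variant with df = k−1 behind another). Direction is *hypo* when the pooled
case rate is below the control rate. Pooling counts across subjects ignores
between-subject overdispersion, so on cohorts with real biological
variability the test is anticonservative as a subject-level inference; the
per-sample rate table is exported so users can run subject-level tests, and
the pooled test's null calibration is verified only under pure binomial
sampling.

## Diagnostic INDEX model

Features are the nine gene methylation percentages plus log10 copy number
(the raw copy scale spans ~3 decades; a raw option exists). Features are
standardized with training-fold statistics only; missing values are imputed
with training-fold medians; samples missing more than a third of features
are excluded with a warning.

The model is elastic-net penalized logistic regression minimizing

    mean deviance + λ·[α·‖β‖₁ + (1−α)/2·‖β‖₂²]

with an unpenalized intercept, solved in-package by FISTA proximal gradient
with adaptive restart on the slopes and an exact-curvature Newton update of
the intercept each iteration; the smooth case (λα = 0: ridge or
unpenalized) uses L-BFGS. The solver is deterministic and is cross-checked
in tests against fully-converged sklearn saga, R glmnet (thresh 1e-14) and a
statsmodels Logit oracle at λ = 0. Default stopping tolerance is 1e-7 on the
coefficient change with 20,000 iterations; cross-validation fits inside
tuning use a looser 1e-5 / 1000 because CV only ranks hyperparameters, and
the final model is refitted tightly.

Hyperparameters (α mixing weight, λ strength) are tuned by stratified
k-fold cross-validated AUC on the grid α ∈ {0, 0.1, …, 1.0} with a 50-point
per-α log-spaced λ path spanning four decades down from λ_max (the smallest
λ zeroing all slopes; α is floored at 0.001 in the λ_max formula). Ties
break toward larger λ then larger α (more parsimonious). The repeated
hold-out benchmark tunes inside every training fold on a coarser grid
(α ∈ {0, 0.5, 1}, 10 λs, k = 3) so thousands of splits stay tractable on
one CPU; the coarse grid brackets the same path.

**Benchmark.** Stratified random 70/30 train/test partitions (the hold-out
ratio is a design choice; configurable), 5000 splits by default (tests and
the bundled configs use 200–500; per-split metric means are split-count-
invariant in expectation), keyed on sorted sample ids so row order is
irrelevant, fully seed-determined. Five families: CART (depth 4), logistic
regression (unpenalized), RBF-kernel SVM (C = 1, scale gamma), random
forest (500 trees), elastic net — comparator settings are fixed documented
constants, not tuned. Metrics per split with case as the positive class:
AUC from continuous scores, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
accuracy at the 0.5 probability threshold (strict inequality → a 0.5
probability is called control). The threshold is fixed at 0.5; the
Youden-optimal point on the averaged ROC is reported but not used for
headline metrics. ROC curves are vertically averaged: per split the TPR is
interpolated on a fixed 101-point FPR grid, then averaged; the area under
the averaged curve is reported alongside the mean of per-split AUCs.

**Null calibration.** Calibration checks draw a fresh label permutation for
every replicate (the standard permutation-test construction). A single fixed
permutation does not give mean hold-out AUC 0.5 on a finite dataset: the
chance correlations of that one dataset appear in both train and test folds,
and at n = 200 with 10 features the elastic net reads them at mean AUC
≈ 0.59 — subsampling optimism, not leakage.

**INDEX.** The final model is refitted on the full table at the selected
(α, λ). INDEX(x) = b₀ + Σβⱼxⱼ; probability is the logistic transform;
status is *case* when probability strictly exceeds the threshold. Betas are
stored on the standardized scale together with algebraically equivalent
raw-scale coefficients (prediction uses the raw-scale form); the model
serializes to JSON and reloads bit-exactly.

## Numerical and degenerate-input conventions

- Standard curves need ≥ 3 distinct concentrations; a non-negative slope is
  flagged, and quantification refuses such a curve.
- Chi-square tables with a zero margin are "not testable" and recorded as
  skipped, as are genes with no retained sites.
- A single-class training fold is an error (the benchmark's stratified
  splitter cannot produce one; non-stratified draws are redrawn).
- Merge/assignment tie-breaks are fully specified (see above) so batched and
  single-read paths agree bit-for-bit.
- Factors are rounded half-up via decimal arithmetic, only in report fields.

## What passing tests do and do not show

The synthetic generator plants gene-level truth with beta between-subject
noise, binomial sampling at known coverage, and an idealized substitution-
only error model. Recovery and calibration tests therefore validate the
pipeline's accounting, filters, statistics and resampling machinery — not
performance on real serum libraries, where indels, adapter artifacts,
strand effects, conversion bias and cohort confounding exist. Reproducing
any real cohort's classifier performance is out of scope.

## Problem sizes used by the bundled checks

The default pipeline configuration runs the 38/40 cohort at 300 read pairs
per amplicon with a 200-split elastic-net benchmark; the recovery check uses
coverage 1000 over nine genes and 20 seeds; null-calibration checks use 2000
simulated tables and 500-split benchmarks. These sizes were chosen to give
stable estimates on a single CPU in minutes while keeping every binomial
tolerance meaningful.
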
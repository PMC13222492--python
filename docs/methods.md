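# Methods

This note documents the models and procedures implemented in `subtyper`,
the defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical decisions that were genuinely
open.

## Problem setting and assumptions

The classifier assigns one of a fixed set of tumor subtypes to a bulk
RNA-seq sample represented by gene-level feature counts, and abstains when
its confidence falls below a calibrated cutoff. The scheme assumes:

* subtype identity is expressed in the global transcriptome, not in a
  handful of marker genes — hence PCA features over all retained genes;
* training cohorts mix library protocols (poly(A) and total RNA) and carry
  batch structure, so protocol-sensitive genes must be removed and latent
  batch factors corrected *before* the classifier sees the data;
* at prediction time a sample arrives alone, so every preprocessing stage
  must be frozen at training time and applicable to a single profile.

## Stage-by-stage description

### Gene filtering

Four rules, applied in order, each gene recording the first rule that
fired:

1. *Low expression*: max CPM over all samples strictly below 5.
2. *Median percentile shift*: a gene's expression percentile is its rank
   within each sample's expression distribution, mapped by
   (rank−1)/(n−1)×100 with mean ranks for ties; the per-gene median of
   those percentiles is compared between protocol groups and a shift of
   ≥ 25 points excludes the gene. Ranking across genes within a sample (and
   not across samples within a gene) is the only reading under which the
   criterion can fire at all — ranking a gene against itself always gives a
   median percentile of 50 — so that is what is implemented.
3. *Support overlap*: the 5th and 95th CPM percentiles per protocol;
   exclusion when the 95th of one protocol is strictly below the 5th of the
   other, tested in both directions. The overlap and consistency tests
   operate on CPM, matching the scale of the low-expression rule.
4. *Consistency*: the fraction of cross-protocol sample pairs in which one
   protocol's value exceeds the other's, ≥ 0.95 in either direction. This
   pairwise-comparison reading was chosen over a percentile-threshold
   reading because it is symmetric, distribution-free, and reduces to the
   overlap criterion in the disjoint-support limit.

Boundary semantics are verbatim: "below 5" strict, "≥ 25" inclusive,
"lower than" strict. Single-protocol cohorts skip rules 2–4 with a warning
(the criteria are undefined with one group). Annotation/histone exclusion
lists and the protein-coding restriction are user-supplied gene-id lists;
the package does not re-derive annotation differences.

The percentile criterion needs stable within-sample gene ranks, which real
expression matrices provide through their wide spread of per-gene means.
On matrices whose genes all share one distribution the criterion is noise
and will fire spuriously — a property of the criterion, not of this
implementation.

### Frozen quantile normalization

Counts are shifted by a pseudocount of 1 and log₂-transformed. The
reference is the rank-wise mean of the sorted training columns; applying
the model replaces each sample's values rank-wise by the reference, with
tied input values receiving the mean of the reference values at their tied
ranks (implemented by interpolating fractional mean ranks). The transform
is written in-package: it is a small, fully specified primitive, and the
test suite checks it against an independent brute-force oracle on random
matrices to 1e-10.

### Frozen surrogate-variable correction

Let X be the normalized training matrix (samples × genes) and D the
one-hot subtype design. Residuals R = X − D(DᵀD)⁻¹DᵀX are computed, and
each gene is weighted by the p-value of its design F test before the SVD
that defines the surrogate-variable directions. This down-weighting of
design-associated genes is the essential ingredient of iteratively
re-weighted surrogate-variable estimation (implemented here as a single
weighting pass): without it, label noise leaves true-class structure in
the residuals of signature genes, the leading "surrogate variables" align
with the biology, and the correction destroys the signal the classifier
needs. With the weighting, planted batch factors are recovered at
|r| ≥ 0.99 while surrogate variables stay uncorrelated with class under
30% label noise (verified against generator ground truth).

The number of surrogate variables is chosen by permutation (parallel
analysis): each of 20 permutations scrambles every gene column of the
weighted residuals, the permuted matrix is re-residualized against the
design (so observed and null spectra share the same rank deficit), and
leading components are kept while their singular value exceeds the null's
95th percentile by a 10% relative margin. The margin exists because
quantile normalization couples samples (all share one value multiset),
lifting the whole observed leading spectrum ~2% above the permutation null
even with no latent factor; genuine factors exceed the null severalfold,
so the margin separates the two regimes cleanly. The count can also be
fixed in configuration.

Freezing: the model stores the gene-space projection (weighted SVD
directions), training gene means for centering, and per-gene regression
coefficients of expression on the training surrogate-variable coordinates.
Correction of any profile x is x − B·ŝ(x) with ŝ(x) the frozen projection
of the centered profile — the "exact" per-sample scheme. Training
corrected profiles are *defined* as this frozen application, which makes
the train/apply consistency contract exact rather than approximate.

### PCA

PCA of the corrected training matrix, centered by training gene means, no
unit-variance scaling (variance-explained targets are conventionally
computed on centered, unscaled data). k is minimal with cumulative
explained variance ≥ the target; the deployed profiles use 0.80
(solid-tumor-like, ST) and 0.85 (hematologic-like, HM). Helper statistics:
per-PC one-way ANOVA across subtypes with BH adjustment for ranking, and
for two-group contrasts a per-PC t test with the two-stage selection
q < 1e-20, relaxing to q < 1e-15 when empty (a flag records whether the
relaxed stage was used). BH adjustment is always within one family — all
PCs of one model.

### Stacked ensemble

scikit-learn `StackingClassifier` with five base learners (LDA;
RBF-kernel SVM wrapped in sigmoid `CalibratedClassifierCV`, 3 internal
folds; MLP with one hidden layer of 32 units; multinomial logistic
regression; random forest with 100 trees) and a logistic-regression
final estimator over the concatenated base-learner class probabilities.
Meta-features come from 5-fold stratified internal cross-validation, so
the final estimator never sees in-fold base predictions; a leakage probe
(random labels must generalize at chance) is part of the test suite.
Hyperparameters are library-standard, exposed in configuration, and seeded;
the scheme — not a particular weight set — is the deliverable. Confidence
is the final estimator's maximum class posterior.

### Abstention thresholds

Bootstrap replicates (in-bag drawn with replacement at training-set size;
out-of-bag the untouched complement) refit the quantile reference, the
surrogate-variable model (count held at the full-training estimate for
stability), PCA, and the classifier on the in-bag data, then score the
out-of-bag samples. Pooled out-of-bag confidences calibrate:

* the overall threshold — the largest cutoff retaining ≥ 95% (ST) / 90%
  (HM) of the pool;
* per-class thresholds — equal to the overall cutoff for major classes;
  classes with fewer pooled out-of-bag samples than 1/(1−retention) (too
  few for the retention quantile to be achievable) are *minor* and receive
  max(0.5, minimum observed confidence in the class).

A sample is filtered when its confidence is strictly below its *predicted*
class's threshold; exactly at the threshold counts as scored. Reported
accuracy is correct/scored; filtered samples are counted separately.

## Synthetic data generator

Counts are negative binomial (gamma-Poisson), variance μ + φμ², the
standard overdispersed model for bulk RNA-seq. The log₂ mean decomposes
into a log-normal baseline (mean 5, SD 1.5 on the log₂ scale), disjoint
per-subtype signature blocks (default 5 subtypes × 60 samples, 40 signature
genes at ±2 log₂ units), a protocol capture bias on 5% of genes (±3 log₂
units in poly(A) samples — strong biases of the kind poly(A) selection
produces on non-polyadenylated or short transcripts), one rank-1 batch
factor (N(0, 0.4) loadings on all genes, N(0,1) per-sample factor,
independent of subtype), and a log-normal library-size factor (SD 0.25).
Default dispersion φ = 0.05. The protocol mix is 25% poly(A) / 75% total
RNA. Ten percent of samples share a patient with one other sample of the
same subtype. The harder HM-like preset uses 10 subtypes × 40 samples with
25 signature genes at ±1 log₂ units, emulating the higher inter-class
similarity of hematologic subtypes.

What the generator does **not** emulate: transcriptome scale (2000 genes,
not ~17,000 — problem sizes were chosen so every experiment runs at desk
scale), correlated gene modules within subtypes, gradual or continuous
subtype boundaries, tumor purity variation, and protocol effects that are
gradational rather than multiplicative. Passing tests therefore demonstrate
that the *machinery* (filtering, freezing, calibration, abstention,
robustness) behaves as designed under its own assumptions — not that any
particular accuracy will be achieved on clinical data.

## Experiments the package ships

* **Threshold retention**: pooled out-of-bag retention meets the profile's
  target by construction of the quantile rule; the tests verify ≥ 95% (ST)
  and ≥ 90% (HM) end to end with 30 bootstrap sets.
* **Label-noise robustness**: a patient-level 70/30 split (stratified by
  the patient's modal subtype; all of a patient's samples stay on one
  side); for each noise level a fraction of training labels is redrawn
  from other classes, the entire pipeline is refit, and accuracy over
  scored test samples is compared to the same split's 0%-noise baseline.
  Reduced settings for these experiments: 3 replicates per level and
  3-bootstrap-set threshold calibration per refit. Class-specific noise
  (mislabeling only one class) is supported for minor-class analyses.
* **Recovery experiments**: planted protocol-biased genes recovered by the
  filter (sensitivity ≥ 0.95, false exclusions ≤ 0.05), planted batch
  factor recovered by the leading surrogate variable (|r| ≥ 0.9) and
  suppressed after frozen correction of held-out samples (mean |r| ≤ 0.2),
  end-to-end held-out accuracy ≥ 0.9 on the default cohort.
* **Open-set behavior**: a subtype withheld from training is filtered at a
  strictly higher rate than trained subtypes.

## Numerical and design choices

* Percentile convention (rank−1)/(n−1)×100 with mean-rank ties: endpoints
  at 0 and 100 make a 25-point quartile shift interpretable.
* Quantile-normalization ties average the reference values at the tied
  ranks.
* "Frozen consistency" is exact by construction (see above); bit-identity
  holds for whole-matrix reapplication, and single-sample application
  agrees to floating-point accumulation accuracy (different BLAS paths).
* Paired t tests between feature sets share bootstrap draws (pairing by
  replicate index); a constant nonzero difference with zero variance
  reports ±∞ with p = 0 by convention.
* Feature-set selection prefers the smallest set not significantly worse
  than the best at BH-adjusted 0.05 — parsimony over raw accuracy.
* Degenerate inputs fail loudly: genes missing from a query relative to
  the trained gene vector are a hard error (frozen transforms are defined
  only on that vector); zero-count query samples trigger a warning, not
  silent handling; empty retained gene sets, single-class designs, and
  classes smaller than the fold count are errors with guidance.
* Bundle serialization is a single versioned joblib archive; the stages
  are only valid together, and loading verifies the format version and
  cross-stage gene-count consistency. Round-trip preserves predictions
  bit-identically.

## Known limitations

* The surrogate-variable count estimator assumes batch factors are
  stronger than the quantile-normalization coupling artifact; factors
  within ~10% of the permutation null are not detected. The count can be
  fixed in configuration when a cohort's batch structure is known.
* The consistency criterion's pairwise comparison is O(n₁·n₂) per gene —
  fine at cohort scale, but the dominant filter cost on very large cohorts.
* Minor-class thresholds depend on the minimum of few observed
  confidences and are accordingly unstable; the 0.5 floor bounds that
  instability from below.
* Abstention calibration targets the pooled out-of-bag distribution; per
  true class, retention may differ (the per-class threshold equals the
  overall cutoff for major classes).
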
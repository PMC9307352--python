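# Methods

`ovaclass` re-implements, as a tested library, a classification pipeline for
two-class (normal vs. ovarian-cancer) microarray gene-expression data:
per-gene ANOVA gene selection, five feature-extraction methods, optional
correlation-distance feature selection, six classifiers trained against a
0.9/0.1 target encoding, and stratified 10-fold cross-validation reporting
nine confusion-matrix metrics plus MSE.  Because the original cohort is not
shipped, a seeded synthetic generator provides data with the statistical
structure the pipeline assumes.  This note records the model, the defaults,
and every place where the original description was silent and a design
choice had to be made.

## Synthetic cohort

On the log2 scale, gene g in sample s is

    log2 x[g, s] = mu_g + delta_g * 1{s in cancer} + sigma * t_nu

with `mu_g ~ N(base_log_mean, baseline_gene_sd^2)` a fixed per-gene
baseline, `delta_g = ±effect_size` for a DE subset of
`round(de_fraction * n_genes)` genes (up/down signs split 50/50 at random,
recorded in `de_truth`), and iid Student-t noise with `tail_df` degrees of
freedom scaled by `noise_sd`.  Intensities are `2**log2 x`.

Defaults (the desk-scale study conditions): `n_genes=2000`,
`n_per_class=50`, `de_fraction=0.1`, `effect_size=2.0`, `base_log_mean=7.0`,
`baseline_gene_sd=1.0`, `noise_sd=0.5`, `tail_df=5`.  The full 33,000-gene
scale is supported by raising `n_genes`; every dimensionality default
scales proportionally (see below).  Choices worth flagging:

* **Heavy-tailed noise.** Student-t with 5 degrees of freedom reproduces the
  strongly non-Gaussian, high-kurtosis feature summaries microarray
  intensities show in practice; `tail_df` must exceed 2 so the noise has a
  variance.
* **Per-gene baselines** (`baseline_gene_sd`, default 1.0 on the log2
  scale).  Real genes differ enormously in baseline expression; without
  between-gene structure, clustering genes (the FCM stage) would be
  meaningless.
* **What the generator does *not* emulate:** probe-level artifacts,
  normalization residuals, batch effects, gene-gene correlation beyond the
  shared class shift, and class-dependent covariance.  Passing tests on
  this generator therefore demonstrate that the pipeline machinery is
  correct and calibrated — not that the reported real-data accuracies
  transfer.

The generator is a pure function of its config (a single `numpy`
`default_rng(seed)` with a fixed call order), so identical configs are
bit-identical.

Calibration (enforced by tests): with `effect_size >= 2` and
`noise_sd <= 0.5` more than 90% of DE genes reach ANOVA p < 0.01 at 50
samples per class; with `effect_size = 0` the per-gene p-values are
uniform (Kolmogorov-Smirnov p > 0.01 on 2,000 genes).

## Gene selection

Each gene gets a one-way ANOVA F and p between the two classes.  The test
runs on `log2(x + 1e-9)` by default — the standard scale for microarray
differential expression, and the scale on which the generator's noise is
additive and symmetric so that null p-values are uniform.  (`log_transform=False`
gives intensity-scale tests.)  For two groups F equals the squared pooled
two-sample t statistic, which the tests verify against an independent
t-test.  Fold change is reported on the intensity scale as
`log2(mean_cancer / mean_normal)` with means floored at 1e-9; a gene whose
groups are constant and equal gets F=0, p=1 with a warning.

Selection modes: `fraction_by_p` (default, fraction 16000/33000 — the
study's reduction from 33,000 to 16,000 prominent genes), `top_k_by_p`, and
a volcano-style `thresholds` mode (p < p_max and |log2FC| > fc_min).  Ties
in p are broken by larger |log2FC|, then lower index.  The selected index
list is reported in ascending original gene order, so the gene ordering
that the transform extractors depend on is deterministic.

## Feature extraction

Input is the selected-gene intensity matrix; output is samples x features.
Dimensionality defaults preserve the study-scale ratios at any input size:
FCM uses `round(n_genes * 660/16000)` clusters and the other four methods
`round(n_genes * 3300/16000)` features (16,000 → 660 and 16,000 → 3,300 at
study scale).

**Fuzzy C-means (FCM).**  Genes are soft-clustered on their training-column
profiles by alternating optimization of the standard FCM objective
`sum_mn u_mn^y ||k_m - c_n||^2`, memberships `u ∝ (1/d^2)^(1/(y-1))`
normalized over clusters, centers the `u^y`-weighted means.  Defaults:
fuzzifier y=2, tolerance 1e-5 on the largest center shift, max 300
iterations.  Initial centers sit at per-coordinate quantiles of the items
at stratified random levels `(i + U_i)/C` (seeded), which spreads them
across the data range and avoids duplicate-center collapse.  An item equal
to a center receives full membership there (standard singularity rule);
empty clusters keep their previous center.  The objective after each
iteration is recorded and is non-increasing (property-tested).  A sample's
feature for cluster c is the membership-weighted average of that sample's
expression over the genes of cluster c, so with C equal to the gene count
the features reproduce the genes, and with perfectly redundant gene groups
they reproduce the group means.

**Softmax discriminant (SDA).**  The gene axis is partitioned into
near-equal contiguous blocks, one feature per block.  Block b of sample s
is scored against each class j over the training samples:

    d_s^j(b) = log sum_i exp(-lambda * ||z_sb - z_ib^(j)||^2)

with a training sample always excluded from its own class sum.  Two
numerical/design choices matter here:

* Genes are standardized (z-scored with training-fold mean and sd) before
  distances are computed.  On raw intensities (hundreds to thousands of
  units) every kernel term underflows at lambda=1 and the log-sum-exp
  degenerates to a nearest-neighbour distance; standardization puts block
  distances on the O(block size) scale the kernel expects.  lambda
  defaults to 1.0.
* The default per-block feature is the **softmax class probability**
  `expit(d_s^1 - d_s^0)` — the nonlinear transformation of the class
  distances that carries the label information behind the argmax
  assignment rule, bounded in (0, 1).  The raw score gap (`"difference"`)
  and the winning class's score (`"max"`) are available by flag.  The max
  variant is retained for completeness but is nearly uninformative whenever
  the two class clouds are congruent translations of each other (identical
  within-class densities), which is exactly the synthetic generator's DE
  model — a property the end-to-end tests made unmissable.

**Hilbert.**  Each sample's ordered gene vector is treated as a discrete
signal; the feature vector samples the magnitude envelope of its analytic
signal at `n_features` evenly spaced positions.  The envelope of a pure
cosine is 1 away from the edges, and the envelope scales linearly with
positive rescaling of the input (both tested).

**DCT.**  Leading `n_features` coefficients of the orthonormal DCT-II
(energy compaction keeps the smooth, high-variance structure).  The
full-length transform is orthonormal: perfect inverse and Parseval equality
are tested.

**FFT.**  Magnitudes of the leading `n_features` non-negative-frequency DFT
coefficients (`n_features <= n//2 + 1`); magnitudes are circular-shift
invariant and match a brute-force O(N^2) DFT on small inputs (tested).

**Feature statistics.**  For any feature matrix the per-class summary pools
all feature values of the class: mean, sd (n−1), variance, Fisher-Pearson
skewness, *non-excess* kurtosis (Gaussian → 3), plus: `pearson` — the
correlation between the two class-mean feature vectors; `t_test` — the
p-value of a two-sample t-test between the classes' per-sample feature
means; and sample entropy SampEn(m=2, r=0.2·sd, Chebyshev matching)
computed per sample and averaged.  A constant series has sample entropy 0
by convention (with a warning).

## Feature selection

Relevance of a feature to the label vector is a correlation *distance*
d = 1 − a.  Default `pearson_distance` uses a = |Pearson r| (absolute, so
anti-correlated features count as relevant; a constant feature has
distance 1).  `distance_correlation` uses the Szekely distance correlation
computed from double-centered pairwise distance matrices, which also
captures non-linear association.  The k features with the *smallest*
distance to the label are kept (default k=45, the study's selected feature
count), ties broken by lower index, computed on training folds only.

## Target encoding and classifiers

All six classifiers regress onto targets T_C=0.9 (cancer), T_N=0.1
(normal); the gap T_C − T_N ≥ 0.5 is enforced.  Each emits a continuous
score and the label `score > 0.5` (ties to normal), so scores and labels
are consistent by construction.

* **GMM** — per-class mixture of Q diagonal-covariance Gaussians (default
  Q=1, a plain Gaussian; EM with seeded initialization for Q>1) with a
  variance floor of 1e-6 times the mean feature variance.  Score = posterior
  probability of cancer (training class priors) mapped onto [T_N, T_C].
* **DFA** — each sample's feature vector, in feature order, is summarized
  by its detrended-fluctuation scaling exponent alpha: cumulative-sum
  profile, per-box order-1 polynomial detrend, RMS fluctuation G(s), alpha
  the log-log slope over log-spaced box sizes from 4 to length/4 (extended
  to length/2 for short vectors; vectors shorter than 16 fall back to the
  sample mean as the summary).  The decision threshold is the midpoint of
  the training class-mean alphas; the score maps alpha through a logistic
  centered at the threshold with slope set by the class-mean gap.  Known
  limitation, deliberate and documented: alpha is invariant to location and
  scale of the series, so when the class signal is purely a mean shift
  (as in the synthetic generator) this classifier is close to chance — the
  end-to-end grid shows it clearly.  The amplitude-dependent fluctuation
  G(s) itself is exposed (`dfa_fluctuations`) but is not the classifier's
  statistic.
* **NLR** — scalar logistic curve `T_N + (T_C−T_N)/(1+exp(−(a+b·u)))` in
  the sample-mean feature u, fitted to the encoded targets by damped
  Gauss-Newton (max 200 iterations, tolerance 1e-8, step halving when the
  SSE would increase; slope sign initialized from corr(u, targets)).  A
  projection vector can replace the mean.  Limitation: on feature sets
  whose mean carries little class signal (signed DCT coefficients average
  toward DC/K) the scalar summary is weak by construction.
* **BLDC** — Bayesian linear regression of the encoded targets on
  (features, bias), with prior precision alpha and noise precision beta
  maximized by the MacKay evidence fixed point (caps 1e10/1e12 keep the
  noise-free limit finite; in that limit the weights reach the
  least-squares solution, which the tests verify).
* **LR** — ordinary least squares via pseudo-inverse (well defined for
  d ≥ n); an IRLS logistic variant is available behind `logistic=True`.
* **KNN** — Euclidean majority vote among K neighbours, K odd (default 3,
  even K rejected), neighbour ties resolved by training index so
  predictions are invariant to training-order permutation.  Score = cancer
  vote fraction mapped onto [T_N, T_C].

Models serialize to JSON (parameters, hyperparameters, encoding) for
predict-only reuse.

## Evaluation

From TP/TN/FP/FN (cancer positive): accuracy, precision, F1, error rate,
Jaccard and CSI = PPV + SEN − 100 on the percent scale; MCC and
Fowlkes-Mallows as unitless coefficients; plus the MSE of scores against
encoded targets.  Values are held at full precision; printing rounds
half-up to 3 decimals (the convention the published tables use — four of
their cells sit exactly on a half, e.g. 57.8125 → 57.813).  A metric with
a zero denominator is 0 and flagged.  Metric identities
(accuracy + error = 100, Jaccard ↔ F1, FM = sqrt(PPV·TPR),
CSI = PPV + SEN − 100, prediction-flip negates MCC) are property-tested
over random confusion matrices.

Cross-validation is seeded stratified k-fold (default k=10; each class
must have at least k samples).  Within every fold the full pipeline — gene
selection, extraction-model fitting, feature selection, classifier — is
fitted on the training 90% only; the tests verify that perturbing held-out
values changes nothing that was fitted.  The headline confusion matrix
pools the test folds (summing to the cohort size), with per-fold matrices
and fold-mean metrics also reported.  The grid runner shares per-fold gene
selection across methods and per-fold features across classifiers, which
keeps the full 5 x 6 x 2 grid on 2,000 genes x 100 samples under half a
minute on one CPU.

An audit utility recomputes all metrics from a table of confusion matrices
and diffs them against printed values (tolerance 0.001 for percent
metrics, 0.0005 for MCC/FM).  The 60 published rows shipped in
`reference_tables` audit clean in all eight metric columns.

## Determinism

One master seed governs a run.  Every stochastic stage (fold assignment,
FCM initialization, classifier initialization) derives a substream seed
from (master seed, stage label, fold) via CRC32, below 2^31.  Identical
configs produce byte-identical `metrics.csv`/`metrics.json` artifacts; the
output directory is deliberately excluded from the config echo inside
those artifacts.

## Problem sizes used in the test suite

Unit tests run on 200-500-gene cohorts with 10 samples per class; the
calibration and end-to-end checks use the 2,000-gene x 100-sample
desk-scale defaults (the end-to-end grid uses effect size 3, i.e. strongly
separable classes).  These sizes keep the full suite around ten seconds
plus ~20 s for the end-to-end grid while preserving every ratio
(16000/33000 gene fraction, 660/16000 and 3300/16000 feature ratios, k=45
selected features, 10-fold CV) of the study-scale pipeline.
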
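# Methods

## Problem setting

`tepsel` implements a screening pipeline for multiclass cancer detection
from tumor-educated platelet RNA-seq profiles: seven classes (six cancer
subtypes plus healthy controls), on the order of 10^4 gene-expression
features per sample, and far fewer samples than features. The pipeline's
job is (i) to rank genes by how informative they are about the class
label while penalizing redundancy among selected genes, (ii) to find how
many top-ranked genes a support-vector classifier actually needs, and
(iii) to distill a small biomarker panel.

## Preprocessing

Three steps, applied to the whole matrix in this order:

1. **Zero-fraction filter.** A gene is discarded when its value is zero
   in *more than* 90% of samples; a gene zero in exactly 90% is kept
   (strict-inequality reading of "more than"). The threshold is a
   parameter (`zero_fraction_threshold`, default 0.90).
2. **Quantile normalization.** Every sample's sorted value vector is
   replaced by the reference vector (the mean of per-sample sorted
   vectors), preserving within-sample ranks. Tied values within a sample
   receive the mean of the reference values across the tied ranks. This
   tie rule is the standard mean-of-sorted method, but it costs exact
   idempotence on heavily tied (integer-count) data: a tied block's
   averaged value perturbs the next pass's reference. On tie-free data
   normalization is a fixed point to well below 1e-9.
3. **log2(x + 1).** The offset handling of zeros is not canonical
   anywhere; x + 1 is the field convention and the offset is exposed.

Normalization precedes any train/test split. This mirrors the usual
whole-matrix practice for this kind of screen and is a known, accepted
information-leak caveat: fold-wise test samples have influenced the
reference distribution.

## Discretization and mutual information

The MI functional is defined for distributions; with ~285 samples per
gene the practical estimator in the mRMR family is the discrete plug-in
sum. Each gene is z-scored (population SD) and cut into three states at
±`k_sigma` (default 1.0): low / mid / high. Constant genes map wholly to
the middle state. Any `n_bins` other than 3 switches to per-gene
equal-frequency binning. MI is then the plug-in estimate from the
empirical joint table, base-2 logarithm (bits), with 0·log 0 = 0. The
estimator satisfies non-negativity, symmetry, I(x,x) = H(x), and
I(x,y) ≤ min(H(x), H(y)); all are property-tested.

The choice of cut points and log base means absolute MI values are only
comparable within one configuration; published per-gene MI values from
any specific cohort depend on that study's (unstated) estimator and are
not reproduction targets.

## mRMR ranking

Two lists over the same feature set:

* **MaxRel**: sort by D = I(f, c) descending, ties broken by input gene
  order (stable).
* **mRMR**: greedy selection; at each step the candidate maximizing
  D − R is moved to the selected set, R being the mean MI between the
  candidate and the already-selected features (empty-mean convention
  R = 0 at step one). The recorded score is D − R at selection time.

The implementation keeps a running redundancy sum per candidate and
computes the MI of each newly selected feature against all remaining
candidates in one vectorized pass, so each feature pair is evaluated at
most once (O(N·S) pair evaluations for S selections). `n_select` caps the
number of selections; the default ranks everything. Correctness is pinned
by an exact-equivalence test (ordering and scores) against a naive
reference that recomputes D and R from scratch each iteration, over 100
random discrete datasets of up to 20 features, including ties.

## Classification and measurements

The classifier contract is a maximum-margin SVM in the SMO-default
configuration: linear kernel, complexity constant C = 1.0, one-vs-one
pairwise voting for the multiclass decision, with per-feature
standardization. Standardization is fitted on each training split only —
the one place this package deliberately tightens the protocol, since a
globally fitted scaler would leak fold information and nothing hinges on
it. scikit-learn's `SVC` provides the solver.

Ten-fold cross-validation: samples are randomly permuted under a seed and
dealt round-robin into k folds (first n mod k folds one larger), each
sample tested exactly once. Folds are non-stratified by default to match
the plain "randomly and equally divided" protocol; a stratified mode
exists because a 14-sample class can otherwise vanish from a training
split. One partition is fixed per run and shared by every feature-subset
evaluation, so IFS curves compare subsets rather than fold luck.

From the pooled confusion matrix: per-class accuracy ACC_j = x_j / X_j,
overall accuracy TACC = Σ x_j / Σ X_j (identically the class-size-weighted
mean of ACC_j), and one-vs-rest sensitivity/specificity; SN_j ≡ ACC_j by
construction. Degenerate denominators (empty class, single-class matrix)
raise rather than returning NaN.

## Two-stage IFS

Stage 1 evaluates prefix sizes step, 2·step, … (step defaults to 10,
optionally capped by `max_size`). The near-optimal band is formalized as:
all tested sizes with TACC within `delta` (default 0.01) of the stage-1
maximum, widened by `pad` grid steps and clipped to [1, N]. The default
delta reflects the kind of spread seen between a coarse-grid peak and the
cluster of near-maximal sizes in this family of screens. Stage 2
evaluates every size in the band; the optimal model is the *smallest*
size attaining the stage-2 maximum (cheapest-model tie rule), re-run in
full for the report. Panel benchmarking reruns discretization, mRMR and
both IFS stages on the matrix restricted to the panel's intersection with
the measured genes.

## Biomarker extraction and clustering

The biomarker set is the prefix of the MaxRel list with MI *strictly*
greater than `mi_threshold` (default 0.360); because MaxRel is sorted,
the result is always a gap-free prefix and larger thresholds give nested
subsets. Cross-referencing attaches 1-based mRMR ranks (from a computed
list or a supplied gene → rank mapping) and reports whether the whole set
sits inside a given optimal subset size. The report step uses
average-linkage agglomerative clustering on correlation distance —
conventional for expression heatmaps; the method is a parameter in
spirit, and constant rows are assigned unit distance rather than NaN —
cutting the gene dendrogram into `n_gene_groups` (default 3) groups.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not platelet biology:

* **Counts**: negative binomial via gamma-Poisson; per-gene baseline mean
  lognormal(μ=3, σ=1.5) (median ≈ 20 reads, heavy right tail), shared
  overdispersion `dispersion` (default 0.3, variance μ + 0.3 μ²) — a
  realistic bulk-RNA-seq spread.
* **Class structure**: default class sizes are the published 285-sample
  breakdown (39/42/40/14/60/35/55). Each of `n_informative` genes gets a
  multiplicative mean shift exp(`effect_size`) in exactly one class,
  assigned round-robin so all classes carry signal.
* **Zero inflation**: a `zero_gene_fraction` share of genes (taken
  disjoint from the informative block) has each entry zeroed with
  probability 0.95, so nearly all of them trip the 90%-zero filter.
* **Determinism**: identical config + seed gives bit-identical output.

Not emulated: library-size variation between samples, gene–gene
correlation beyond the planted signal, multi-class effects per gene, and
any real platelet count distribution. Passing tests on these cohorts
therefore demonstrate that the machinery recovers planted structure under
a clean generative model — not that any particular accuracy carries over
to real cohorts, where signal is weaker and correlated.

## Problem sizes and numerical choices

The heavier self-checks run at: 2000 genes / 50 informative / effect 2.0
/ the 285-sample class breakdown over 5 seeds (parameter recovery and
IFS performance, with mRMR and the stage-1 grid capped at 300 — six times
the planted signal size); 20 label permutations on a balanced 7 × 20
cohort (null calibration against TACC = 1/7; balance matters, since with
skewed classes the permutation null sits at the majority-class rate
instead); and 5 paired 400-gene cohorts for the panel-direction check.
These sizes were chosen as the smallest at which the expected effects are
unambiguous.

Tolerances: exact identities (MI properties, metric identities, oracle
equivalence) are asserted to 1e-12; stochastic checks use three
Monte-Carlo standard errors. Tie-breaks are everywhere deterministic
(input order / smallest size), so a fixed seed reproduces every output
bit-for-bit.

## Known limitations

* Whole-matrix normalization before CV (fidelity to the protocol) mildly
  inflates absolute accuracies.
* The plug-in MI estimator is biased upward at small sample sizes; ranks
  are far more stable than MI magnitudes, and only ranks feed the
  pipeline.
* The greedy mRMR order is a heuristic; no optimality over subsets is
  claimed, which is exactly why IFS re-scores prefixes with a classifier.
* Quantile normalization with the tie-averaging rule is not exactly
  idempotent on tied data (see above).
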
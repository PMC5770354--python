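# Methods

This note documents the statistical procedure implemented by `qsarflow`,
the defaults and why they were chosen, what the synthetic benchmark does
and does not emulate, and the numerical corner cases.

## The modeling protocol

The pipeline follows a fixed regression protocol for compound–activity
data. Its premise is the similarity principle: structurally similar
compounds tend to show similar activity, so a feature space in which
similarity is meaningful supports both a cheap modelability estimate and
distance-based domain-of-applicability reasoning.

**Curation.** Records are filtered to one activity type, records with
missing or non-positive activity values are dropped (the activity scaling
takes a logarithm, so a non-positive concentration is treated as missing),
structures are canonicalized and desalted to the largest
carbon-containing fragment, and duplicates by canonical structure are
resolved. Duplicate resolution keeps the record with the unique most
recent year; when the most recent year is tied or no years are present,
the median-activity record among the candidates is kept (even-sized
candidate sets keep the lower-input-index of the two middle records).
This makes deduplication deterministic and order-independent whenever
years are distinct. The per-rule drop counts always reconcile:
`sum(drops) + |output| = |input|`.

**Activity scaling.** Raw activities are assumed to be nM concentrations
(the convention of ChEMBL `standard_value` for Ki/IC50-type measures;
payload entries with other declared units are skipped, not converted).
The piecewise transform maps ≥ 10,000 nM (10 µM, effectively inactive) to
0, ≤ 1 nM (maximal potency) to 1, and interpolates as (4 − log₁₀ v)/4 in
between; it is continuous at both cut-offs, monotone non-increasing, and
surjective onto [0, 1]. Users with already-normalized responses set the
skip flag and the values pass through unchanged (they must lie in [0, 1]).

**Partition and feature scaling.** A uniform random 75/25 split produces
the training set and the Independent Validation Set (IVS); the training
size is round(0.75·n) with both sides forced non-empty. Min–max
parameters are fitted on the training rows only and applied unchanged to
the IVS, without clipping: fitting on all rows would leak the IVS into
model selection, and out-of-range IVS values are legitimate
applicability-domain signal. Columns constant on the training partition
have no fittable range and are dropped (and logged) before scaling.

**Modelability (MODI).** MODI for regression is the leave-one-out kNN
coefficient of determination on the scaled training set: each compound's
prediction is the unweighted mean activity of its k nearest neighbours by
Euclidean distance over all retained columns (descriptors and fingerprint
bits alike, all on [0, 1]); exact distance ties break toward the lower
row index via a stable sort. Both k = 3 and k = 5 are reported; the gate
uses k = 5 and passes only when the score strictly exceeds 0.45. In halt
mode a failing gate aborts the run with curation advice; warn mode
proceeds with a logged warning. The score can be negative (neighbours
predicting worse than the mean); constant activities make it undefined
and fail the gate with an explicit error.

**Feature ranking.** Variable importance is the permutation importance
native to bagged regression trees: for each tree, the increase in
out-of-bag MSE when one feature column is permuted among that tree's OOB
samples. The raw ("unscaled") score of a feature is the mean increase
over trees; the "scaled" score divides by the standard error (per-tree
standard deviation over √ntree), with z := 0 when the standard error is
exactly 0 (e.g. a constant column, whose importance is exactly zero).
Because one forest is stochastic, the fit is repeated over an nfold
shuffled cross-validation split of the training set — run t fits on fold
t's training portion with seed base+t — and per-run scores are averaged
(the unscaled aggregate averages raw importances; the scaled aggregate
averages per-run z ratios). Features are then ranked in descending score
with ties broken by name; no feature is eliminated at this stage. The
ensemble is built by hand on top of scikit-learn `DecisionTreeRegressor`
with explicit bootstrap/OOB bookkeeping, because the stock random-forest
API does not expose per-tree OOB permutation importance. Defaults:
ntree = 500, p/3 features tried per split (the regression convention),
nfold = 10.

**Stepwise selection.** The training partition is split once more, 75/25,
into a sub-train and internal test set held fixed across steps. Ranked
features are introduced cumulatively (prefix sizes step_size, 2·step_size,
…, always ending with the full prefix); each prefix gets a freshly fitted
learner on the sub-train rows and an internal-test RMSE/PVE. The selected
feature set (SF) is the prefix of minimal internal-test RMSE, ties going
to the smaller prefix; an optional parsimony tolerance τ > 0 instead
accepts the smallest prefix within τ of the minimum (off by default).
The IVS never enters this procedure. The default learner is SVM
regression with an RBF kernel, C = 1, ε = 0.1 and kernel width
γ = 1/(number of features currently in the model) — standard library
conventions, all configurable; a random forest can be swapped in.

**Final models, validation, applicability domain.** The full-feature
model and the SF-model(s) are fitted on the entire training partition and
scored with PVE and RMSE on (a) the internal test rows replayed from the
stepwise stage, so internal and external numbers are comparable, and (b)
the IVS. The applicability domain is distance-based: the threshold is
mean + Z·std (population std, Z default 0.5) of each training compound's
Euclidean distance to its nearest training neighbour (self excluded),
computed in the scaled feature space restricted to the columns of the
model being assessed — the domain is judged in the model's own input
space. An external compound is outside iff its nearest-training distance
strictly exceeds the threshold; a compound exactly at the threshold is
inside. Flagged compounds are reported, never removed. The Z form of the
threshold is the conventional distance-based construction; Z is exposed
in the configuration.

**Persistence and determinism.** Every stage writes its artifact
(curation log, feature matrix + manifest, split, MODI report, importance
tables, stepwise traces and plots, validation report, AD report, model
bundles) into the working directory, and the run manifest lists them.
All stochastic stages derive their seeds from one base seed at fixed
offsets (partition +1, ranking +100, stepwise +200, model fits +300), so
identical configuration and seed reproduce byte-identical reports. A
model bundle stores the fitted learner, the feature subset, the scaler
parameters, the activity-scaling flag and the scaled training matrix, so
external predictions are reproduced bit-exactly and carry AD flags.

## The synthetic benchmark

The generator provides ground-truthed datasets for every stage without
chemistry downloads. It emulates one specific, load-bearing property of
real bioactivity data: *whole-feature-space similarity tracks activity*.
Rows draw a latent position u ~ U[0, 1] (a "chemical series" coordinate);
every feature is a clipped affine projection of u plus feature noise —
the designated informative columns with very low noise (0.01), continuous
distractors with high noise (0.25), and half of the distractor columns
binarized at 0.5 with per-column offsets (noise 0.05), which makes the
binary block a thermometer code whose Hamming distance grows with latent
distance, like fingerprint similarity. The response is a function of the
realized informative columns only — linear, or with an interaction and a
quadratic term — min–max squashed onto [0, 1] (so synthetic activities
are drop-in replacements for scaled bioactivities) plus Gaussian noise.
The response coefficients are aligned with each informative column's
projection sign so their contributions add coherently along the latent
axis; with random signs the latent parts can cancel and the squash then
amplifies feature noise into the response, destroying the smoothness the
benchmark is supposed to have.

This construction gives, by design: high MODI on the smooth benchmark
(neighbours in the full 200-column space share latent positions and hence
activities), recoverable informative features (they are the least noisy
views of the latent axis and the only direct inputs to the response), and
a selection benefit (distractors add only noise to an RBF kernel). The
activity-cliff variant replaces rows with near-duplicate feature pairs
(perturbation 10⁻³, binary bits identical within a pair) carrying
activities near 0 and near 1 — the canonical violation of the similarity
principle — which drives MODI strongly negative.

What the generator does **not** emulate: real descriptor distributions
and inter-block correlation structure, multiple chemical series (the
latent space is one-dimensional), assay noise heteroscedasticity,
activity-type mixtures, or class imbalance in fingerprint bits. Passing
the benchmark tests therefore shows the machinery is correct and the
protocol behaves as intended under its own assumptions — not that any
particular real target will reach a given PVE.

An embedded list of 40 hand-curated drug-like SMILES (with planted
duplicates, a hydrochloride salt, one invalid SMILES, one missing
activity and one off-type record) exercises every curation branch with
exactly known drop counts.

## Problem sizes used in the test suite

The benchmark-scale tests (modelability discrimination, ranking recovery,
selection benefit) run at n = 300, p = 200, 10 informative features,
noise 0.05, with nfold = 5, ntree = 200 and stepwise step_size = 4; the
selection-benefit check averages 10 generator seeds. These are the
package's chosen benchmark sizes — large enough for stable forest
importances (the 200-tree/500-tree rankings agree on this benchmark)
while keeping the suite quick. Library defaults remain ntree = 500,
nfold = 10, step_size = 1.

## Numerical choices and degenerate inputs

* Constant (zero-variance) feature columns are removed when feature
  blocks are merged — before any scaling, since min–max is undefined for
  max = min; columns constant only on the training partition are removed
  after the split. A constant column reaching the scaler raises an
  internal-consistency error rather than silently producing NaNs.
* kNN distance ties break toward the lower row index (stable argsort);
  ranking score ties break by ascending feature name; stepwise RMSE ties
  break toward fewer features. All tie-breaks are deterministic.
* PVE/MODI are undefined for constant observed activities and raise; RMSE
  of an empty vector raises.
* The partition requires n ≥ 4; the stepwise internal split requires at
  least 4 rows on each side; forest importance requires n ≥ 10 and the
  LOO kNN requires n > k.
* Bootstrap replicates whose OOB set has fewer than 2 samples contribute
  zero importance for that tree (no usable error estimate).
* MACCS keys have a fixed 167-bit length; a requested bit width is
  ignored with a warning. Fingerprint bit matrices are {0, 1}-valued
  floats.
* Activities equal to 0 or below are treated as missing during curation
  (the log transform requires positivity).

## Known limitations

* Eq-style activity scaling assumes nM units; payload entries in other
  units are skipped rather than converted, so datasets reported mostly in
  µM shrink accordingly.
* The stepwise search is a forward pass over one fixed ranking — no
  backward elimination or floating search — and its internal split is
  drawn once, so the selected count inherits that split's sampling noise.
* The applicability-domain threshold (mean + Z·std of training NN
  distances) is one conventional choice among several; leverage- or
  density-based domains are out of scope.
* Classification modelability criteria and 3-D/conformer-dependent
  descriptors are not implemented.
* MODI and the final models share the training partition, so the gate is
  an optimistic estimate of modelability for very small datasets.
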
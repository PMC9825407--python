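# Methods

This note documents the models and procedures implemented in
`cytoresponse`, the assumptions behind them, the defaults that matter, and
what the synthetic-data tests do and do not establish about real data.

## Data model

A sample is a cells × channels matrix of non-negative "dual count"
intensities with metadata (patient, timepoint in hours, batch, role).
Channels are *clustering* (19 surface markers), *excluded* (2 surface
markers kept out of top-level clustering but used for sub-clustering), or
*functional* (15 intracellular phospho-markers). All analysis happens on the
variance-stabilized scale `v = asinh(x / c)` with cofactor `c = 5`, the mass
cytometry convention.

## Batch standardization

Each acquisition batch carries an aliquot of one shared reference material.
For each channel, the empirical quantiles of each batch's reference at the
grid 0%, 1%, …, 100% (101 knots; linear interpolation of order statistics,
the "type 7" convention, recorded in the serialized map) define a
piecewise-linear map onto the quantiles of a designated standard batch.
The standard batch is an analyst choice and must be given explicitly.

Numerical choices:

* **Ties** (zero-inflation atoms): consecutive identical source knots are
  collapsed to one knot whose target is the **median** of their targets.
  Both references carry an atom at the same point of the distribution, so
  the median equals the target's own atom value and the map carries atom
  onto atom exactly; a mean would drift off the atom by the few above-atom
  knots and displace the entire atom mass in distribution distance.
* **Extrapolation**: outside the knot range the terminal segments extend
  linearly, with slopes taken as a secant over the outermost ~5 knots (the
  5% tail window). The spacing of the two extreme order statistics is far
  too noisy to extrapolate from; with a population absent from the
  reference material, cells beyond the reference's support would otherwise
  map to absurd values.
* **Degenerate channels** (constant reference): pass-through with a warning.
* Excluded channels are never corrected (they were excluded precisely for
  batch-variable staining).

Because the map is monotone, within-channel cell rankings — and hence which
cell attains a given percentile — are unchanged by correction.

A practical sensitivity worth knowing: with *small* reference aliquots, the
sampling noise of mode fractions misaligns the knots spanning the gap of a
bimodal channel between batches, and mode-edge cells can be mapped across
the gap. Reference aliquots are full acquisitions in the emulated design;
the generator defaults to 5,000-cell references for this reason, and the
guarantee tests run at the 10⁴ scale.

Exactness caveat: type-7 quantiles commute with a piecewise-linear map only
where the map is linear between adjacent order statistics, so
knot-level reproduction of the target quantiles is exact when the grid
quantiles coincide with order statistics (reference size n with
(n − 1) mod 100 = 0) and, at collapsed tie-knots, holds up to the span of
the tied targets (an atom cannot be split by any single-valued map).

## Clustering

A 5×5 rectangular self-organizing map is trained on the pooled
pre-treatment patient cells and healthy-donor cells over the 19 clustering
channels: classic online updates with a Gaussian grid neighborhood,
learning rate decaying linearly 0.05 → 0.01 and radius max(rows, cols)/2 →
0.5 over 10 shuffled passes, followed by a **convergence phase** of 10
zero-radius passes that snap each node to the centroid of its best-matching
cells. Without the convergence phase, node weights linger between
populations and downstream grouping is unstable across seeds.

Nodes are grouped into k = 10 metaclusters by consensus: 100 resamples of
90% of the nodes, each cut into k groups by Ward-linkage hierarchical
clustering of the node weights; the co-assignment frequencies form a
consensus matrix, and the final labels cut an average-linkage tree of
1 − consensus. Nodes holding < 0.5% of training cells are excluded from the
consensus — they represent essentially no population, and as dendrogram
outliers they would consume metaclusters and force genuine populations to
merge — and afterwards inherit the nearest retained node's label.

Every cell of every sample (including post-treatment) is assigned to the
Euclidean-nearest node ("closest cluster center"; ties break to the lowest
node index) and inherits the node's metacluster. Assignment to the nearest
metacluster *centroid* is available behind a flag; nearest-node is the
default reading. Sub-clustering re-runs the same machinery on one
metacluster's cells using all 21 surface markers; a consensus-dispersion
score (mean distance of consensus entries from {0, 1}) flags sub-cluster
structure that resampling does not support.

## Features

Per sample and metacluster, each functional marker is summarized by the
90th percentile (type 7) of the transformed intensities; fewer than 10
cells (default `min_cells`) yields a missing value — a tail percentile of a
handful of cells is noise. The patient matrix holds these levels at each
timepoint, the 24 h / 0 h ratio per MC × marker (denominators below 1e-6
flagged missing rather than exploding), the 10 MC sizes (% of cells at
baseline), and age (years) and sex (0/1): 612 columns in the default
10-MC × 15-marker × 3-timepoint design. The 24 h − 0 h difference (delta)
is available behind `include_delta`. Missing entries (absent 4 h samples,
sparse metaclusters) are imputed with the cohort column mean; the
missingness mask and an imputation log are kept alongside the matrix,
because the penalized model needs a complete matrix but the imputation is
information the reader of a selection result needs.

## Survival analysis

**Penalized model.** The Lasso–Cox objective `−(1/n)·pl(β) + λ‖β‖₁` (Breslow
partial likelihood; ties by the Breslow approximation) is solved by cyclic
coordinate descent on the usual quadratic approximation (gradient and
diagonal Hessian in the linear predictor), with an ever-active set, full
KKT checks, warm starts along a decreasing λ path, and convergence measured
on both the linear predictor and the partial likelihood. Columns are
z-scored, so coefficients are log hazard ratios per standard deviation. At
λ ≥ λmax (largest absolute score component at β = 0, over n) the solution
is exactly zero; at λ = 0 it is the unpenalized maximizer (checked against
an independent Newton oracle and against an independent coordinate-descent
implementation in the test suite). With exactly duplicated columns the L1
solution is non-unique; this implementation deterministically concentrates
the shared coefficient on the first column — the invariant is the sum.

**Nested leave-one-out selection.** Outer loop: every 1-patient subset is
left out once; inner loop: leave-one-out on the remainder scores each λ by
the cross-validated partial likelihood (the Verweij–van Houwelingen
construction, so censored left-out subjects still contribute through risk
sets), and the **1-SE rule** picks the largest λ within one standard error
of the best value — the standard sparser choice for feature selection; the
CV-minimum rule is available (`rule="min"`). Per-fold selected features
accumulate into selection frequencies. The final model refits the whole
cohort at the λ chosen by the inner criterion on the full cohort; the
selected set is then refit *unpenalized* (lifelines) to report per-feature
log-HR per SD, Wald p, and Benjamini–Hochberg adjusted p across the refit
features (penalized point estimates are biased toward zero and carry no
standard errors). Raw univariate Cox p-values are also emitted. The λ grid
defaults to 15 log-spaced values from λmax down to 0.1·λmax: below that the
p ≫ n fits are near-saturated and the inner criterion never chooses them;
CV-fold fits run with capped iteration budgets (tol 1e-5) while final and
oracle-facing fits use precise settings (tol ≤ 1e-6).

**Stratification.** The selected feature is split at the cohort median
(value ≤ median → "low"; even n with distinct values splits equally);
Kaplan–Meier curves per arm; the Mantel–Cox log-rank test from the
per-event-time O − E tabulation, with HR = (O₁/E₁)/(O₂/E₂) and CI
exp(log HR ± 1.96·√(1/E₁ + 1/E₂)) as the figure-style summary. Overall
survival can be administratively censored at 2 or 5 years. Confounder
models use counting-process episode splitting at the transplant day
(covariate 0 before, 1 after; total follow-up conserved exactly) fitted
with lifelines' time-varying Cox; constant covariates are inestimable and
reported as dropped. Fisher exact p-values sum hypergeometric
probabilities no larger than the observed table's (relative tolerance
1e-7); BH adjustment is the standard step-up.

## Gating and drug screening

Blasts are gated CD45-low AND CD66b-low (strict inequalities). Default
thresholds derive from a healthy reference: CD45 at its 35th percentile;
CD66b at the 90th percentile of the *lymphoid* cells (CD45 above its 65th
percentile) — a whole-sample CD66b quantile would sit inside the dominant
granulocyte mode and exclude nothing. Both thresholds are analyst-overridable;
the defaults are declared conventions, not reconstructions. Gated signaling
features take the 90th percentile of the **raw** counts of the gated cells
and arcsinh-transform that one number — deliberately the reverse order of
the clustering pipeline; with a strictly increasing transform both orders
pick the same cell up to interpolation, so patient rankings agree.

Drug plates are normalized per plate to percent inhibition between the
negative (DMSO) and positive (total-kill) control medians — invariant to
affine readout rescaling. DSS is the DSS1-style score: isotonic
(monotone non-decreasing) smoothing of the 5-point inhibition series, then
the trapezoidal area above an activity threshold (t = 10%) over log₁₀
concentration, normalized by (100 − t)·(log-range), clipped to [0, 100];
inhibition outside [−10, 110] is clipped with a log entry. The threshold
and a 4-parameter-logistic alternative are configurable. sDSS subtracts the
mean healthy-donor DSS per drug; top-target tallies take each sample's
top-n drugs by sDSS (ties break lexicographically).

## Synthetic cohorts

The generator draws ten immunophenotypic populations (CD34⁺ blasts ×2,
granulocytes, CD4/CD8 T cells, B cells, NK cells, monocytes, a large dim
myeloid population, stem cells) as Gaussians on the transformed scale,
back-transformed with sinh and floored at zero; zero-inflation is
intensity-dependent (dim channels at the nominal rate, bright channels 10×
rarer — bright channels essentially never read an exact zero). Healthy
material is ~60% granulocytes / 30% lymphocytes / 3% monocytes; patients
have an expanded blast + myeloid compartment with Dirichlet-distributed
per-patient compositions. Batch effects are affine maps on the transformed
scale (slopes 0.85–1.25, offsets 0–0.45, so raw intensities stay
non-negative and quantile equivariance is exact); each batch distorts its
patient samples, its healthy donor, and its aliquot of the shared reference.

Treatment response: each patient is a responder (probability 0.5) whose
target marker (p-ERK1/2) in the responsive populations shifts by
−1.2 ± 0.35 at 24 h, or a non-responder shifting +0.5 ± 0.35; a persistent
patient baseline offset (sd 0.3) sets the within-patient correlation of
signaling across timepoints (exposed as a parameter — its true value is
unknown); per-timepoint jitter (sd 0.15) models sample-handling variation.
The myeloid population carries the response at weight 1; p-p38 co-responds
at weight 0.35; blasts and stem cells respond weakly (0.15) — the emulated
signal is localized to the myeloid compartment. The **latent** value is the
closed-form 90th percentile of the target marker in the target population
at 24 h (jitter included — it is the patient's realized value), and
survival is exponential with hazard `h0·exp(β·z)` on the cohort-standardized
latent (β = 1 per SD by default; median ≈ 600 days at z = 0; administrative
censoring at 5 years). All randomness flows from one integer seed through a
fixed `SeedSequence` spawning order, so outputs are byte-identical per seed.

What the generator does *not* emulate: barcoding chemistry, doublets,
spillover, bead drift, non-affine batch distortions, patient-specific blast
phenotypes, or correlated marker programs beyond the single response axis.
Passing recovery tests therefore show the pipeline correctly inverts the
distortions and rediscoveries the planted signal under these idealized
conditions; they do not certify performance on real acquisitions.

## Problem sizes used in the recovery tests

Survival-parameter recovery runs 10 generator seeds at 64 patients ×
400 cells/sample with SOM training capped at 300 cells/sample; clustering
recovery uses the 32-patient default cohort; the batch-correction
guarantees use 10,001-cell references (grid quantiles on order statistics);
null calibration runs 200 seeds on the generator's patient-level fast path
(the latent *is* the pre-registered causal feature; under β = 0 the
cell-level measurement adds only noise). These sizes are the package's
choices for desk-scale reproducibility; the generator accepts larger ones.

## Known limitations

* The consensus metaclustering assumes the requested k matches the number
  of well-separated populations; with fewer real populations than k, the
  cut splits the loosest population (flagged only by consensus dispersion).
* Quantile standardization assumes the reference spans each channel's
  range and that batch distortions are monotone; composition-dependent
  distortions are outside its model class.
* The 1-SE rule trades sensitivity for stability; with tiny effect sizes
  the final model can be empty even when the outer folds select reliably.
* Selection frequencies treat near-collinear features (a level and its
  ratio) as competitors; which sibling tops can flip between cohorts.
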
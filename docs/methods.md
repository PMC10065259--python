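# Methods

## Scope and design

`momfa` implements a longitudinal multi-omic integration workflow:
simulate (or load) four omic views over a shared mouse × week design,
normalize each view by its modality, match samples into multiomic
profiles, fit a shared-factor decomposition across views, select the
number of factors by an ELBO-ranked ensemble, and relate the selected
factors to genotype group and time. The package is a library first
(`src/momfa`, narrated in `examples/`); the `momfa` CLI is a thin layer
over the same functions for shell-driven runs.

## Synthetic study generator

The generator reproduces the structure of a 30-week dystrophic-mouse
experiment rather than any particular dataset:

* **Design.** 4 groups (WT, mdx, mdx-utrn++, mdx-utrn+-) × 10 mice by
  default (40 mice total); blood sampled at weeks 6, 12, 18, 24, 30;
  muscle only at the sacrifice week (30). The per-group count of 10 is
  a symmetric default — the 40-mouse total is the design anchor, the
  split is configurable. Optional humane-endpoint dropout
  right-censors late weeks (off by default).
* **Cross-view missingness.** Blood volume does not permit both
  RNA-seq and plasma LC-MS on one draw, so each (mouse, week) pair is
  assigned to the blood-RNA arm or the plasma arm
  (`blood_rna_fraction`, default 0.5, Bernoulli per pair). Every pair
  lands in exactly one arm; lipids and metabolites share the plasma
  draw. Which pairs get which assay is not derivable from the study
  description, so it is an explicit free parameter.
* **Latent truth.** Factor scores per (mouse, week) are design-matrix
  effects plus Gaussian residuals. Three presets encode the phenotype
  patterns such studies report: a *disease offset* factor (WT vs
  dystrophic offset plus a week-6 spike), a *growth trend* factor
  (linear in week, all groups, slope 1/6 per week), and an
  *early-disease* factor (week-6 offset in dystrophic groups only — a
  pure interaction).
* **Emissions.** RNA views: per-feature log-rates
  `baseline + (Z Wᵀ)` are renormalized to per-sample proportions
  before the negative-binomial draw (gamma–Poisson, quadratic
  overdispersion 0.05), so library size and composition stay decoupled
  and TMM has something real to correct. Library sizes are LogNormal
  around 2×10⁶ reads. Plasma views: `dilution · exp(baseline + Z Wᵀ +
  noise)` with per-sample LogNormal dilutions (σ = 0.3) — the nuisance
  PQN exists to remove. True scores, loadings, and dilutions are all
  returned for oracle checks.
* **Feature counts.** Lipids default to 524 and metabolites to 106
  features, matching the scale of typical plasma LC-MS panels; RNA
  views default to 3000 genes — large enough that the top-2500
  variance cap binds, small enough for desk-scale runs.
* **What it does not emulate.** Real gene/lipid identities, pathway
  structure, batch effects, and count–abundance covariance beyond the
  shared factors. Tests passing on these data show the pipeline's
  statistical machinery is correct under its own assumptions, not that
  any biological conclusion transfers.

A second generator, `make_gaussian_study`, emits directly Gaussian
views with *exact* per-(view, factor) variance shares. It is the tool
for parameter-recovery experiments, where the question is whether
inference finds a known subspace, not whether normalization works.

## Normalization

* **Low-expression filter**: keep genes with cpm ≥ 5 (raw library
  sizes) in ≥ 10% of samples; the fraction comparison is inclusive.
* **TMM**: reference = sample whose upper-quartile cpm is closest to
  the mean upper-quartile; per sample, M and A values against the
  reference over genes positive in both; rank-trimming of 30% (M) and
  5% (A) tails; factor = 2^(precision-weighted mean of surviving M)
  with delta-method binomial weights; factors rescaled to geometric
  mean 1. This matches edgeR's `calcNormFactors(method="TMM")` to
  ~1e-8 (asserted in the tests against edgeR via Rscript).
* **cpm**: counts / (library × factor) × 10⁶, then log2(cpm + 1). The
  log is configurable off, but variance ranking on raw cpm is
  dominated by the most abundant genes, so it defaults on.
* **PQN**: reference spectrum = feature-wise median across samples
  (mean available); dilution = median quotient over positive-reference
  features; output = sample / dilution, then log2(x + 1).
* **Variance cap and scaling**: RNA views are reduced to their
  top-2500-variance genes (ties broken by feature ID) so the
  low-dimensional LC-MS views are not swamped; all views are then
  centered per feature and scaled to unit sample variance
  (zero-variance features dropped with a warning). Centering is
  required by a factor model without intercepts, and unit scaling puts
  counts and abundances on one footing.

## Profile matching

Profiles are (mouse, group, week) keys; the profile index is the union
of keys over all views, sorted by mouse then week. A view's missing
profiles are NaN columns with an explicit observed mask — no
imputation before modelling. Keys carrying several samples in one view
are averaged per feature (normalized data only; averaging raw counts
would corrupt library sizes), and matching performs the same averaging
internally, so matching and averaging commute.

## Factor model and inference

Bayesian group factor analysis with Gaussian likelihood per view over
observed entries only, standard-normal prior on scores, per-(view,
factor) ARD-scaled normal prior on loadings, and Gamma(10⁻³, 10⁻³)
priors on ARD and noise precisions. Inference is coordinate-ascent
mean-field VB cycling (Z, W, α, τ). Implementation choices:

* **Initialization**: Z from the SVD of the row-concatenated views
  (missing entries zeroed), rescaled and perturbed by seed-dependent
  N(0, 0.1²) noise. The non-convexity the ensemble protocol exploits
  enters exclusively through this seed.
* **Missingness**: whole-view-per-profile masks are exploited by
  grouping profiles with the same observation pattern (one Z posterior
  covariance per pattern).
* **Pruning**: every 5 iterations after a 10-iteration burn-in, any
  factor whose variance-explained fraction (posterior means) is below
  the threshold in *all* views is dropped — a factor surviving in one
  view survives, so view-specific factors are kept. The last remaining
  factor is never pruned: a zero-factor model is not a useful fit, and
  ARD already drives a redundant final factor's loadings to zero, so
  pure-noise data end at k_active ≤ 1 with R² ≈ 0.
* **ELBO trace and pruning**: each full update cycle provably does not
  decrease the ELBO at fixed dimension, but removing a factor changes
  the model, so the bound jumps. `elbo_trace` therefore holds the
  trace since the last pruning event (monotone by construction, slack
  1e-6 for floating point); `elbo_history` keeps the full history.
  Only ELBO comparisons *within equal factor counts on the same data*
  are meaningful, which is exactly how model selection uses them.
* **Convergence**: relative ELBO change < tol (default 1e-6) on two
  consecutive iterations, max 2000 iterations.
* **Identification**: factors ordered by total variance explained
  (descending); signs fixed so each factor's largest-|loading| feature
  is positive. Quality metrics are invariant to the remaining
  permutation/sign ambiguity, and recovery tests match factors
  greedily by |Pearson r|.
* **Variance explained**: per-factor R²(m, k) = 1 − Σ_obs(Y_m − z_k
  w_mkᵀ)² / Σ_obs Y_m², clipped to [0, 1]; per-view totals from the
  full reconstruction (not the per-factor sum, which only coincides
  under orthogonality); the overall total weights views by observed
  entry counts.

Identifiability caveat: factors with identical activity profiles
across views are only identified up to rotation (as in any Gaussian
factor model); distinct per-view variance shares — the typical
situation in multi-omic data, where each factor dominates somewhere —
pin the axes down, and the recovery experiments use such structure.

## Model selection

The grid is thresholds × seeds (defaults: 8 thresholds evenly spaced
on [0.02, 0.20] — the stated range, with even spacing as the concrete
choice — and 100 seeds each, i.e. 800 fits). Seeds follow
`base + 10⁴·threshold_index + rep`, so per-threshold streams never
collide. Fits are grouped by their converged factor count; the
highest-ELBO fit per count wins (ties to the smallest seed); the
variance-explained curve over the winners is cut by an elbow rule —
the smallest K whose gain in overall R² to the next candidate is below
`elbow_delta` (default 0.01 absolute). The reference protocol's visual
elbow choice is reproducible as an explicit `k_override`; both paths
log their decision. Failed fits are recorded with their error, never
silently dropped.

## Association

Per factor, three least-squares models on the profile scores: group
only, week only, and the saturated group×week cell-means model (equal
to main effects + interaction with both factors categorical), each
reported as R²; overall F-tests of the two one-way models, computed by
sums of squares (cross-checked against statsmodels OLS in the tests).
BH adjustment runs across the K factors, separately for the group
family and the week family. Post-hoc pairwise contrasts (6 group
pairs, 10 week pairs) use pooled-variance t statistics from the
one-way fit, Welch by flag, BH-adjusted within each (factor, family).
Conventions: a constant factor reports R² = 0, p = 1 (least squares is
undefined); p-values are floored at 1e-300 so perfect separation
cannot overflow; levels with fewer than 2 profiles flag the test or
skip the pair. Loading summaries rank by |loading| with ties broken by
feature ID; the loading-magnitude threshold (default 2, strict
inequality) applies to loadings fitted on unit-variance data and is
exposed as a parameter; cross-view loading comparison inner-joins by
feature ID (≥ 3 shared required) and reports Pearson correlation plus
sign consistency.

## Problem sizes used in the automated checks

The acceptance checks run the full 8×100 grid on a 20-profile,
4-view, 50-features-per-view set (the grid's cardinality and factor
count range are what is under test, not large-data behaviour); factor
recovery uses 20 replicate studies of 100 profiles with 4 true factors
whose per-view shares all exceed 10%; the end-to-end check runs the
default 40-mouse study with 3000-gene RNA views through the complete
pipeline with a 2-threshold × 3-seed grid. These sizes were chosen so
the whole suite completes in minutes while still exercising every code
path at realistic shape ratios (features ≫ profiles in RNA views,
views with disjoint observation patterns).

## Known limitations

* Gaussian likelihoods only; counts are made Gaussian-like by
  normalization and scaling rather than modelled natively.
* ARD is per (view, factor) — no spike-and-slab sparsity within a
  loading column.
* The elbow rule is a heuristic; the curve and override exist because
  no automatic rule matches a judgment call in every case.
* ELBO values are implementation-specific (they depend on priors and
  convergence settings); only their ranking within equal factor counts
  on identical data carries meaning.
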
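# Methods

## Pipeline overview

`rmkllpp` implements similarity-based multi-omics integration for cancer
subtyping: per-layer preprocessing → per-layer Gaussian kernels → joint
embedding by multiple-kernel locality preserving projections → k-means
subtyping with silhouette model selection → survival-based subtype merging
→ prognostic evaluation. The sections below state the model, the
conventions chosen where the procedure is underdetermined, and what the
synthetic cohorts do and do not establish.

## Preprocessing

Per layer (features × samples):

1. **Missingness filter.** A feature is dropped when its missing fraction
   is *strictly greater* than `max_missing_rate` (default 0.30); exactly
   30% missing survives. The strict reading is asserted in tests so the
   boundary is auditable.
2. **KNN imputation.** Missing entries are replaced by the unweighted mean
   of the k nearest *features* (rows; k default 10), nearness by Euclidean
   distance over the columns observed in both features — the canonical
   orientation for expression-matrix imputation. Delegated to
   scikit-learn's `KNNImputer`; observed cells are never modified.
3. **log2(x+1)** for count-like layers (expression, miRNA).
4. **Annotation filter** for methylation arrays: keep CpGs with
   |distance to TSS| ≤ 2000 bp (inclusive) and chromosome not in
   {chrX, chrY}; unannotated features are dropped with a logged count.

Samples are aligned across layers by id intersection in lexicographic
order.

## Kernels

Each layer yields one Gaussian kernel per bandwidth factor (default
0.5, 1, 2) around the median heuristic `γ₀ = 1 / (2 d̃²)`, `d̃` the median
pairwise Euclidean distance — so M = 3 × (number of layers) by default,
and the kernel weights can select the relevant scale per data type.

Kernels are conditioned by **cosine normalization only** (unit diagonal;
a no-op for Gaussian kernels). Double-centering in feature space is
implemented (`center_and_normalize`) but not the default: centering makes
every kernel singular, and the composite kernel's null space then enters
the bottom generalized eigenpairs of the embedding step as full-amplitude
noise directions. On reference cohorts this cut recovery from ARI 1.0 to
≈ 0.7 and broke cluster-number selection, so the strictly-positive-definite
conditioning is the default and centering is an option
(`conditioning="center"`).

## The embedding: multi-kernel LPP

With `κ_i` the N×M matrix of kernel column slices, sample i embeds as
`Aᵀκ_iβ`. The locality preserving objective over the symmetrized 9-nearest
neighbor graph (edge when either endpoint lists the other; distances are
kernel-induced `d²(i,j) = K(i,i)+K(j,j)−2K(i,j)` under the uniform-weight
composite) is minimized by coordinate descent:

* **A-step** — generalized eigenproblem: the columns of A are the
  eigenvectors of `(S_W, S_D + rI)` with the P smallest eigenvalues,
  `S_W = 2 U L Uᵀ`, `S_D = U D Uᵀ`, normalized so `Aᵀ(S_D + rI)A = I`,
  with a deterministic sign convention (largest-magnitude entry positive).
* **β-step** — minimize `βᵀS_W^Aβ / βᵀS_D^Aβ` over the probability
  simplex (scale-invariance makes the simplex parameterization lossless).
  The subproblem is nonconvex; it is solved by SLSQP from several starts
  (incumbent, uniform, near-vertices, plus a dense grid for M ≤ 3) keeping
  the best, with the incumbent as fallback.

**Regularization.** The ridge is *relative* to the constraint-matrix
scale: the constraint is `S_D + ridge·(tr(S_D)/N)·I`, ridge default 1e-3,
escalated ×10 on eigensolver failure. This serves the regularizer's
purpose of preventing overfitting in a scale-free way: directions in the
composite kernel's near-null space — which would otherwise be amplified to
full embedding amplitude by the constraint normalization while carrying no
locality information — are shrunk to near-zero amplitude, so surplus
embedding dimensions beyond the intrinsic cluster structure become
harmless for k-means and silhouette.

**Monotone alternation.** The recorded objective is
`tr(AᵀS_W A) / tr(Aᵀ(S_D+rI)A)` — the mean of the P smallest generalized
eigenvalues — evaluated after each A-step. The two half-steps optimize
differently normalized criteria (per-column eigen-constraint vs trace
ratio), so no scalar is decreased by both in general; the fit therefore
accepts a β proposal only if the subsequent A-step objective does not
increase, backtracking along the segment toward the incumbent when the
full step overshoots. The objective is multimodal in β (each sufficiently
expressive kernel supports a low-objective basin), and mixtures can sit on
ridges between basins; when no damped step descends, the simplex vertices
are probed and the best strict improvement accepted. The result: the
objective trace is non-increasing by construction, and convergence
(relative change < 1e-6, or no descending move) typically takes 4–6
alternations.

Initialization follows the stated scheme: `A_first` starts from uniform β;
`beta_first` runs a weight step under `AAᵀ = I` first. The neighbor graph
is built once from the uniform-weight composite kernel and held fixed;
rebuilding per iteration is exposed (`rebuild_graph=True`, off by default)
but makes objectives across iterations incomparable.

P defaults to 5 and k to 9 neighbors. Out-of-sample projection is not
supported; `transform` re-embeds the training kernels.

**A caveat on β as an importance measure.** β concentrates on kernels
whose geometry most cheaply expresses functions smooth over the (fixed)
neighbor graph. Since the graph itself is informative-layer-driven, the
embedding recovers the planted subtypes even in the occasional run where a
very wide noise-layer kernel wins the objective; β dominance of the
informative layer holds in ~9/10 reference-cohort runs, not all.

## Subtyping and merging

k-means (k-means++, best of 50 restarts, one deterministic RNG stream per
k) over k ∈ [2, 10]; the selected k maximizes the mean silhouette
coefficient in the embedding (Euclidean), ties toward smaller k.

Published analyses of this kind merge clusters after visual inspection of
their survival curves; `rmkllpp` formalizes that step reproducibly: all
pairwise log-rank tests among the initial clusters, an edge for every pair
with p > α (default 0.05), merged subtypes = connected components,
renumbered by ascending Kaplan–Meier 3-year mortality (label 1 = best
prognosis). Clusters with fewer than 2 samples are attached to the
component with the nearest 3-year mortality, with a warning. Merging is
optional (`merge: false`) and the merge map is recorded in the run log.

## Survival evaluation

Kaplan–Meier product-limit curves per subtype; mortality at a horizon is
`100·(1 − S(t))` with the 3-year horizon at 3 × 365.25 days. Group
differences use the unweighted log-rank test (G−1 df). The Cox model
(lifelines, Efron ties) adjusts the subtype contrast for age, gender and
pathologic stage, with treatment coding against reference levels female
and Stage I (both configurable). Reported per term: coefficient, SE,
Wald Z = coef/SE, p, HR = exp(coef), and 95% CI = exp(coef ± 1.96·SE) —
the normal-approximation arithmetic used in published tables, which the
acceptance script verifies against printed values.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, at
desk scale: multiple layers on shared samples, a latent subtype partition,
MCAR missingness, and subtype-dependent exponential survival with
independent censoring.

* **Planted signal.** Informative feature f shifts the mean of subtype
  (f mod S) by `effect_size` latent standard deviations; other features
  are exchangeable noise. The shifted-vs-rest standardized mean difference
  therefore recovers `effect_size`, which tests re-estimate from the
  generated matrices.
* **Value models.** Expression: log-normal counts `exp(base + signal)`
  (kernels, not count likelihoods, consume the data downstream, so a
  negative-binomial model would add nothing testable); methylation:
  Gaussian on the logit scale through the inverse logit, keeping values in
  (0,1); `gaussian` emits the latent signal directly.
* **Censoring** is exponential with its rate solved in closed form so the
  expected censored fraction matches the request.
* **Determinism.** One cohort seed expands into per-layer substreams
  (`SeedSequence`), so adding a layer never perturbs earlier layers.

The **reference cohort** used by tests and the acceptance script has
n = 150, three equal subtypes, one informative mRNA-like layer
(400 features, 80 informative, effect size 2.5), an uninformative
miRNA-like layer (100 features) and an uninformative methylation layer
(400 CpGs), 2% missingness, 30% censoring, and survival following the
null-groups-plus-one-high-risk pattern (log-HR 0, 0, 1.5) so that merging
collapses the null pair. These sizes keep a full 10-replicate pipeline
evaluation under a minute while leaving all statistics comfortably
powered.

What passing on these cohorts does **not** show: robustness to batch
effects, non-MCAR missingness, heavy-tailed count noise, correlated
features, or cluster structure weaker than the planted separation — real
TCGA-scale matrices (tens of thousands of features, hundreds of patients)
share none of the generator's independence assumptions. The synthetic
results validate the machinery, not the biology.

## Numerical choices and degenerate inputs

* Kernel symmetry is enforced (`(K+Kᵀ)/2`) after construction; kernel-set
  validation rejects asymmetry beyond 1e-10.
* k-NN ties break by sample index (stable argsort); eigenvector signs are
  fixed deterministically; k-means uses a fixed stream per k — full runs
  are bit-reproducible given config + seed.
* Degenerate inputs fail loudly: all-identical samples (median distance
  0), all-features-dropped, features with no observed values, degenerate
  β-step (`S_D^A = 0`), non-finite objectives (with the iteration index).
* A horizon beyond the last observed time evaluates the KM curve at the
  last time with a logged caveat.

## Limitations

* The β-step is a nonconvex trace-ratio program; the multi-start SLSQP +
  vertex-probe scheme gives no global-optimality guarantee (the M = 2 case
  is verified against a dense grid in the acceptance suite).
* The merging rule's connected components can chain: A~B and B~C merge
  {A,B,C} even if A and C differ pairwise. This mirrors the manual
  curve-inspection practice it formalizes but is order-free rather than
  hierarchical.
* No out-of-sample embedding, no consensus clustering, no competing risks
  or time-varying covariates.
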
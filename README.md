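# rmkllpp

Multi-omics cancer subtyping with regularized multiple-kernel learning and
locality preserving projections (rMKL-LPP).

Molecular subtypes of a tumor — groups of patients with shared genomic
disorders and distinct prognosis — are rarely visible in a single data
type. `rmkllpp` integrates several omics layers observed on the same
patients (mRNA expression, miRNA expression, DNA methylation) into one
low-dimensional embedding, clusters that embedding into candidate
subtypes, collapses clusters whose survival is statistically
indistinguishable, and quantifies the prognostic value of the final
subtypes with Kaplan–Meier curves, log-rank tests and covariate-adjusted
Cox regression. A synthetic-cohort generator with planted subtypes and
subtype-dependent hazards makes every stage testable without access to a
real cohort.

## The model

Each omics layer contributes Gaussian kernels
`K_m(i, j) = exp(-γ ||x_i - x_j||²)` at several bandwidths around the
median heuristic. With `κ_i` the N×M matrix stacking column `i` of every
kernel, a sample is embedded as `Aᵀ κ_i β`, where the projection
`A ∈ R^{N×P}` and the simplex-constrained kernel weights `β`
(`Σβ_m = 1, β_m ≥ 0`) jointly minimize the locality preserving criterion

```
min_{A,β}  Σ_ij w_ij ‖Aᵀκ_iβ − Aᵀκ_jβ‖²   s.t.  Σ_i d_ii ‖Aᵀκ_iβ‖² = 1
```

over the symmetrized k-nearest-neighbor graph `W` (degree matrix `D`).
Writing `U(β) = Σ_m β_m K_m` and `L = D − W`, the `A`-step is a
generalized eigenproblem on `(2 U L Uᵀ, U D Uᵀ + r I)` and the `β`-step a
quadratic ratio over the simplex; the two are alternated until the
normalized objective stabilizes. The ridge `r` regularizes the constraint
matrix and suppresses embedding directions without support in the
composite kernel. Subtypes come from k-means on the embedding with the
cluster number chosen by the mean silhouette coefficient; clusters whose
pairwise log-rank tests are non-significant are merged (connected
components), and the merged subtypes are evaluated with Kaplan–Meier
3-year mortality, the log-rank test and a Cox model adjusted for age,
gender and pathologic stage.

## Worked example

Simulate a 150-patient cohort (three equal subtypes; one informative
expression layer, two uninformative layers; two subtypes share the
baseline hazard, the third carries log-HR 1.5) and run the full pipeline:

```
$ rmkllpp simulate --seed 7 --out demo/cohort
$ cat > demo/config.yaml <<EOF
layers:
  mrna: demo/cohort/mrna.tsv
  mirna: demo/cohort/mirna.tsv
  methylation: demo/cohort/methylation.tsv
clinical: demo/cohort/clinical.tsv
log_transform_layers: [mrna, mirna]
k_range: [2, 8]
seed: 7
out_dir: demo/run
EOF
$ rmkllpp run --config demo/config.yaml
run complete: demo/run
```

`demo/run/run_log.json` records the fit: silhouette selects k = 3, the
kernel weights put all mass on the informative mRNA layer
(`beta = [1.0, 0, 0, ...]`), and survival-based merging collapses the two
baseline-hazard clusters (`merge: {1: 1, 2: 2, 3: 1}`), leaving two final
subtypes whose survival differs at log-rank χ² = 50.5, p = 1.2e-12.
`subtype_survival_summary.tsv` shows the prognosis gap:

```
subtype  n    events  mortality_3yr_pct
1        100  56      51.1
2        50   46      92.7
```

and `cox_summary.tsv` reports the adjusted hazard ratio of the high-risk
subtype (here HR 4.29, 95% CI 2.77–6.65, against a planted hazard ratio of
exp(1.5) ≈ 4.48). The same stages are available individually
(`rmkllpp preprocess / kernels / fit / cluster / evaluate`) and as library
calls (`MKLLPP`, `SilhouetteKMeans`, `merge_subtypes_by_survival`).

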
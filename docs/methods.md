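# Methods

## Model

`hirrm` implements a two-hierarchy analysis of longitudinal phenotypes.

**First hierarchy.** For individual *i* with measurements *y<sub>i</sub>* at
ages *t<sub>i</sub>*,

  y_i(t) = f(θ_i, t) + e_i,  e_i ~ N(0, σ²_e I),

where *f* is a growth function (Richards, Bertalanffy, Gompertz, Logistic,
or a normalized Legendre polynomial) and θ_i its parameter vector.  θ̂_i is
the (non)linear least-squares estimate; the analysis assumes individuals
have enough measurements for this to be well posed and drops (with a log
note) the rare individual whose fit does not converge.  Prediction of
parameters for sparsely measured individuals is deliberately out of scope.

**Second hierarchy.** The matrix P of fitted parameters is modelled as

  P = XB + G + E,  G ~ MN(0, V_g, K),  E ~ MN(0, V_pe, I_n),

i.e. vec-covariances V_g ⊗ K and V_pe ⊗ I.  K is the standardized genomic
relationship matrix W W′/m.  V_pe absorbs both true permanent-environmental
effects and the stage-1 estimation error of θ̂, which is iid across
individuals; nothing in the pipeline tries to separate the two.

Marker tests use the canonical transform L (simultaneous diagonalization of
V_pe and V_g) followed by per-pseudo-trait EMMAX whitening; the summed
per-trait χ² is referred to χ²_d.  The identity of the summed statistic
with the full multivariate GLS Wald statistic (V = S_λ ⊗ K + I) is exact
and is asserted in the tests to 1e-6 on small fixtures.

## Estimation choices

* **REML.** The rotated likelihood (rows independent after multiplying by
  U_k′) is maximized over Cholesky-parameterized (V_g, V_pe) with
  log-diagonals, which enforces positive semidefiniteness without
  constraints.  A 5-step EM warm start precedes L-BFGS-B with an analytic
  gradient; convergence requires the quasi-Newton success flag plus a
  gradient max-norm below 1e-2 (one polishing restart otherwise); the
  iteration cap is 500.  Standard deviations of every element come from the
  inverse observed information, computed by central differences of the
  analytic gradient on the (vech V_g, vech V_pe) scale with steps scaled to
  the per-trait units (flat steps lose positive-definiteness when trait
  scales differ by orders of magnitude).  Wald tests are one-sided for
  variances, two-sided for covariances.
* **Canonical transform.** s_λ is returned descending and each row of L is
  signed so its largest entry is positive — eigenvectors are otherwise
  sign-ambiguous and output would not be reproducible.  A non-PD V_pe is
  ridged by 1e-8·trace/d; a condition number beyond 1e12 after repair is an
  error naming the offending eigenvalue.
* **EMMAX with candidate exclusion.**  The whitened residual variance is
  fixed at 1 — the EMMAX convention; only the refinement pass re-estimates
  variance ratios.  A marker that itself contributes to K is partly
  corrected away by the polygenic term; with n/m ≈ 0.25 this deflates χ²
  by ~10% (λ_GC ≈ 0.90).  The scan therefore downdates K by the candidate's
  own column (Sherman–Morrison, O(n) per marker), restoring λ_GC ≈ 0.98,
  and does so only when the supplied kinship verifiably equals the panel's
  standardized cross-product.  Chromosome-level (LOCO) exclusion was
  rejected: under a polygenic architecture in which every marker carries a
  small effect, removing a whole chromosome uncovers genuine local signal
  and inflates λ far above 1.  `exclude_candidate=False` restores the plain
  EMMAX statistic, which equals brute-force GLS with the genome-wide K.
* **Refinement.**  Markers with first-pass p < 1e-4 or in the top 0.1%
  (configurable) are re-tested exactly: per pseudo-trait, the variance
  ratio is re-estimated by univariate REML with the marker as a fixed
  covariate, warm-started at the genome-wide s_λ.  At most one refinement
  pass runs (two EMMAX rounds total); non-convergence keeps the first-pass
  statistic with a flag; identical genotype columns share a cached result.
* **Curve fitting.**  Starts follow standard self-starting heuristics
  (a₀ = 1.05·max y; r₀ from a log-linear regression of log(a₀ − y) on t;
  b₀ from the first observation).  The Richards family additionally uses a
  four-point multi-start over the shape parameter spanning both k branches,
  because its b–k ridge produces local optima; k is excluded from
  (1 − 1e-4, 1 + 1e-4), with Gompertz available as the exact k → 1 family.
  Reported criteria: residual variance RSS/(n − d) (unbiased under the
  linearized model), R² = 1 − RSS/TSS, AIC = n ln(RSS/n) + 2(d + 1) and
  BIC = n ln(RSS/n) + (d + 1) ln n, counting σ² as a parameter.  BIC ties
  rank the smaller family first.
* **Genotypes.**  PLINK bed/bim/fam I/O is implemented directly (2-bit
  SNP-major codec).  QC defaults: MAF ≥ 0.01, missingness ≤ 0.1; missing
  calls are mean-imputed per marker before standardization; the GRM is bent
  to PSD by flooring eigenvalues at zero.  Effects are reported per copy of
  the counted (A1) allele; genotypes are centred but not standardized for
  testing, so effect sizes stay on the per-allele scale.
* **Thresholds.**  Bonferroni only: −log10(α/m).  −log10 p is computed on
  the log scale and capped at 320.  Genomic control is the median of the
  summed statistic over the χ²_d median.

## The synthetic-data generator

The generator emulates a dense-panel longitudinal GWAS: haplotype-copying
genotypes (allele frequencies U(0.05, 0.5); within a block each haplotype
allele copies its left neighbour with probability 0.9, so LD decays
geometrically; blocks of 20 markers, independent across blocks, 10
chromosomes with evenly spaced positions), QTLs placed uniformly among the
markers, and an infinitesimal polygenic background (iid effects on every
marker through the standardized panel, giving exactly MN(0, (1−f)V_g, K)
conditional on the realized panel).  Defaults: permanent-environmental
variances 4.0, all effect correlations 0.5, regression heritability 0.5
(hence genetic regression variances 4.0), QTL share f = 0.3 of the genetic
variance split equally among QTLs, 16 time points, measurement-error
variance 4.0.

**Parameter map.**  The stated covariances are drawn on a standardized
regression scale and mapped to natural curve parameters by a linear map S.
Applied directly in natural units, a variance of 4.0 on an intrinsic growth
rate of ~0.2 per week produces divergent trajectories; and any mapping that
shrinks the deviations far below the stage-1 sampling error of the curve
fit would make the second-hierarchy covariances unrecoverable in principle.
The default therefore whitens by the curve's information: S = c (J′J)^{−1/2}
with J the Jacobian of the population curve on the time grid and c² = 50,
so each regression trait is measured by stage 1 with error variance
σ²_e/c² = 0.08 — two percent of the permanent-environmental variance, the
dense-measurement regime in which a two-stage analysis is the appropriate
tool.  The default population curve is a large-phenotype (maize-like)
Richards/Bertalanffy curve (a = 220), which keeps the implied natural-scale
deviations biologically moderate (±12% on r).  For the four-parameter
Richards family, whose b–k direction is nearly unidentifiable, equal-
information whitening would demand deviations outside the curve's domain;
the map then falls back to a bounded diagonal form with 3σ deviations
capped at 25% of each population coefficient.  A user-supplied
`parameter_map` (e.g. diagonal) overrides all of this, and is what the
tests use to plant effects on a single named parameter.

**What passing tests do and do not show.**  The generator reproduces the
covariance structure, LD, and measurement error of the stated design, but
not selection, shared environment, genotype-age interaction beyond the
curve family, missing visits, or measurement error that grows with size —
so recovery of (V_g, V_pe) here demonstrates correctness of the estimator
under its own model, not robustness to real-data violations.  Stage-1
error (~0.1 in regression units, individual-Jacobian variation included)
is absorbed into V_pe, so estimated V_pe sits 1–3% above the generative
4.0 by construction; this is a property of the two-stage method, visible
in the recovery study, and within its Monte-Carlo resolution.

**QTL calling and power.**  A marker is called a QTL when it passes the
significance threshold and carries the largest summed statistic among its
20 closest positional neighbours (10 each side, truncated at chromosome
ends; plateau ties go to the leftmost marker).  A simulated QTL counts as
identified when a called marker falls inside its own 20-neighbour window;
type-I error is the called fraction of markers outside every QTL window.
`replicate_recovery_study` exposes replicate orchestration (50 replicates
being a conventional full-study count); the shipped recovery study runs 20
replicates of 500 × 2,000, a size chosen to keep the whole pipeline
re-runnable on a laptop in about a minute.

## Numerical notes and limitations

* Exact Richards evaluation raises on a non-positive base 1 + b e^{−rt};
  the fitting residual clamps the base instead, so the optimizer can pass
  through infeasible iterates.
* Eigen-decompositions are cached on the `Kinship` object; reconstruction
  error is asserted below 1e-8 in the tests.
* A kinship eigenvalue spread below 0.05 triggers a warning: V_g and V_pe
  are then nearly confounded.
* REML standard errors are unavailable (with a warning) when the observed
  information is singular — typical when a variance sits on the boundary.
* The univariate refinement REML optimizes the ratio on a log grid
  followed by bounded scalar minimization in [1e-5, 1e5].
* λ_GC is defined only for ≥ 100 markers; the scan reports NaN below that.
* FDR control, sex-stratified curve fitting, and non-linear mixed-model
  (random-coefficient) stage-1 estimation are intentionally not provided.
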
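# Methods

## Model and estimator

The trait model is the standard two-variance-component GREML linear mixed
model: Y ~ N(Xβ, σ_h²A + σ_e²I) with A the GRM from column-standardized
genotypes and h² = σ_h²/(σ_h²+σ_e²). The package's estimator replaces A with
the knot-anchored low-rank-plus-diagonal surrogate

    Ã = A_BI A_II⁻¹ A_IB + diag(A − A_BI A_II⁻¹ A_IB),

i.e. the best rank-r predictor of every GRM entry from the knot individuals,
with the Schur-complement diagonal restored so that Ã matches A exactly on
the diagonal and on the knot×knot block (and everywhere when r = N).

### Likelihood evaluation

With Ã = UUᵀ + diag(d), U = A_BI R⁻¹ (A_II = RᵀR by Cholesky), the model
covariance is V = Δ + U_c U_cᵀ, Δ = σ_h² diag(d) + σ_e² I, U_c = σ_h^{1/2} U.
Solves use the Woodbury identity with the r×r capacitance
C = I + U_cᵀ Δ⁻¹ U_c; the determinant uses log|V| = log|C| + Σᵢ log Δᵢᵢ.
One evaluation costs O(Nr² + r³ + Np²) and O(Nr) memory; nothing N×N is
formed. REML adds the standard −½ log|XᵀV⁻¹X| adjustment (the |XᵀX| constant
is omitted — it cancels in all comparisons and matches the dense evaluator
used as oracle).

### Optimization

h² is the only free shape parameter: the total variance σ_p² = σ_h² + σ_e²
is profiled in closed form (σ̂_p² = rᵀK⁻¹r / df with K = h²Ã + (1−h²)I,
df = N−p for REML, N for ML) and β by GLS. The profile likelihood is
maximized by bounded Brent search on h² ∈ [0, 1] (`scipy`'s bounded
`minimize_scalar`), tolerance 1e-6 on h², at most 200 evaluations. The upper
bound is kept 1e-9 inside 1.0 because Δ is exactly singular at h² = 1 at the
knots (d = 0 there). Defaults: REML on, an intercept always included,
covariates appended. Estimates within 1e-3 of a bound are flagged
`boundary_flag`; a profile that is constant to 1e-8 relative (e.g. A = I,
where the two components are unidentifiable) raises a flat-likelihood
warning and flag. Fits never error at a boundary — the estimate is reported.

### Degenerate inputs and numerical guards

- A_II Cholesky uses a jitter ladder 0, 1e-10, …, 1e-4 (near-duplicate knot
  individuals make A_II singular); failure at 1e-4 raises with advice to
  change the knot set.
- Negative entries of d (round-off when A is only numerically PSD) are
  clipped to 0 and counted (`n_clipped`); d is forced to exactly 0 at knots.
- Dense GREML clips negative GRM eigenvalues at 0 and is guarded at
  N = 10,000 by default — beyond that is the regime the approximation
  exists for.
- Monomorphic variants are flagged and excluded from standardization, never
  zero-divided; missing genotypes are mean-imputed (contributing exactly 0
  to standardized columns) with a fixed divide-by-M_used denominator, so the
  streamed blocks agree with the dense GRM to 1e-10.

### Standard error

The reported SE inverts the 2×2 expected Fisher information of
(σ_h², σ_e²), I_jk = ½ tr(P V_j P V_k) with V_1 = Ã, V_2 = I and P the
(RE)ML projection, then delta-methods to h². All traces are assembled from
diagonal-plus-low-rank products in O(N(r+p)²); the algebra is verified in
the tests to reproduce the dense-matrix Fisher computation to machine
precision, and validated against finite-difference Hessians of the dense
restricted likelihood (averaged over phenotype draws at the fitted
parameters, since a single realization's observed information scatters
10–50% around its expectation at N = 300). The SE is approximate in the
usual asymptotic sense and is not reported at boundary or flat fits.

## Knot selection

Two designs: uniform random sub-sampling, and row-sum ordering (knots = the
r individuals with the largest GRM row sums, computed in O(NM) without
forming A; ties broken by ascending index for determinism). Row-sum knots
favor individuals sharing the most relatedness with the rest of the cohort,
which is what the low-rank term needs to predict the unselected block.
Random knots are robust in strongly tree-structured cohorts where any
sub-sample spans all blocks. No automatic choice of r is attempted: the
approximation improves monotonically in r but the cost is cubic, and the
trade-off is the user's.

## Synthetic data

The generator emulates a four-generation coalescent hierarchy: one
ancestral allele frequency per SNP ~ U(0.1, 0.9) drifts down a binary tree
(1 → 2 → 4 lineages) by Balding–Nichols steps — child ~ Beta(p(1−θ)/θ,
(1−p)(1−θ)/θ), so E = p and Var = θp(1−p) — with drift θ = 0.05; each
individual then draws a personal frequency around its subpopulation value
and genotypes Bin(2, p) under Hardy–Weinberg. Defaults (θ = 0.05, four
equal subpopulations, frequencies on [0.1, 0.9]) are the study conditions
used throughout the tests. The tree depth is configurable; subpopulation
count is 2^(generations−2).

Phenotypes:

- **Causal-SNP model.** m_causal variants (drawn from the
  polymorphic/retained set) get effects u_m ~ N(0, h²/m_causal) on
  *standardized* columns — on raw allele counts the stated effect variance
  would not produce genetic variance h². The residual is iid with
  σ_e² = var̂(g)·(1/h² − 1), anchored to the realized genetic variance so
  the realized heritability is exactly h²; the fixed alternative
  σ_e² = 1/h² − 1 is available (`literal_residual=True`) but is exact only
  when var(g) = h², which population structure violates (the Wahlund effect
  inflates the GRM diagonal, and var(g) with it, by ~10% at these settings).
- **GRM-Gaussian model.** Y ~ N(0, c·(h²A + (1−h²)I)) drawn exactly by
  Cholesky (dense A) or from the low-rank structure (when only a PP factor
  exists — then the generative covariance is the approximation itself and
  is labeled as such). The scale c cancels in h² and defaults to 1.

What the generator does *not* emulate: linkage disequilibrium beyond the
correlation the tree induces, minor-allele-frequency spectra from real
ascertainment, genotyping error/missingness patterns, and non-Gaussian or
binary traits. Passing recovery tests on these data therefore demonstrates
correctness of the estimator under its own model assumptions, not
robustness to real-data artifacts.

## Replication experiments and problem sizes

The experiment driver reports per-replication estimates plus empirical
bias, variance and RMSE = sqrt(bias² + variance). The causal-SNP study
redraws genotypes every replication; the GRM-Gaussian study draws one
genotype set, fixes its GRM, and redraws phenotypes — mirroring a fixed
real cohort. Sub-sample GREML is always evaluated on exactly the PredLMM
knot set (its likelihood sees only A_II), isolating the value of the
cross-block A_BI.

The shipped validation runs use deliberately desk-scale sizes chosen to
keep the full suite in minutes on one CPU while preserving the qualitative
regime (knots at 10–25% of N, SNPs at twice N): the causal-SNP design at
N = 1000, M = 2000, r = 250, truths {0.2, 0.8}; the GRM-Gaussian design at
N = 2000, M = 4000, r = 200, truth 0.4; 50 replications each, per-replication
seeds spawned deterministically from one base seed. At these sizes the mean
estimate recovers the generative truth within ±0.05 and the predictive
process beats sub-sample GREML on RMSE at matched r, with most of the gap
coming from variance — the orderings that motivate the method. A mild
attenuation (−0.01 to −0.03) of the predictive-process mean is visible at
high h²; it shrinks with M/N (GRM noise) and with r, and is absent from the
dense-GREML control, i.e. it is the approximation error of Ã at these small
scales, not an estimator defect.

## Design choices that were genuinely open

- **Parameterization.** Optimizing (h², σ_p²) with σ_p² profiled, rather
  than (σ_h², σ_e²) jointly, reduces the search to one bounded dimension and
  keeps the estimate in [0, 1] by construction.
- **GRM convention.** Allele-frequency standardization sqrt(2p̂(1−p̂)) and a
  single divide-by-M (GCTA convention), not per-pair missingness
  denominators; per-SNP weights fold in as A = (Σd_j)⁻¹ Σ d_j w̃_j w̃_jᵀ,
  preserving E[diag] ≈ 1. The weight hook accepts externally computed (e.g.
  LD-based) weights; estimating them is out of scope.
- **Fixed effects** are profiled by GLS, mathematically equivalent at the
  optimum to joint estimation.
- **Missing phenotypes/covariates** are handled by complete-case filtering
  in the CLI (knots are selected among complete cases).
- **Causal SNPs** are drawn from the same pool used for the GRM (the GRM is
  not pruned of causal variants).

## Known limitations

Single genetic variance component (no partitioned heritability); quantitative
traits only; PLINK 1 hard calls only (no dosages/BGEN/VCF); the SE is an
expected-information approximation, absent at boundary fits; sub-sample and
predictive-process estimates share the small-r attenuation discussed above in
cohorts whose GRM carries substantial sampling noise (small M).
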
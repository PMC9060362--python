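# predlmm

SNP heritability estimation for large cohorts with a Gaussian
predictive-process approximation of GREML.

## The problem

Given genome-wide SNP genotypes on N distantly related individuals and a
quantitative trait **Y**, the standard GREML linear mixed model decomposes the
trait variance into an additive genetic and a residual component,

    Y ~ N(Xβ, σ_h² A + σ_e² I),        h² = σ_h² / (σ_h² + σ_e²),

where **A** = (1/M) W̃ W̃ᵀ is the genetic relationship matrix (GRM) built from
the column-standardized genotype matrix W̃. Restricted maximum likelihood
(REML) estimation of (σ_h², σ_e²) needs the inverse and determinant of the
dense N×N covariance at every step — O(N³) work and O(N²) memory, intractable
for biobank-scale N.

## The method

Genetic relatedness in a cohort is tree-structured: individuals who coalesce
to a recent common ancestor have correlated genotypes. That makes the GRM
behave like a Gaussian-process covariance and invites the *predictive
process* approximation from spatial statistics. Pick r ≪ N "knot"
individuals (index set I); then

    Ã = A_BI A_II⁻¹ A_IB + diag(A − A_BI A_II⁻¹ A_IB)

is a low-rank-plus-diagonal surrogate that agrees with **A** on the diagonal
and on the knot block, and equals **A** exactly when r = N. Writing
Ã = UUᵀ + diag(d) with U = A_BI R⁻¹ (Cholesky A_II = RᵀR), the covariance
σ_h²Ã + σ_e²I is diagonal-plus-rank-r, so the Woodbury identity and the
matrix determinant lemma evaluate the exact likelihood of the approximate
model in O(Nr² + r³) time and O(Nr) memory — and only the N×r, r×r and
diagonal blocks of the GRM are ever computed.

The package provides:

- PLINK 1 (.bed/.bim/.fam) and GCTA binary GRM (.grm.bin/.grm.N.bin/.grm.id)
  readers/writers, plus whitespace-delimited phenotype/covariate/weight
  tables (`predlmm.io_genetics`);
- streaming GRM block / row-sum computation with optional per-SNP weights
  (`predlmm.grm`);
- random and GRM-row-sum knot selection (`predlmm.knots`);
- the predictive-process (RE)ML fit with a profile search over h² and an
  asymptotic standard error from the low-rank Fisher information
  (`predlmm.predictive_process`);
- exact dense GREML and sub-sample GREML baselines (`predlmm.greml_exact`);
- a coalescent (Balding–Nichols) genotype simulator with causal-SNP and
  GRM-Gaussian phenotype models, and a replication/RMSE experiment driver
  (`predlmm.simulate`);
- a `predlmm` command-line tool wrapping all of the above (`predlmm.cli`).

## Worked example

Simulate a four-subpopulation cohort (N=1000, M=2000) with a causal-SNP
trait of heritability 0.5, then estimate h² three ways:

```sh
predlmm simulate --n 1000 --m 2000 --h2 0.5 --seed 7 --out sim
predlmm fit   --bfile sim --pheno sim.pheno --knots 250 --knot-method rowsum --out fit.tsv
predlmm greml --bfile sim --pheno sim.pheno --subsample 250 --seed 7 --out sub.tsv
predlmm greml --bfile sim --pheno sim.pheno --out dense.tsv
```

The three output records (tab-separated, abridged):

```
h2        se        sigma_h2  sigma_e2  method       r
0.355996  0.094863  0.382382  0.691737  predlmm      250
0.251094  0.196304  0.280324  0.836087  greml_sub    250
0.413366  0.063123  0.442010  0.627284  greml_dense  NA
```

All three point estimates sit within ~1.5 standard errors of the generative
truth 0.5 on this single replicate. The ordering of the standard errors is
the method's point: with the *same* 250 individuals, sub-sample GREML throws
away the genetic correlation between sampled and unsampled individuals
(SE 0.20), while the predictive process keeps it through A_BI and halves the
uncertainty (SE 0.09), approaching the dense full-likelihood fit (SE 0.06)
at a fraction of its cost. Averaged over replications the gap shows up as
RMSE (see `predlmm experiment`, which prints bias/variance/RMSE tables).

Every run writes a `.manifest` file recording inputs, flags and seeds;
re-running the same command reproduces the output byte for byte.

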
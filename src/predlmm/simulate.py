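"""Synthetic genotype and phenotype generators, plus the replication driver.

Genotypes follow a four-generation coalescent hierarchy: a single ancestral
allele frequency per SNP drawn U(freq_low, freq_high) drifts down a binary
tree of lineages (1 -> 2 -> 4) via the Balding-Nichols model — each child
frequency is Beta(p(1-theta)/theta, (1-p)(1-theta)/theta) around its parent
p, so E[child] = p and Var[child] = theta p (1-p) — and finally every
individual in a terminal subpopulation draws its own frequency around the
subpopulation value and a genotype Bin(2, p) under Hardy-Weinberg.  The
resulting cohort has block-structured relatedness: individuals within a
subpopulation share a more recent ancestor than individuals across.

Two phenotype models are provided: a causal-SNP architecture (m_causal
standardized SNP columns with N(0, h2/m_causal) effects plus iid noise) and
a GRM-Gaussian draw Y ~ N(0, total_variance * (h2 A + (1-h2) I)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grm import (
    GRMBlocks,
    compute_grm_blocks,
    compute_standardization,
    grm_row_sums,
    standardized_block,
)
from .greml_exact import fit_greml_dense, fit_greml_subsample
from .io_genetics import GenotypeDataset
from .knots import select_knots_random, select_knots_rowsum
from .predictive_process import PPFactor, build_pp_factor, fit_predlmm

_FREQ_EPS = 1e-12


@dataclass
class CoalescentConfig:
    """Parameters of the coalescent genotype hierarchy.

    Defaults are the study conditions: four subpopulations from a
    four-generation binary tree, drift theta = 0.05, ancestral frequencies
    uniform on [0.1, 0.9].
    """

    n_individuals: int
    n_variants: int
    theta: float = 0.05
    freq_low: float = 0.1
    freq_high: float = 0.9
    n_generations: int = 4
    seed: int | None = None

    @property
    def n_subpops(self) -> int:
        return 2 ** (self.n_generations - 2)

    def __post_init__(self):
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must be in (0,1), got {self.theta}")
        if not 0.0 <= self.freq_low < self.freq_high <= 1.0:
            raise ValueError("need 0 <= freq_low < freq_high <= 1")
        if self.n_generations < 2:
            raise ValueError("need at least 2 generations")
        if self.n_individuals % self.n_subpops != 0:
            raise ValueError(
                f"n_individuals={self.n_individuals} must be divisible by "
                f"n_subpops={self.n_subpops}"
            )


@dataclass
class PhenotypeSimConfig:
    """Phenotype generative model parameters.

    ``model`` is "causal_snp" (sparse standardized-SNP effects) or
    "grm_gaussian" (multivariate normal with GRM-proportional covariance).
    ``total_variance`` only rescales the phenotype; heritability is
    scale-free, so it defaults to 1.
    """

    h2_true: float
    m_causal: int = 200
    total_variance: float = 1.0
    model: str = "causal_snp"
    standardize_causal: bool = True
    literal_residual: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.model not in ("causal_snp", "grm_gaussian"):
            raise ValueError(f"unknown phenotype model {self.model!r}")
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError(f"h2_true must be in [0,1], got {self.h2_true}")
        if self.model == "causal_snp" and self.h2_true == 0.0:
            raise ValueError(
                "causal-SNP residual variance diverges at h2=0; "
                "use model='grm_gaussian' for a null trait"
            )
        if self.total_variance <= 0:
            raise ValueError("total_variance must be positive")


def _bn_child(parent: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step: Beta around each parent frequency."""
    c = (1.0 - theta) / theta
    child = rng.beta(parent * c, (1.0 - parent) * c)
    return np.clip(child, _FREQ_EPS, 1.0 - _FREQ_EPS)


def simulate_bn_frequencies(
    config: CoalescentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-individual allele frequencies (N x M) from the coalescent tree.

    Lineages double each generation (1 -> 2 -> ... -> n_subpops); the final
    generation gives every individual its own frequency drawn around its
    subpopulation's value.
    """
    m = config.n_variants
    pops = np.clip(
        rng.uniform(config.freq_low, config.freq_high, size=(1, m)),
        _FREQ_EPS,
        1.0 - _FREQ_EPS,
    )
    for _ in range(config.n_generations - 2):
        pops = np.concatenate([_bn_child(pops, config.theta, rng) for _ in range(2)])
        # children interleaved per parent would also work; order is arbitrary
    k = config.n_subpops
    per_pop = config.n_individuals // k
    freqs = np.empty((config.n_individuals, m))
    for i in range(k):
        parent = np.broadcast_to(pops[i], (per_pop, m))
        freqs[i * per_pop : (i + 1) * per_pop] = _bn_child(parent, config.theta, rng)
    return freqs


def simulate_genotypes(
    freqs: np.ndarray, config: CoalescentConfig, rng: np.random.Generator
) -> GenotypeDataset:
    """Hardy-Weinberg genotypes: independent Bin(2, p_ij) draws."""
    freqs = np.asarray(freqs)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies must lie in [0,1]")
    g = rng.binomial(2, freqs).astype(np.int8)
    per_pop = config.n_individuals // config.n_subpops
    sample_ids = [
        (f"P{i // per_pop + 1}", f"I{i + 1}") for i in range(config.n_individuals)
    ]
    return GenotypeDataset.from_array(g, sample_ids=sample_ids)


def simulate_phenotype_causal(
    dataset: GenotypeDataset,
    stats,
    sim: PhenotypeSimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Causal-SNP phenotype: y = W_causal u + e.

    m_causal variants are drawn uniformly without replacement (from the
    variants retained by standardization); effects u_m ~ N(0, h2/m_causal)
    act on standardized columns, so the genetic values have variance ~ h2.
    The residual is iid N(0, sigma_e^2) with sigma_e^2 = var(g) (1/h2 - 1),
    which makes the realized heritability exactly h2 relative to the
    realized genetic variance; ``literal_residual=True`` instead uses the
    fixed sigma_e^2 = 1/h2 - 1 (exact only when var(g) = h2).

    Returns (y, causal indices, bookkeeping dict).
    """
    if sim.m_causal > stats.n_retained:
        raise ValueError(
            f"m_causal={sim.m_causal} exceeds the {stats.n_retained} retained variants"
        )
    h2 = sim.h2_true
    causal = np.sort(rng.choice(stats.retained, size=sim.m_causal, replace=False))
    u = rng.normal(0.0, np.sqrt(h2 / sim.m_causal), size=sim.m_causal)
    if sim.standardize_causal:
        W = standardized_block(dataset, stats, causal)
    else:
        W = dataset.genotypes(variants=causal).astype(np.float64)
        W -= W.mean(axis=0)  # centered raw allele counts
    g = W @ u
    var_g = float(g.var())
    if sim.literal_residual:
        sigma_e2 = 1.0 / h2 - 1.0
    else:
        sigma_e2 = var_g * (1.0 / h2 - 1.0)
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=dataset.n_samples)
    y = g + e
    info = {
        "var_g": var_g,
        "sigma_e2": sigma_e2,
        "realized_h2": var_g / (var_g + sigma_e2) if sigma_e2 > 0 else 1.0,
    }
    return y, causal, info


def simulate_phenotype_grm(
    A_or_factor: np.ndarray | PPFactor,
    sim: PhenotypeSimConfig,
    rng: np.random.Generator,
    n_draws: int = 1,
    chol: np.ndarray | None = None,
) -> np.ndarray:
    """Exact draw(s) from N(0, total_variance (h2 A + (1-h2) I)).

    With a dense GRM the covariance is factored by Cholesky (pass ``chol``
    to reuse a precomputed factor across replications).  With a
    :class:`PPFactor` the generative covariance is the predictive-process
    approximation total_variance (h2 A_pp + (1-h2) I), sampled exactly from
    its low-rank-plus-diagonal structure (and labeled as such by the input
    type).  Returns shape (N,) for one draw, else (N, n_draws).
    """
    h2, tv = sim.h2_true, sim.total_variance

    if isinstance(A_or_factor, PPFactor):
        f = A_or_factor
        n = f.n_samples
        z_r = rng.standard_normal((f.r, n_draws))
        z_d = rng.standard_normal((n, n_draws))
        z_e = rng.standard_normal((n, n_draws))
        y = np.sqrt(tv) * (
            np.sqrt(h2) * (f.U @ z_r + np.sqrt(f.d_res)[:, None] * z_d)
            + np.sqrt(1.0 - h2) * z_e
        )
    else:
        A = np.asarray(A_or_factor, dtype=np.float64)
        n = A.shape[0]
        if chol is None:
            chol = grm_covariance_chol(A, sim)
        y = chol @ rng.standard_normal((n, n_draws))
    return y[:, 0] if n_draws == 1 else y


def grm_covariance_chol(A: np.ndarray, sim: PhenotypeSimConfig) -> np.ndarray:
    """Lower Cholesky factor of total_variance (h2 A + (1-h2) I), with a
    small jitter ladder for GRMs that are PSD only up to round-off."""
    from scipy import linalg

    n = A.shape[0]
    cov = sim.total_variance * (sim.h2_true * A + (1.0 - sim.h2_true) * np.eye(n))
    for j in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return linalg.cholesky(cov + j * sim.total_variance * np.eye(n), lower=True)
        except linalg.LinAlgError:
            continue
    raise linalg.LinAlgError("phenotype covariance is indefinite beyond jitter 1e-6")


def _rep_rng(seed: int, rep: int, stream: int = 0) -> np.random.Generator:
    """Deterministic, independent per-replication stream (rep -1 = shared setup)."""
    return np.random.default_rng(np.random.SeedSequence((seed, rep + 1, stream)))


def run_replication_experiment(
    config: CoalescentConfig,
    sim: PhenotypeSimConfig,
    estimators: Sequence[str] = ("predlmm", "greml_sub"),
    knot_sizes: Sequence[int] = (250,),
    n_reps: int = 50,
    seed: int = 1,
    knot_method: str = "rowsum",
    reml: bool = True,
    dense_limit: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated estimator comparison; the RMSE machinery of the studies.

    Per replication the causal-SNP model redraws genotypes and phenotype;
    the GRM-Gaussian model draws genotypes (and hence the GRM) once and
    redraws only the phenotype, mirroring a fixed real cohort.  Each
    estimator is fitted at each knot size; "greml_sub" reuses exactly the
    PredLMM knot set (its likelihood sees only A_II).  Returns per-rep
    estimates and a summary with empirical bias, variance and
    RMSE = sqrt(bias^2 + variance).
    """
    for est in estimators:
        if est not in ("predlmm", "greml_sub", "greml_dense"):
            raise ValueError(f"unknown estimator {est!r}")
    if "greml_dense" in estimators and config.n_individuals > dense_limit:
        raise ValueError("dense estimator requested above the dense limit")

    fixed_geno = sim.model == "grm_gaussian"
    records = []

    if fixed_geno:
        rng_g = _rep_rng(seed, -1, stream=1)
        freqs = simulate_bn_frequencies(config, rng_g)
        dataset = simulate_genotypes(freqs, config, rng_g)
        stats = compute_standardization(dataset)
        from .grm import compute_grm_full

        A = compute_grm_full(dataset, stats, dense_limit=max(dense_limit, config.n_individuals)).values
        chol = grm_covariance_chol(A, sim)
        row_sums = A.sum(axis=1)

    for rep in range(n_reps):
        rng = _rep_rng(seed, rep)
        if fixed_geno:
            y = simulate_phenotype_grm(A, sim, rng, chol=chol)
        else:
            freqs = simulate_bn_frequencies(config, rng)
            dataset = simulate_genotypes(freqs, config, rng)
            stats = compute_standardization(dataset)
            y, _, _ = simulate_phenotype_causal(dataset, stats, sim, rng)
            row_sums = None

        for r in knot_sizes:
            if knot_method == "rowsum":
                if row_sums is None:
                    row_sums = grm_row_sums(dataset, stats)
                knots = select_knots_rowsum(row_sums, r)
            else:
                knots = select_knots_random(
                    config.n_individuals, r, seed=int(_rep_rng(seed, rep, 2).integers(2**31))
                )
            if fixed_geno:
                blocks = _blocks_from_dense(A, knots.indices)
            else:
                blocks = compute_grm_blocks(dataset, stats, knots.indices)

            for est in estimators:
                if est == "predlmm":
                    factor = build_pp_factor(blocks)
                    fit = fit_predlmm(y, None, factor, reml=reml, compute_se=False)
                elif est == "greml_sub":
                    fit = fit_greml_subsample(y, None, blocks, reml=reml, compute_se=False)
                else:
                    if fixed_geno:
                        A_full = A
                    else:
                        from .grm import compute_grm_full

                        A_full = compute_grm_full(dataset, stats, dense_limit=dense_limit).values
                    fit = fit_greml_dense(y, None, A_full, reml=reml, compute_se=False)
                records.append(
                    {
                        "rep": rep,
                        "estimator": est,
                        "r": r if est != "greml_dense" else config.n_individuals,
                        "h2_hat": fit.h2_hat,
                        "converged": fit.converged,
                        "boundary": fit.boundary_flag,
                        "truth": sim.h2_true,
                    }
                )

    per_rep = pd.DataFrame.from_records(records)
    rows = []
    for (est, r), grp in per_rep.groupby(["estimator", "r"]):
        est_vals = grp["h2_hat"].to_numpy()
        bias = est_vals.mean() - sim.h2_true
        var = est_vals.var()
        rows.append(
            {
                "estimator": est,
                "r": r,
                "n_reps": len(est_vals),
                "mean_h2": est_vals.mean(),
                "bias": bias,
                "variance": var,
                "rmse": float(np.sqrt(bias**2 + var)),
                "truth": sim.h2_true,
            }
        )
    summary = pd.DataFrame(rows).sort_values(["estimator", "r"]).reset_index(drop=True)
    return per_rep, summary


def _blocks_from_dense(A: np.ndarray, knot_indices: np.ndarray) -> GRMBlocks:
    """GRM blocks read off a dense GRM (used when the GRM is precomputed)."""
    idx = np.asarray(knot_indices, dtype=np.int64)
    A_II = A[np.ix_(idx, idx)]
    return GRMBlocks(
        knot_indices=idx,
        A_BI=A[:, idx].copy(),
        A_II=(A_II + A_II.T) / 2.0,
        diag_A=np.diag(A).copy(),
        n_variants_used=0,
    )
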
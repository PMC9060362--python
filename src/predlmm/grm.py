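"""Genotype standardization and genetic relationship matrix (GRM) computation.

The GRM is A = (1/M) W W', with W the column-standardized genotype matrix:
each variant is centered at twice its allele-1 frequency and scaled by
sqrt(2 p (1 - p)), the Hardy-Weinberg standard deviation (the GCTA
convention).  Optional per-variant weights d_j generalize this to
A = (sum_j d_j)^-1 sum_j d_j w_j w_j', preserving E[diag(A)] ~ 1.

Everything streams over variant chunks, so the predictive-process blocks
(A_BI, A_II, diag A) and GRM row sums cost O(N r + chunk) memory — the full
N x N matrix is only ever formed by :func:`compute_grm_full`, the dense
oracle/baseline path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_genetics import MISSING, GenotypeDataset, GRMFile


@dataclass
class StandardizationStats:
    """Per-variant centering/scaling constants and weights.

    mean = 2 p-hat, scale = sqrt(2 p-hat (1 - p-hat)) with p-hat the sample
    allele-1 frequency over non-missing calls.  Monomorphic variants
    (p-hat in {0, 1}) are flagged excluded, never silently zero-divided.
    """

    mean: np.ndarray
    scale: np.ndarray
    weight: np.ndarray
    excluded: np.ndarray  # boolean mask, True = dropped from the GRM
    n_nonmissing: np.ndarray

    @property
    def n_retained(self) -> int:
        return int((~self.excluded).sum())

    @property
    def retained(self) -> np.ndarray:
        return np.flatnonzero(~self.excluded)


@dataclass
class GRMBlocks:
    """The sub-matrices of A that the predictive process needs.

    A_BI is the N x r block of GRM columns at the knot individuals, A_II its
    r x r knot sub-matrix, diag_A the full GRM diagonal.  Rows of A_BI at
    knot positions reproduce A_II.
    """

    knot_indices: np.ndarray
    A_BI: np.ndarray
    A_II: np.ndarray
    diag_A: np.ndarray
    n_variants_used: int

    @property
    def n_samples(self) -> int:
        return self.A_BI.shape[0]

    @property
    def r(self) -> int:
        return len(self.knot_indices)


def compute_standardization(
    dataset: GenotypeDataset,
    weights: pd.DataFrame | dict | None = None,
    chunk_size: int = 1024,
) -> StandardizationStats:
    """Allele-frequency standardization constants for every variant.

    ``weights`` maps variant ids to non-negative per-SNP weights (e.g.
    externally computed LD weights); omitted variants get weight 1.  Unknown
    variant ids in the weight table raise, listing them.
    """
    n, m = dataset.n_samples, dataset.n_variants
    if n == 0 or m == 0:
        raise ValueError("dataset must contain at least one sample and one variant")

    mean = np.empty(m)
    scale = np.empty(m)
    n_nonmiss = np.empty(m, dtype=np.int64)
    for lo in range(0, m, chunk_size):
        hi = min(lo + chunk_size, m)
        g = dataset.genotypes(variants=slice(lo, hi)).astype(np.float64)
        miss = g == MISSING
        g[miss] = np.nan
        cnt = (~miss).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(g, axis=0) / np.maximum(2 * cnt, 1)
        mean[lo:hi] = 2.0 * p
        scale[lo:hi] = np.sqrt(np.clip(2.0 * p * (1.0 - p), 0.0, None))
        n_nonmiss[lo:hi] = cnt

    excluded = (scale <= 0) | (n_nonmiss == 0)

    w = np.ones(m)
    if weights is not None:
        if isinstance(weights, pd.DataFrame):
            table = dict(zip(weights.index, weights.iloc[:, 0]))
        else:
            table = dict(weights)
        known = {v[1]: j for j, v in enumerate(dataset.variants)}
        unknown = [vid for vid in table if vid not in known]
        if unknown:
            raise ValueError(f"weight table references unknown variant ids: {unknown}")
        for vid, val in table.items():
            if val < 0:
                raise ValueError(f"negative weight for variant {vid}")
            w[known[vid]] = float(val)

    return StandardizationStats(
        mean=mean, scale=scale, weight=w, excluded=excluded, n_nonmissing=n_nonmiss
    )


def standardized_block(
    dataset: GenotypeDataset,
    stats: StandardizationStats,
    variant_range: slice | np.ndarray,
    sample_rows=None,
) -> np.ndarray:
    """Standardized (and sqrt-weighted) genotype columns for a variant slice.

    Missing genotypes are imputed to the per-variant mean before centering,
    hence contribute exactly 0; excluded (monomorphic) variants are dropped
    from the returned block.
    """
    m = dataset.n_variants
    vidx = np.arange(m)[variant_range]
    vidx = np.atleast_1d(vidx)
    if vidx.size and (vidx.min() < 0 or vidx.max() >= m):
        raise IndexError("variant range out of bounds")
    keep = ~stats.excluded[vidx]
    vidx = vidx[keep]
    g = dataset.genotypes(samples=sample_rows, variants=vidx).astype(np.float64)
    g[g == MISSING] = np.nan
    centered = g - stats.mean[vidx]
    centered[np.isnan(centered)] = 0.0  # mean imputation
    return centered / stats.scale[vidx] * np.sqrt(stats.weight[vidx])


def _weight_normalizer(stats: StandardizationStats) -> float:
    w = stats.weight[~stats.excluded]
    total = float(w.sum())
    if total <= 0:
        raise ValueError("no retained variants with positive weight")
    return total


def compute_grm_full(
    dataset: GenotypeDataset,
    stats: StandardizationStats,
    chunk_size: int = 512,
    dense_limit: int = 20_000,
) -> GRMFile:
    """Dense N x N GRM, accumulated over variant chunks in float64.

    Guarded by ``dense_limit``: this is the oracle/baseline path, the
    predictive process never needs it.
    """
    n, m = dataset.n_samples, dataset.n_variants
    if n > dense_limit:
        raise ValueError(f"N={n} exceeds dense GRM guard ({dense_limit})")
    if stats.n_retained == 0:
        raise ValueError("no retained variants (all monomorphic?)")

    A = np.zeros((n, n))
    for lo in range(0, m, chunk_size):
        w = standardized_block(dataset, stats, slice(lo, min(lo + chunk_size, m)))
        A += w @ w.T
    A /= _weight_normalizer(stats)
    A = (A + A.T) / 2.0

    counts = _pair_counts(dataset, stats, chunk_size)
    return GRMFile(values=A, pair_counts=counts, sample_ids=list(dataset.sample_ids))


def _pair_counts(dataset, stats, chunk_size) -> np.ndarray:
    """Per-pair non-missing SNP counts over retained variants."""
    n, m = dataset.n_samples, dataset.n_variants
    if (stats.n_nonmissing[~stats.excluded] == dataset.n_samples).all():
        return np.full((n, n), stats.n_retained, dtype=np.int64)
    obs = np.zeros((n, n))
    for lo in range(0, m, chunk_size):
        hi = min(lo + chunk_size, m)
        vidx = np.arange(lo, hi)[~stats.excluded[lo:hi]]
        g = dataset.genotypes(variants=vidx)
        ok = (g != MISSING).astype(np.float64)
        obs += ok @ ok.T
    return np.maximum(obs, 1).astype(np.int64)


def compute_grm_blocks(
    dataset: GenotypeDataset,
    stats: StandardizationStats,
    knot_indices: np.ndarray,
    chunk_size: int = 512,
) -> GRMBlocks:
    """A_BI, A_II and diag(A) without ever forming the N x N GRM.

    Streams variant chunks; memory is O(N r + N chunk).  The blocks equal
    the corresponding entries of :func:`compute_grm_full` to float64
    round-off.
    """
    n, m = dataset.n_samples, dataset.n_variants
    knots = np.asarray(knot_indices, dtype=np.int64)
    if knots.ndim != 1 or knots.size < 1:
        raise ValueError("need at least one knot index")
    if len(np.unique(knots)) != knots.size:
        raise ValueError("duplicate knot indices")
    if knots.min() < 0 or knots.max() >= n:
        raise IndexError("knot index out of range")
    if stats.n_retained == 0:
        raise ValueError("no retained variants (all monomorphic?)")

    A_BI = np.zeros((n, knots.size))
    diag_A = np.zeros(n)
    for lo in range(0, m, chunk_size):
        w = standardized_block(dataset, stats, slice(lo, min(lo + chunk_size, m)))
        A_BI += w @ w[knots].T
        diag_A += np.einsum("ij,ij->i", w, w)
    norm = _weight_normalizer(stats)
    A_BI /= norm
    diag_A /= norm
    A_II = A_BI[knots]
    A_II = (A_II + A_II.T) / 2.0
    return GRMBlocks(
        knot_indices=knots,
        A_BI=A_BI,
        A_II=A_II,
        diag_A=diag_A,
        n_variants_used=stats.n_retained,
    )


def grm_row_sums(
    dataset: GenotypeDataset,
    stats: StandardizationStats,
    chunk_size: int = 512,
) -> np.ndarray:
    """Row sums A.1 of the GRM in O(NM) time and O(N) extra memory.

    Uses A.1 = (1/sum_j d_j) sum_j w_j (1' w_j) — no N x N matrix is formed.
    """
    n, m = dataset.n_samples, dataset.n_variants
    if stats.n_retained == 0:
        raise ValueError("no retained variants (all monomorphic?)")
    rs = np.zeros(n)
    for lo in range(0, m, chunk_size):
        w = standardized_block(dataset, stats, slice(lo, min(lo + chunk_size, m)))
        rs += w @ w.sum(axis=0)
    return rs / _weight_normalizer(stats)
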
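"""Dense GREML: the exact O(N^3) baseline the predictive process approximates.

Serves as oracle and small-N baseline.  A single symmetric eigendecomposition
of the GRM makes the covariance K(h2) = h2 A + (1-h2) I diagonal in the
eigenbasis, so each step of the h2 profile search costs O(N p^2) after the
one-time O(N^3) factorization.  Also provides the sub-sample GREML baseline:
dense GREML on the knot block A_II alone, which discards all genetic
correlation between sampled and unsampled individuals.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .grm import GRMBlocks, compute_grm_blocks, compute_standardization
from .io_genetics import GenotypeDataset, GRMFile
from .predictive_process import (
    HeritabilityFit,
    VarianceParams,
    _design,
    _maximize_h2,
)


def _as_matrix(A) -> np.ndarray:
    if isinstance(A, GRMFile):
        return A.values
    return np.asarray(A, dtype=np.float64)


def dense_loglik(
    params: VarianceParams,
    y: np.ndarray,
    X: np.ndarray,
    A: np.ndarray | GRMFile,
    reml: bool = True,
) -> tuple[float, np.ndarray]:
    """(Restricted) log-likelihood of N(X beta, sigma_h^2 A + sigma_e^2 I).

    Direct dense evaluation — explicit factorization of V — used as the
    independent oracle for the Woodbury path.
    """
    A = _as_matrix(A)
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, p = y.size, X.shape[1]
    V = params.sigma_h2 * A + params.sigma_e2 * np.eye(n)
    cv = linalg.cho_factor(V)
    logdet_V = float(2.0 * np.log(np.diag(cv[0])).sum())
    Viy = linalg.cho_solve(cv, y)
    ViX = linalg.cho_solve(cv, X)
    S = X.T @ ViX
    cs = linalg.cho_factor((S + S.T) / 2.0)
    beta = linalg.cho_solve(cs, X.T @ Viy)
    quad = float(y @ Viy - (X.T @ Viy) @ beta)
    if reml:
        logdet_S = float(2.0 * np.log(np.diag(cs[0])).sum())
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_V + logdet_S + quad)
    else:
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet_V + quad)
    return float(ll), beta


def _eig_profile(h2, ystar, Xstar, lam, reml):
    """Profile log-likelihood in the GRM eigenbasis (K diagonal)."""
    n, p = ystar.size, Xstar.shape[1]
    k = h2 * lam + (1.0 - h2)
    yk = ystar / k
    Xk = Xstar / k[:, None]
    S = Xstar.T @ Xk
    cs = linalg.cho_factor((S + S.T) / 2.0)
    XVy = Xstar.T @ yk
    beta = linalg.cho_solve(cs, XVy)
    quad = float(ystar @ yk - XVy @ beta)
    df = n - p if reml else n
    sigma_p2 = max(quad / df, np.finfo(float).tiny)
    logdet_K = float(np.log(k).sum())
    if reml:
        logdet_S = float(2.0 * np.log(np.diag(cs[0])).sum())
        ll = -0.5 * (
            df * np.log(2 * np.pi) + logdet_K + logdet_S + df * (np.log(sigma_p2) + 1.0)
        )
    else:
        ll = -0.5 * (df * np.log(2 * np.pi) + logdet_K + df * (np.log(sigma_p2) + 1.0))
    return float(ll), float(sigma_p2), beta


def fit_greml_dense(
    y: np.ndarray,
    X: np.ndarray | None,
    A: np.ndarray | GRMFile,
    reml: bool = True,
    h2_bounds: tuple[float, float] = (0.0, 1.0),
    tol: float = 1e-6,
    max_evals: int = 200,
    add_intercept: bool = True,
    dense_limit: int = 10_000,
    compute_se: bool = True,
) -> HeritabilityFit:
    """Exact dense GREML via one-time eigendecomposition of the GRM.

    Small negative eigenvalues (float round-off of a Gram matrix) are
    clipped at zero.  Guarded at ``dense_limit`` samples — beyond that, this
    is exactly the cost the predictive process exists to avoid.
    """
    A = _as_matrix(A)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size
    if n > dense_limit:
        raise ValueError(f"N={n} exceeds the dense GREML guard ({dense_limit})")
    if A.shape != (n, n):
        raise ValueError("GRM shape does not match y")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values; filter to complete cases first")
    X = _design(X, n, add_intercept)

    lam, Q = linalg.eigh(A)
    lam = np.clip(lam, 0.0, None)
    ystar = Q.T @ y
    Xstar = Q.T @ X

    h2_hat, ll, ok, n_evals, boundary, flat = _maximize_h2(
        lambda h: _eig_profile(h, ystar, Xstar, lam, reml), h2_bounds, tol, max_evals
    )
    _, sigma_p2, beta_star = _eig_profile(h2_hat, ystar, Xstar, lam, reml)
    fit = HeritabilityFit(
        h2_hat=h2_hat,
        sigma_h2=h2_hat * sigma_p2,
        sigma_e2=(1.0 - h2_hat) * sigma_p2,
        beta_hat=beta_star,
        loglik=ll,
        reml=reml,
        n_evaluations=n_evals,
        converged=ok,
        boundary_flag=boundary,
        flat=flat,
        method="greml_dense",
        r=None,
    )
    if compute_se and not boundary and not flat and n <= 4000:
        try:
            fit.se_h2 = dense_fisher_se(fit, A, X, reml=reml, add_intercept=False)
        except (linalg.LinAlgError, ValueError):
            fit.se_h2 = None
    return fit


def dense_fisher_se(
    fit: HeritabilityFit,
    A: np.ndarray | GRMFile,
    X: np.ndarray | None,
    reml: bool = True,
    add_intercept: bool = True,
) -> float:
    """SE of h2 from the dense 2x2 Fisher information (oracle-grade, O(N^3))."""
    A = _as_matrix(A)
    n = A.shape[0]
    X = _design(X, n, add_intercept)
    V = fit.sigma_h2 * A + fit.sigma_e2 * np.eye(n)
    Vi = linalg.inv(V)
    if reml:
        ViX = Vi @ X
        P = Vi - ViX @ linalg.solve(X.T @ ViX, ViX.T)
    else:
        P = Vi
    PA = P @ A
    info = 0.5 * np.array(
        [
            [np.sum(PA * PA.T), np.sum(PA * P.T)],
            [np.sum(PA * P.T), np.sum(P * P.T)],
        ]
    )
    cov = np.linalg.inv(info)
    a, b = fit.sigma_h2, fit.sigma_e2
    grad = np.array([b, -a]) / (a + b) ** 2
    var_h2 = float(grad @ cov @ grad)
    if var_h2 <= 0:
        raise linalg.LinAlgError("Fisher information is not positive definite")
    return float(np.sqrt(var_h2))


def fit_greml_subsample(
    y: np.ndarray,
    X: np.ndarray | None,
    source: GRMBlocks | GRMFile | np.ndarray | GenotypeDataset,
    r: int | None = None,
    seed: int | None = None,
    reml: bool = True,
    add_intercept: bool = True,
    **fit_kwargs,
) -> HeritabilityFit:
    """Sub-sample GREML: dense GREML restricted to r of the N individuals.

    Given :class:`GRMBlocks`, the sub-sample is the knot set and the GRM is
    exactly A_II — the likelihood never sees the cross-block A_BI, i.e. the
    genetic correlation between sampled and unsampled individuals is
    discarded.  Given a dense GRM or a dataset, a random sub-sample of size
    ``r`` is drawn with ``seed``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size

    if isinstance(source, GRMBlocks):
        idx = np.asarray(source.knot_indices)
        if r is not None and r != idx.size:
            raise ValueError(f"blocks carry r={idx.size} knots but r={r} was requested")
        A_sub = source.A_II
    else:
        if r is None:
            raise ValueError("r is required unless GRMBlocks are given")
        if r > n:
            raise ValueError(f"sub-sample size r={r} exceeds N={n}")
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=r, replace=False))
        if isinstance(source, GenotypeDataset):
            stats = compute_standardization(source)
            A_sub = compute_grm_blocks(source, stats, idx).A_II
        else:
            A_full = _as_matrix(source)
            A_sub = A_full[np.ix_(idx, idx)]

    y_sub = y[idx]
    X_sub = None
    if X is not None:
        X_arr = np.asarray(X, dtype=np.float64)
        if X_arr.ndim == 1:
            X_arr = X_arr[:, None]
        X_sub = X_arr[idx]

    fit = fit_greml_dense(
        y_sub, X_sub, A_sub, reml=reml, add_intercept=add_intercept, **fit_kwargs
    )
    fit.method = "greml_sub"
    fit.r = int(idx.size)
    fit.subsample = idx
    return fit
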
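"""Low-rank predictive-process approximation of the GREML likelihood.

The GRM A is replaced by

    A_pp = A_BI A_II^-1 A_IB + diag(A - A_BI A_II^-1 A_IB)
         = U U' + diag(d_res),        U = A_BI R^-1,  A_II = R'R,

the optimal low-rank approximation anchored at r knot individuals plus the
Schur-complement residual diagonal (which restores the exact GRM diagonal
and vanishes at the knots).  The model covariance

    V = sigma_h^2 (U U' + diag(d_res)) + sigma_e^2 I = Delta + Uc Uc'

is diagonal-plus-rank-r, so V^-1 products use the Woodbury identity with the
r x r capacitance matrix C = I_r + Uc' Delta^-1 Uc and log|V| uses the
matrix determinant lemma log|V| = log|C| + sum log Delta_ii.  Every
likelihood evaluation costs O(N r^2 + r^3 + N p^2) time and O(N r) memory.

Heritability is estimated by a bounded scalar search over h^2 in [0, 1] with
the total variance sigma_p^2 = sigma_h^2 + sigma_e^2 profiled out in closed
form and fixed effects profiled by generalized least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .grm import GRMBlocks

_JITTER_LADDER = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)
_BOUNDARY_TOL = 1e-3
_H2_EPS = 1e-9  # interior margin: at h2=1 exactly, Delta is singular at knots


@dataclass
class PPFactor:
    """Low-rank factor of the predictive-process GRM approximation.

    ``U @ U.T + np.diag(d_res)`` reconstructs A_pp.  ``d_res`` is the
    Schur-complement diagonal: zero at knots, non-negative elsewhere
    (negative float round-off is clipped and counted in ``n_clipped``).
    """

    U: np.ndarray
    d_res: np.ndarray
    knot_indices: np.ndarray
    jitter_used: float = 0.0
    n_clipped: int = 0

    @property
    def n_samples(self) -> int:
        return self.U.shape[0]

    @property
    def r(self) -> int:
        return self.U.shape[1]

    def dense(self) -> np.ndarray:
        """Materialize A_pp (oracle/testing only)."""
        return self.U @ self.U.T + np.diag(self.d_res)


@dataclass
class VarianceParams:
    """(h^2, sigma_p^2) parameterization of the two variance components."""

    h2: float
    sigma_p2: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must be in [0,1], got {self.h2}")
        if self.sigma_p2 <= 0:
            raise ValueError(f"sigma_p2 must be positive, got {self.sigma_p2}")

    @property
    def sigma_h2(self) -> float:
        return self.h2 * self.sigma_p2

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.h2) * self.sigma_p2


@dataclass
class HeritabilityFit:
    """Result of a variance-component fit."""

    h2_hat: float
    sigma_h2: float
    sigma_e2: float
    beta_hat: np.ndarray
    loglik: float
    reml: bool
    n_evaluations: int
    converged: bool
    boundary_flag: bool
    flat: bool = False
    se_h2: float | None = None
    method: str = "predlmm"
    r: int | None = None
    subsample: np.ndarray | None = field(default=None, repr=False)


def build_pp_factor(blocks: GRMBlocks, jitter: float | None = None) -> PPFactor:
    """Factor the GRM blocks into U (N x r) and the residual diagonal.

    Cholesky of A_II + jitter*I, with jitter escalated by decade from 0 up
    to 1e-4 until the factorization succeeds (near-duplicate knots make A_II
    ill-conditioned).  Raises if even the maximum jitter fails.
    """
    A_II = np.asarray(blocks.A_II, dtype=np.float64)
    if A_II.shape[0] != A_II.shape[1] or A_II.shape[0] != blocks.r:
        raise ValueError("A_II must be r x r")
    if not np.allclose(A_II, A_II.T, atol=1e-8):
        raise ValueError("A_II must be symmetric")

    ladder = _JITTER_LADDER if jitter is None else (jitter,)
    R = None
    used = 0.0
    for j in ladder:
        try:
            R = linalg.cholesky(A_II + j * np.eye(blocks.r), lower=False)
            used = j
            break
        except linalg.LinAlgError:
            continue
    if R is None:
        raise linalg.LinAlgError(
            "A_II is not positive definite even with jitter 1e-4; "
            "choose a different (e.g. smaller or re-drawn) knot set"
        )

    # U = A_BI R^-1, so U U' = A_BI A_II^-1 A_IB
    U = linalg.solve_triangular(R, blocks.A_BI.T, trans="T", lower=False).T
    d_res = blocks.diag_A - np.einsum("ij,ij->i", U, U)
    n_clipped = int((d_res < 0).sum())
    d_res = np.clip(d_res, 0.0, None)
    d_res[blocks.knot_indices] = 0.0  # exact Schur identity at knots
    return PPFactor(
        U=U,
        d_res=d_res,
        knot_indices=np.asarray(blocks.knot_indices),
        jitter_used=used,
        n_clipped=n_clipped,
    )


def _design(X: np.ndarray | None, n: int, add_intercept: bool) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != n:
        X = X.T
    if X.shape[0] != n:
        raise ValueError("design matrix row count does not match y")
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def _woodbury_pieces(delta: np.ndarray, Uc: np.ndarray):
    """Cholesky of the capacitance C = I + Uc' Delta^-1 Uc and helpers."""
    if (delta <= 0).any():
        raise linalg.LinAlgError(
            "singular diagonal: sigma_e^2 = 0 with a zero residual diagonal entry"
        )
    Ud = Uc / delta[:, None]  # Delta^-1 Uc
    C = Uc.T @ Ud
    C[np.diag_indices_from(C)] += 1.0
    Rc = linalg.cholesky(C, lower=False)
    logdet = float(2.0 * np.log(np.diag(Rc)).sum() + np.log(delta).sum())
    return Ud, Rc, logdet


def _vinv_apply(M: np.ndarray, delta: np.ndarray, Ud: np.ndarray, Rc: np.ndarray) -> np.ndarray:
    """V^-1 M  via Woodbury:  Delta^-1 M - Ud C^-1 Ud' M."""
    t = linalg.cho_solve((Rc, False), Ud.T @ M)
    return M / delta[:, None] - Ud @ t


def _gls_core(y, X, delta, Ud, Rc):
    """GLS beta, X' V^-1 X and residual quadratic form y -> r' V^-1 r."""
    Z = np.column_stack([y, X])
    VinvZ = _vinv_apply(Z, delta, Ud, Rc)
    G = Z.T @ VinvZ  # [[y'Vy, y'VX], [X'Vy, X'VX]]
    yVy = G[0, 0]
    XVy = G[1:, 0]
    S = (G[1:, 1:] + G[1:, 1:].T) / 2.0
    cs = linalg.cho_factor(S)
    beta = linalg.cho_solve(cs, XVy)
    quad = float(yVy - XVy @ beta)
    logdet_S = float(2.0 * np.log(np.diag(cs[0])).sum())
    return beta, quad, logdet_S


def pp_loglik(
    params: VarianceParams,
    y: np.ndarray,
    X: np.ndarray,
    factor: PPFactor,
    reml: bool = True,
) -> tuple[float, np.ndarray]:
    """Exact Gaussian (restricted) log-likelihood of N(X beta, V) with GLS beta.

    V = sigma_h^2 (U U' + diag(d_res)) + sigma_e^2 I, evaluated in
    O(N r^2 + r^3 + N p^2) via the Woodbury identity and the matrix
    determinant lemma — never forming V.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    if n <= p:
        raise ValueError("need more samples than fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    delta = params.sigma_h2 * factor.d_res + params.sigma_e2
    Uc = np.sqrt(params.sigma_h2) * factor.U
    Ud, Rc, logdet_V = _woodbury_pieces(delta, Uc)
    beta, quad, logdet_S = _gls_core(y, X, delta, Ud, Rc)

    if reml:
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_V + logdet_S + quad)
    else:
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet_V + quad)
    return float(ll), beta


def _pp_profile(h2, y, X, factor, reml):
    """Profile log-likelihood at h2: sigma_p^2 and beta maximized in closed form.

    K(h2) = h2 A_pp + (1-h2) I; sigma_p2_hat = r'K^-1 r / (N - p*reml).
    """
    n, p = y.size, X.shape[1]
    delta = h2 * factor.d_res + (1.0 - h2)
    Uk = np.sqrt(h2) * factor.U
    Ud, Rc, logdet_K = _woodbury_pieces(delta, Uk)
    beta, quad, logdet_S = _gls_core(y, X, delta, Ud, Rc)
    df = n - p if reml else n
    sigma_p2 = max(quad / df, np.finfo(float).tiny)
    if reml:
        ll = -0.5 * (
            df * np.log(2 * np.pi) + logdet_K + logdet_S + df * (np.log(sigma_p2) + 1.0)
        )
    else:
        ll = -0.5 * (df * np.log(2 * np.pi) + logdet_K + df * (np.log(sigma_p2) + 1.0))
    return float(ll), float(sigma_p2), beta


def _maximize_h2(profile, h2_bounds, tol, max_evals):
    """Bounded scalar maximization of a profile log-likelihood over h2.

    ``profile(h2) -> (loglik, sigma_p2, beta)``.  Returns the optimum plus
    convergence/boundary/flat diagnostics shared by the predictive-process
    and dense GREML fitters.
    """
    lo = max(h2_bounds[0], 0.0)
    hi = min(h2_bounds[1], 1.0 - _H2_EPS)
    n_evals = 0

    def negll(h2):
        nonlocal n_evals
        n_evals += 1
        return -profile(h2)[0]

    res = optimize.minimize_scalar(
        negll,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol, "maxiter": max_evals},
    )
    h2_hat = float(res.x)
    ll_hat = -float(res.fun)

    # Flat-likelihood detection (e.g. A = I makes h2 unidentifiable).
    probes = [profile(h)[0] for h in (lo + 1e-6 * (hi - lo), 0.5 * (lo + hi), hi)]
    spread = max(probes + [ll_hat]) - min(probes + [ll_hat])
    flat = spread < 1e-8 * max(1.0, abs(ll_hat))
    if flat:
        warnings.warn(
            "profile likelihood is flat in h2 (non-identifiable variance "
            "components, e.g. GRM numerically equal to I)",
            RuntimeWarning,
            stacklevel=3,
        )

    boundary = h2_hat <= lo + _BOUNDARY_TOL or h2_hat >= hi - _BOUNDARY_TOL
    return h2_hat, ll_hat, bool(res.success), n_evals + 3, boundary, flat


def fit_predlmm(
    y: np.ndarray,
    X: np.ndarray | None,
    factor: PPFactor,
    reml: bool = True,
    h2_bounds: tuple[float, float] = (0.0, 1.0),
    tol: float = 1e-6,
    max_evals: int = 200,
    add_intercept: bool = True,
    compute_se: bool = True,
) -> HeritabilityFit:
    """Maximize the predictive-process (restricted) likelihood over h2 in [0,1].

    ``X`` holds covariates (an intercept is prepended unless
    ``add_intercept=False``).  sigma_p^2 is profiled in closed form at each
    h2; ``beta_hat`` is GLS at the optimum.  Boundary maxima are reported
    via ``boundary_flag``, not errored; the asymptotic standard error is
    attached when the fit is interior.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values; filter to complete cases first")
    X = _design(X, y.size, add_intercept)
    if y.size != factor.n_samples:
        raise ValueError("y length does not match the factor's sample count")

    h2_hat, ll, ok, n_evals, boundary, flat = _maximize_h2(
        lambda h: _pp_profile(h, y, X, factor, reml), h2_bounds, tol, max_evals
    )
    _, sigma_p2, beta = _pp_profile(h2_hat, y, X, factor, reml)
    fit = HeritabilityFit(
        h2_hat=h2_hat,
        sigma_h2=h2_hat * sigma_p2,
        sigma_e2=(1.0 - h2_hat) * sigma_p2,
        beta_hat=beta,
        loglik=ll,
        reml=reml,
        n_evaluations=n_evals,
        converged=ok,
        boundary_flag=boundary,
        flat=flat,
        method="predlmm",
        r=factor.r,
    )
    if compute_se and not boundary and not flat:
        try:
            fit.se_h2 = asymptotic_se(fit, factor, X, add_intercept=False)
        except (linalg.LinAlgError, ValueError):
            fit.se_h2 = None
    return fit


def _lowrank_traces(delta, Ud, Rc, X, e, U, reml):
    """tr(P A P A), tr(P A P), tr(P P) for P the (RE)ML projection.

    P = D - L L' with D = diag(1/Delta);  A = diag(e) + U U'.  All traces
    are assembled from diagonal/low-rank products in O(N (r+p)^2).
    """
    n = delta.size
    dinv = 1.0 / delta
    # V^-1 = D - W1 W1'
    W1 = linalg.solve_triangular(Rc, Ud.T, trans="T", lower=False).T
    if reml:
        F = _vinv_apply(X, delta, Ud, Rc)
        S = X.T @ F
        Rs = linalg.cholesky((S + S.T) / 2.0, lower=False)
        F2 = linalg.solve_triangular(Rs, F.T, trans="T", lower=False).T
        L = np.column_stack([W1, F2])
    else:
        L = W1

    LtL = L.T @ L
    Lsq = np.einsum("ij,ij->i", L, L)

    # tr(P P)
    tr_pp = float((dinv**2).sum() - 2.0 * (dinv * Lsq).sum() + (LtL**2).sum())

    # tr(P A P) = tr(A P^2);  P^2 = D^2 + G H'
    DL = L * dinv[:, None]
    G = np.column_stack([DL, L])
    H = np.column_stack([-L, -DL + L @ LtL])
    UtG = U.T @ G
    UtH = U.T @ H
    tr_apap_lin = float(
        (e * dinv**2).sum()
        + ((U * dinv[:, None] ** 2) * U).sum()
        + (e[:, None] * G * H).sum()
        + (UtG * UtH).sum()
    )

    # tr(P A P A) = tr((P A)^2);  P A = diag(e/Delta) + Q R'
    m = e * dinv
    LtU = L.T @ U
    Q = np.column_stack([U * dinv[:, None] - L @ LtU, -L])
    Rm = np.column_stack([U, e[:, None] * L])
    M = Rm.T @ Q
    tr_apap = float((m**2).sum() + 2.0 * (m * np.einsum("ij,ij->i", Q, Rm)).sum() + (M * M.T).sum())
    return tr_apap, tr_apap_lin, tr_pp


def asymptotic_se(
    fit: HeritabilityFit,
    factor: PPFactor,
    X: np.ndarray | None,
    add_intercept: bool = True,
) -> float:
    """Approximate asymptotic standard error of the h^2 estimate.

    Inverts the 2 x 2 Fisher information of (sigma_h^2, sigma_e^2),
    I_jk = tr(P V_j P V_k) / 2 with V_1 = A_pp, V_2 = I and P the (RE)ML
    projection, all traces evaluated through the low-rank structure in
    O(N r^2 + r^3), then applies the delta method to h^2.  Undefined at a
    boundary or flat fit.
    """
    if fit.boundary_flag or fit.flat:
        raise ValueError(
            "asymptotic SE is undefined at a boundary/flat fit "
            f"(h2_hat={fit.h2_hat:.4g}); report the estimate without an SE"
        )
    n = factor.n_samples
    X = _design(X, n, add_intercept)

    delta = fit.sigma_h2 * factor.d_res + fit.sigma_e2
    Uc = np.sqrt(fit.sigma_h2) * factor.U
    Ud, Rc, _ = _woodbury_pieces(delta, Uc)
    tr_apap, tr_ap, tr_pp = _lowrank_traces(
        delta, Ud, Rc, X, factor.d_res, factor.U, fit.reml
    )
    info = 0.5 * np.array([[tr_apap, tr_ap], [tr_ap, tr_pp]])
    cov = np.linalg.inv(info)

    a, b = fit.sigma_h2, fit.sigma_e2
    grad = np.array([b, -a]) / (a + b) ** 2
    var_h2 = float(grad @ cov @ grad)
    if var_h2 <= 0:
        raise linalg.LinAlgError("Fisher information is not positive definite")
    return float(np.sqrt(var_h2))
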
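"""Linear mixed-model machinery: MME solves and EM-REML.

Two model families are supported, both through Henderson's mixed-model
equations (MME) with the residual written as ``e ~ N(0, I sigma_e^2)``:

* a random-regression family with one correlated effect vector per genotype,
  ``u ~ N(0, Sigma (x) A)`` where ``Sigma`` is the (K+1)x(K+1) covariance of
  (intercept, K reaction-norm slopes) and ``A`` the additive relationship
  matrix (``(x)`` is the Kronecker product, effect-major ordering);
* a sum of independent components ``u_i ~ N(0, sigma_i^2 I)`` given through
  factor matrices ``Z_i`` (any covariance ``K = LL'`` is absorbed into the
  factor, so kernel models reduce to this form).

The restricted log-likelihood is always evaluated through the MME
determinant identity

    -2 l_R = n log sigma_e^2 + log|G| + log|C| + y'Py,

which avoids forming the n x n phenotypic covariance. The Kronecker family
is fitted by exact-gradient quasi-Newton (L-BFGS) on an unconstrained
Cholesky parameterization of Sigma — near-singular Sigma, routine when the
markers are strongly correlated, is then a smooth interior point rather
than a constrained boundary where EM crawls. The iid-component family is
fitted by classic EM-REML (cheap, monotone iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.linalg.lapack import dpotri

_SIGMA_FLOOR = 1e-10


class DesignError(ValueError):
    """The fixed-effect design is rank-deficient or misaligned."""


def _as_matrix(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a.reshape(len(a), -1) if a.ndim == 1 else a


def _bend_psd(S: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues so S is symmetric positive semidefinite (and invertible)."""
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    floor = max(_SIGMA_FLOOR, floor_frac * max(w.max(), _SIGMA_FLOOR))
    if w.min() >= floor:
        return S
    w = np.clip(w, floor, None)
    return (V * w) @ V.T


@dataclass
class ReemFit:
    """Result of one random-regression REML fit."""

    b: np.ndarray                 # fixed effects (one per X column)
    fixed_names: list
    Sigma: np.ndarray             # (K+1)x(K+1)
    sigma_e2: float
    U: np.ndarray                 # genotypes x (K+1) BLUPs (intercept, slopes)
    genotype_ids: list
    loglik_reml: float
    converged: bool
    n_iter: int
    structure: str = "unstructured"
    markers_used: list = field(default_factory=list)

    def predict_records(self, X: np.ndarray, M: np.ndarray, geno_idx: np.ndarray) -> np.ndarray:
        """Predicted values for records with marker design M (incl. leading 1s)."""
        return X @ self.b + np.einsum("ij,ij->i", M, self.U[geno_idx])


def _build_mme(XtX, XtZ, ZtZ, Xty, Zty, Ginv, sigma_e2):
    p, q = XtX.shape[0], ZtZ.shape[0]
    C = np.empty((p + q, p + q))
    C[:p, :p] = XtX / sigma_e2
    C[:p, p:] = XtZ / sigma_e2
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = ZtZ / sigma_e2 + Ginv
    rhs = np.concatenate([Xty, Zty]) / sigma_e2
    return C, rhs


def solve_mme_kron(y, X, M, geno_idx, A, Sigma, sigma_e2):
    """BLUE/BLUP at fixed variance components for the Kronecker model.

    Parameters
    ----------
    M : (n, K+1) array
        Per-record random-effect covariables; first column is 1 (intercept).
    geno_idx : (n,) int array
        Row of ``A`` (and of the BLUP matrix) for each record.
    A : (G, G) array
        Additive relationship matrix over all genotypes, including any that
        never appear in ``geno_idx`` (their BLUPs propagate through A).

    Returns
    -------
    b : (p,) fixed-effect solutions
    U : (G, K+1) BLUP matrix
    """
    y = np.asarray(y, dtype=float)
    X = _as_matrix(X)
    M = _as_matrix(M)
    n, p = X.shape
    G = A.shape[0]
    r = M.shape[1]
    Z = np.zeros((n, r * G))
    Z[np.arange(n)[:, None], np.arange(r)[None, :] * G + np.asarray(geno_idx)[:, None]] = M

    Ainv = np.linalg.inv(A)
    Ginv = np.kron(np.linalg.inv(_bend_psd(Sigma)), Ainv)
    C, rhs = _build_mme(X.T @ X, X.T @ Z, Z.T @ Z, X.T @ y, Z.T @ y, Ginv, sigma_e2)
    sol = cho_solve(cho_factor(C, lower=True), rhs)
    b = sol[:p]
    U = sol[p:].reshape(r, G).T
    return b, U


def fit_reml_kron(
    y,
    X,
    M,
    geno_idx,
    A,
    structure: str = "unstructured",
    max_iter: int = 200,
    tol: float = 1e-8,
    init_Sigma=None,
    init_sigma_e2=None,
    fixed_names=None,
    genotype_ids=None,
) -> ReemFit:
    """REML for ``y = Xb + Zu + e`` with ``u ~ N(0, Sigma (x) A)``.

    ``structure`` is ``"unstructured"`` (full Sigma) or ``"diagonal"``
    (independent intercept and slopes). Convergence is declared when the
    restricted log-likelihood can no longer be improved by more than
    ``tol`` relative (L-BFGS ftol, confirmed across restarts).
    """
    y = np.asarray(y, dtype=float)
    X = _as_matrix(X)
    M = _as_matrix(M)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("fixed-effect design matrix is rank deficient")
    if n <= p:
        raise DesignError("need more records than fixed effects")
    G = A.shape[0]
    r = M.shape[1]
    geno_idx = np.asarray(geno_idx, dtype=int)

    Z = np.zeros((n, r * G))
    Z[np.arange(n)[:, None], np.arange(r)[None, :] * G + geno_idx[:, None]] = M
    Z_t = Z.T

    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    Xty, Zty, yty = X.T @ y, Z.T @ y, float(y @ y)
    Ainv = np.linalg.inv(A)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        raise DesignError("A must be positive definite (apply psd_repair first)")

    vary = max(float(np.var(y)), _SIGMA_FLOOR)
    Sigma = np.eye(r) * (0.5 * vary / r) if init_Sigma is None else _bend_psd(np.array(init_Sigma, dtype=float))
    sigma_e2 = 0.5 * vary if init_sigma_e2 is None else float(init_sigma_e2)

    # Unconstrained parameterization: Sigma = L L' + eps I through the lower
    # triangle of L (diagonal-only under structure="diagonal") and log
    # residual variance. A singular optimal Sigma — the usual case when the
    # markers are strongly inter-correlated — is then an interior smooth
    # point (an L column shrinking to zero) instead of a constrained
    # boundary, and quasi-Newton iterations converge normally.
    eps_ridge = 1e-6 * vary
    if structure == "diagonal":
        lidx = (np.arange(r), np.arange(r))
    else:
        lidx = np.tril_indices(r)

    def _theta_to_params(theta):
        L = np.zeros((r, r))
        L[lidx] = theta[:-1]
        S = L @ L.T + eps_ridge * np.eye(r)
        return L, S, float(np.exp(np.clip(theta[-1], -300.0, 60.0)))

    def _m2l_and_grad(theta):
        L, S, e2 = _theta_to_params(theta)
        SigInv = np.linalg.inv(S)
        Ginv = np.kron(SigInv, Ainv)
        C, rhs = _build_mme(XtX, XtZ, ZtZ, Xty, Zty, Ginv, e2)
        # clean (zero-filled) factor: dpotri below reads one full triangle
        cf = (cholesky(C, lower=True), True)
        sol = cho_solve(cf, rhs)
        b, u = sol[:p], sol[p:]
        U = u.reshape(r, G).T

        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        yPy = (yty - b @ Xty - u @ Zty) / e2
        m2l = n * np.log(e2) + G * np.linalg.slogdet(S)[1] + r * logdetA + logdetC + yPy

        # C^{-1} from the Cholesky factor (dpotri fills the lower triangle)
        inv_tri, info = dpotri(cf[0], lower=True)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed on the MME matrix")
        Cinv = np.tril(inv_tri) + np.tril(inv_tri, -1).T
        Cuu = Cinv[p:, p:]
        T = np.empty((r, r))
        for a in range(r):
            for bb in range(a, r):
                blk = Cuu[a * G:(a + 1) * G, bb * G:(bb + 1) * G]
                T[a, bb] = T[bb, a] = float(np.sum(Ainv * blk))

        eP = (y - X @ b - np.einsum("na,an->n", M, U.T[:, geno_idx])) / e2
        W = (Z_t @ eP).reshape(r, G)
        WQ = W @ (A @ W.T)                     # WQ[a, b] = w_a' A w_b

        # dl/dSigma (symmetric-matrix calculus): -0.5 (G SigInv - H - WQ)
        H = SigInv @ T @ SigInv
        Dsym = -0.5 * (G * SigInv - H - WQ)
        grad_L = -4.0 * (Dsym @ L)             # d(-2l)/dL
        t_uu = float(np.sum(SigInv * T))
        trP = (n - p - r * G + t_uu) / e2
        score_e = -0.5 * (trP - eP @ eP)
        grad = np.empty(len(theta))
        grad[:-1] = grad_L[lidx]
        grad[-1] = -2.0 * score_e * e2         # d(-2l)/d log e2
        return m2l, grad

    from scipy.optimize import minimize

    S0 = _bend_psd(Sigma, 1e-8) + 1e-6 * vary * np.eye(r)
    x = np.concatenate([np.linalg.cholesky(S0)[lidx], [np.log(max(sigma_e2, _SIGMA_FLOOR))]])
    # L-BFGS can stall in a line search on the flat near-singular directions
    # before meeting ftol; restart from the stalled point and declare
    # convergence when a restart no longer improves -2 loglik beyond tol.
    converged = False
    it = 0
    f_last = np.inf
    for _attempt in range(5):
        res = minimize(
            _m2l_and_grad,
            x,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": max(max_iter - it, 1),
                "maxfun": 4 * max_iter,
                "ftol": tol,
                "gtol": 1e-7,
            },
        )
        it += max(int(res.nit), 1)
        x = res.x
        if res.success:
            converged = True
            break
        if abs(f_last - res.fun) < tol * (abs(res.fun) + 1.0):
            converged = True
            break
        f_last = res.fun
        if it >= max_iter:
            break
    _, Sigma, sigma_e2 = _theta_to_params(x)

    if structure == "diagonal":
        Sigma = np.diag(np.diag(Sigma))
    # final solve so BLUE/BLUP and loglik correspond to the reported parameters
    Sigma = _bend_psd(Sigma)
    Ginv = np.kron(np.linalg.inv(Sigma), Ainv)
    C, rhs = _build_mme(XtX, XtZ, ZtZ, Xty, Zty, Ginv, sigma_e2)
    cf = cho_factor(C, lower=True)
    sol = cho_solve(cf, rhs)
    b, u = sol[:p], sol[p:]
    U = u.reshape(r, G).T
    logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
    yPy = (yty - b @ Xty - u @ Zty) / sigma_e2
    loglik = -0.5 * (
        n * np.log(sigma_e2)
        + G * np.linalg.slogdet(Sigma)[1]
        + r * logdetA
        + logdetC
        + yPy
    )
    return ReemFit(
        b=b,
        fixed_names=list(fixed_names) if fixed_names is not None else [f"x{i}" for i in range(p)],
        Sigma=_bend_psd(Sigma),
        sigma_e2=float(sigma_e2),
        U=U,
        genotype_ids=list(genotype_ids) if genotype_ids is not None else list(range(G)),
        loglik_reml=float(loglik),
        converged=converged,
        n_iter=it,
        structure=structure,
    )


@dataclass
class ComponentsFit:
    """REML fit for a sum of independent factored random components."""

    b: np.ndarray
    fixed_names: list
    variances: dict        # component name -> sigma_i^2
    sigma_e2: float
    blups: dict            # component name -> u_i (aligned with the factor columns)
    loglik_reml: float
    converged: bool
    n_iter: int

    def predict(self, X_new, factors_new: dict) -> np.ndarray:
        """Predictions for new records given their factor rows."""
        yhat = _as_matrix(X_new) @ self.b
        for name, Znew in factors_new.items():
            yhat = yhat + _as_matrix(Znew) @ self.blups[name]
        return yhat


def fit_reml_components(
    y,
    X,
    factors: dict,
    max_iter: int = 1000,
    tol: float = 1e-8,
    init=None,
    fixed_names=None,
) -> ComponentsFit:
    """REML for ``y = Xb + sum_i Z_i u_i + e`` with iid ``u_i``.

    ``factors`` maps component names to their (n, q_i) factor matrices; a
    component with covariance ``sigma^2 K`` enters through any factor ``L``
    with ``K = LL'``. Variances are optimised on the log scale by L-BFGS
    with exact gradients (components on the zero boundary become smooth
    flat directions), with the same restart-until-stationary convergence
    rule as the Kronecker fitter.
    """
    y = np.asarray(y, dtype=float)
    X = _as_matrix(X)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("fixed-effect design matrix is rank deficient")
    names = list(factors)
    Zs = [_as_matrix(factors[k]) for k in names]
    qs = [Z.shape[1] for Z in Zs]
    Z = np.hstack(Zs)
    q = Z.shape[1]
    offsets = np.concatenate([[0], np.cumsum(qs)])

    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    Xty, Zty, yty = X.T @ y, Z.T @ y, float(y @ y)

    vary = max(float(np.var(y)), _SIGMA_FLOOR)
    if init is None:
        var = {k: 0.5 * vary / max(len(names), 1) for k in names}
        sigma_e2 = 0.5 * vary
    else:
        var = {k: float(init[k]) for k in names}
        sigma_e2 = float(init["residual"])
    floor = _SIGMA_FLOOR * vary

    def _theta_to_var(theta):
        v = np.exp(np.clip(theta, -300.0, 60.0))
        return np.maximum(v[:-1], floor), max(float(v[-1]), floor)

    def _m2l_and_grad(theta):
        vs, e2 = _theta_to_var(theta)
        ginv_diag = np.concatenate(
            [np.full(qs[i], 1.0 / vs[i]) for i in range(len(names))]
        )
        C, rhs = _build_mme(XtX, XtZ, ZtZ, Xty, Zty, np.diag(ginv_diag), e2)
        cf = (cholesky(C, lower=True), True)
        sol = cho_solve(cf, rhs)
        b, u = sol[:p], sol[p:]

        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        yPy = (yty - b @ Xty - u @ Zty) / e2
        logdetG = float(np.sum(np.array(qs) * np.log(vs)))
        m2l = n * np.log(e2) + logdetG + logdetC + yPy

        inv_tri, info = dpotri(cf[0], lower=True)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed on the MME matrix")
        Cinv = np.tril(inv_tri) + np.tril(inv_tri, -1).T
        eP = (y - X @ b - Z @ u) / e2
        ZtP = Z.T @ eP

        grad = np.empty(len(theta))
        t_uu = 0.0
        for i in range(len(names)):
            sl = slice(p + offsets[i], p + offsets[i + 1])
            tr_ii = float(np.trace(Cinv[sl, sl]))
            t_uu += tr_ii / vs[i]
            trP_dV = qs[i] / vs[i] - tr_ii / vs[i] ** 2
            quad = float(ZtP[offsets[i]:offsets[i + 1]] @ ZtP[offsets[i]:offsets[i + 1]])
            score = -0.5 * (trP_dV - quad)
            grad[i] = -2.0 * score * vs[i]            # d(-2l)/d log sigma_i^2
        trP = (n - p - q + t_uu) / e2
        score_e = -0.5 * (trP - eP @ eP)
        grad[-1] = -2.0 * score_e * e2
        return m2l, grad

    from scipy.optimize import minimize

    x = np.log(np.concatenate([[max(var[k], floor) for k in names], [sigma_e2]]))
    converged = False
    it = 0
    f_last = np.inf
    for _attempt in range(5):
        res = minimize(
            _m2l_and_grad, x, jac=True, method="L-BFGS-B",
            options={"maxiter": max(max_iter - it, 1), "maxfun": 4 * max_iter,
                     "ftol": tol, "gtol": 1e-7},
        )
        it += max(int(res.nit), 1)
        x = res.x
        if res.success:
            converged = True
            break
        if abs(f_last - res.fun) < tol * (abs(res.fun) + 1.0):
            converged = True
            break
        f_last = res.fun
        if it >= max_iter:
            break
    vs, sigma_e2 = _theta_to_var(x)
    var = {k: float(vs[i]) for i, k in enumerate(names)}

    # final solve at the reported variances
    ginv_diag = np.concatenate(
        [np.full(qs[i], 1.0 / max(var[k], floor)) for i, k in enumerate(names)]
    )
    C, rhs = _build_mme(XtX, XtZ, ZtZ, Xty, Zty, np.diag(ginv_diag), sigma_e2)
    cf = cho_factor(C, lower=True)
    sol = cho_solve(cf, rhs)
    b, u = sol[:p], sol[p:]
    logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
    yPy = (yty - b @ Xty - u @ Zty) / sigma_e2
    logdetG = sum(qs[i] * np.log(max(var[k], floor)) for i, k in enumerate(names))
    loglik = -0.5 * (n * np.log(sigma_e2) + logdetG + logdetC + yPy)

    blups = {k: u[offsets[i]:offsets[i + 1]] for i, k in enumerate(names)}
    return ComponentsFit(
        b=b,
        fixed_names=list(fixed_names) if fixed_names is not None else [f"x{i}" for i in range(p)],
        variances=dict(var),
        sigma_e2=float(sigma_e2),
        blups=blups,
        loglik_reml=float(loglik),
        converged=converged,
        n_iter=it,
    )


def conditional_mean_oracle(y, X, Z, Gmat, sigma_e2):
    """Dense joint-normal GLS/conditional-mean solve (small instances only).

    Independent of the MME path: forms ``V = Z G Z' + I sigma_e^2`` explicitly,
    computes the GLS fixed effects and ``u_hat = G Z' V^{-1} (y - X b_hat)``.
    """
    y = np.asarray(y, dtype=float)
    X = _as_matrix(X)
    Z = _as_matrix(Z)
    V = Z @ Gmat @ Z.T + sigma_e2 * np.eye(len(y))
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    b = np.linalg.solve(XtVinv @ X, XtVinv @ y)
    u = Gmat @ Z.T @ (Vinv @ (y - X @ b))
    return b, u
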
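"""Laplace-approximate logistic regression with grouped random effects.

Fits y_ij ~ Bernoulli(logit^-1(x_ij' beta + z_ij' u_j)), u_j ~ N(0, D), by
maximizing the Laplace approximation to the marginal likelihood over the
Cholesky factor of D, with a weak Gaussian ridge (SD 10 on the log-odds
scale) on the fixed effects to tame separation in small groups.  The inner
problem (joint mode of beta and all u_j) is solved by Newton iterations that
exploit the arrowhead structure of the Hessian, so cohorts of hundreds of
sessions fit in seconds.

The random-effect covariance is unstructured by default and falls back to a
diagonal when fewer than 30 groups are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

_LOG_SD_LO, _LOG_SD_HI = np.log(1e-4), np.log(5.0)


@dataclass
class MixedLogitFit:
    """Result of a Laplace mixed-logistic fit."""

    fixed: np.ndarray                 # (p,) fixed effects, log-odds scale
    fixed_se: np.ndarray              # (p,) approximate standard errors
    fixed_names: List[str]
    ranef_cov: np.ndarray             # (q, q) random-effect covariance D
    blups: Dict[object, np.ndarray]   # group label -> (q,) posterior mode of u_j
    loglik: float                     # Laplace marginal log-likelihood
    converged: bool
    n_obs: int
    n_groups: int
    cov_structure: str
    diagnostics: dict = field(default_factory=dict)


def _segment_sums(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Sum rows of ``values`` within contiguous segments starting at ``starts``."""
    flat = values.reshape(values.shape[0], -1)
    out = np.add.reduceat(flat, starts, axis=0)
    return out.reshape((len(starts),) + values.shape[1:])


class _Workspace:
    """Group-sorted data plus warm-started inner-mode state."""

    def __init__(self, X, y, Z, groups):
        order = np.argsort(groups, kind="stable")
        self.X = np.asarray(X, float)[order]
        self.y = np.asarray(y, float)[order]
        self.Z = np.asarray(Z, float)[order]
        g = np.asarray(groups)[order]
        self.labels, self.starts = np.unique(g, return_index=True)
        self.starts = np.sort(self.starts)
        self.n, self.p = self.X.shape
        self.q = self.Z.shape[1]
        self.J = len(self.labels)
        self.beta = np.zeros(self.p)
        self.u = np.zeros((self.J, self.q))
        # row -> group index for broadcasting u
        self.gidx = np.repeat(np.arange(self.J), np.diff(np.append(self.starts, self.n)))


def _inner_mode(ws: _Workspace, P: np.ndarray, ridge_prec: float,
                max_iter: int = 60, tol: float = 1e-9):
    """Joint Newton for (beta, u) at fixed random-effect precision P."""
    beta, u = ws.beta.copy(), ws.u.copy()
    X, y, Z, starts, gidx = ws.X, ws.y, ws.Z, ws.starts, ws.gidx

    def objective(beta, u):
        eta = X @ beta + np.einsum("ij,ij->i", Z, u[gidx])
        # log Bernoulli likelihood, stable
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        pen = 0.5 * np.einsum("jk,kl,jl->", u, P, u) + 0.5 * ridge_prec * beta @ beta
        return ll - pen, eta

    Q, eta = objective(beta, u)
    info = {"iterations": 0, "converged": False}
    for it in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        resid = y - mu
        g_beta = X.T @ resid - ridge_prec * beta
        g_u = _segment_sums(Z * resid[:, None], starts) - u @ P
        # per-group blocks
        Zw = Z * w[:, None]
        C = _segment_sums(Zw[:, :, None] * Z[:, None, :], starts) + P  # (J,q,q)
        B = _segment_sums(ws.X[:, :, None] * Zw[:, None, :], starts)   # (J,p,q)
        H_bb = (X * w[:, None]).T @ X + ridge_prec * np.eye(ws.p)
        Cinv_gu = np.linalg.solve(C, g_u[:, :, None])[:, :, 0]
        Cinv_Bt = np.linalg.solve(C, np.transpose(B, (0, 2, 1)))       # (J,q,p)
        S = H_bb - np.einsum("jpq,jqr->pr", B, Cinv_Bt)
        rhs = g_beta - np.einsum("jpq,jq->p", B, Cinv_gu)
        d_beta = np.linalg.solve(S, rhs)
        d_u = Cinv_gu - np.einsum("jqp,p->jq", Cinv_Bt, d_beta)
        # line search with step halving
        step = 1.0
        for _ in range(30):
            nb, nu = beta + step * d_beta, u + step * d_u
            Qn, eta_n = objective(nb, nu)
            if Qn >= Q - 1e-12:
                break
            step *= 0.5
        gain = Qn - Q
        beta, u, Q, eta = nb, nu, Qn, eta_n
        info["iterations"] = it + 1
        if abs(gain) < tol * (abs(Q) + 1.0):
            info["converged"] = True
            break
    ws.beta, ws.u = beta, u
    # quantities for the Laplace criterion at the mode
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    Zw = Z * w[:, None]
    C = _segment_sums(Zw[:, :, None] * Z[:, None, :], starts) + P
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    u_pen = 0.5 * np.einsum("jk,kl,jl->", u, P, u)
    ridge_pen = 0.5 * ridge_prec * beta @ beta
    sign_P, logdet_P = np.linalg.slogdet(P)
    logdet_C = np.linalg.slogdet(C)[1]
    laplace = ll - u_pen - ridge_pen - 0.5 * float(np.sum(logdet_C) - ws.J * logdet_P)
    # Schur complement for fixed-effect covariance
    B = _segment_sums(ws.X[:, :, None] * Zw[:, None, :], starts)
    H_bb = (X * w[:, None]).T @ X + ridge_prec * np.eye(ws.p)
    Cinv_Bt = np.linalg.solve(C, np.transpose(B, (0, 2, 1)))
    S = H_bb - np.einsum("jpq,jqr->pr", B, Cinv_Bt)
    return laplace, C, S, info


def _theta_to_chol(theta: np.ndarray, q: int, structure: str) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.diag_indices(q)] = np.exp(np.clip(theta[:q], _LOG_SD_LO, _LOG_SD_HI))
    if structure == "unstructured":
        L[np.tril_indices(q, -1)] = theta[q:]
    return L


def fit_mixed_logit(
    X: np.ndarray,
    y: np.ndarray,
    groups: Sequence,
    Z: Optional[np.ndarray] = None,
    fixed_names: Optional[Sequence[str]] = None,
    cov_structure: str = "auto",
    ridge_sd: float = 10.0,
    init_ranef_sd: float = 0.3,
    maxiter: int = 200,
) -> MixedLogitFit:
    """Fit the mixed logistic model; see module docstring.

    ``Z`` defaults to ``X`` (random effect for every fixed effect, the layout
    of the stay-probability model).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if Z is None:
        Z = X
    ws = _Workspace(X, y, Z, groups)
    if cov_structure == "auto":
        cov_structure = "unstructured" if ws.J >= 30 else "diagonal"
    if cov_structure not in ("unstructured", "diagonal"):
        raise ValueError(f"unknown cov_structure {cov_structure!r}")
    q = ws.q
    ridge_prec = 1.0 / ridge_sd**2

    n_off = q * (q - 1) // 2 if cov_structure == "unstructured" else 0
    theta0 = np.concatenate([np.full(q, np.log(init_ranef_sd)), np.zeros(n_off)])

    def neg_laplace(theta):
        L = _theta_to_chol(theta, q, cov_structure)
        D = L @ L.T + 1e-10 * np.eye(q)
        P = np.linalg.inv(D)
        lap, _, _, _ = _inner_mode(ws, P, ridge_prec)
        return -lap

    bounds = [(_LOG_SD_LO, _LOG_SD_HI)] * q + [(-5.0, 5.0)] * n_off
    res = optimize.minimize(
        neg_laplace, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-9, "eps": 1e-4},
    )
    L = _theta_to_chol(res.x, q, cov_structure)
    D = L @ L.T
    P = np.linalg.inv(D + 1e-10 * np.eye(q))
    laplace, C, S, inner_info = _inner_mode(ws, P, ridge_prec, max_iter=200)
    cov_beta = np.linalg.inv(S)
    fit = MixedLogitFit(
        fixed=ws.beta.copy(),
        fixed_se=np.sqrt(np.diag(cov_beta)),
        fixed_names=list(fixed_names) if fixed_names is not None
        else [f"x{i}" for i in range(ws.p)],
        ranef_cov=D,
        blups={lab: ws.u[j].copy() for j, lab in enumerate(ws.labels)},
        loglik=float(laplace),
        converged=bool(res.success and inner_info["converged"]),
        n_obs=ws.n,
        n_groups=ws.J,
        cov_structure=cov_structure,
        diagnostics={
            "outer_message": str(res.message),
            "outer_nit": int(res.nit),
            "inner_iterations": inner_info["iterations"],
            "fixed_cov": cov_beta,
        },
    )
    return fit
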
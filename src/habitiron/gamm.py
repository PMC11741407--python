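"""Penalized-spline mixed models for developmental trajectories.

Gaussian additive mixed models of the form

    y_it = b0 + b1*sex_i + b2*visit_it + f(age_it) [+ f(x)*Behavior terms]
           + subject_i + e_it

where each f is a low-rank natural cubic regression spline (default basis
dimension 3, quantile-placed knots, integrated-squared-second-derivative
penalty) and the subject intercept is an i.i.d. Gaussian random effect
absorbed as one more quadratic penalty.  Smoothing parameters and variance
components are chosen by exact Gaussian REML (single-model summaries) or ML
(whenever models are compared), computed in the mixed-model
reparameterization via the Woodbury identity.

Also provided: Wald-type smooth significance tests in the (edf, F, p)
reporting format, the four-model AIC/analysis-of-deviance selection ladder,
varying-coefficient (time-varying) terms f(age)*Behavior, posterior-
simulation windows of significance on the coefficient curve or its finite-
difference first derivative, marginal-effect trajectories at fixed behavior
levels, age residualization, and a Bonferroni helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "SmoothSpec", "GAMMSpec", "GAMMFit", "WindowResult", "CubicSplineBasis",
    "build_basis", "fit_gamm", "smooth_significance", "residualize_age",
    "compare_model_ladder", "derivative_windows", "marginal_trajectories",
    "bonferroni",
]


class CubicSplineBasis:
    """Natural cubic spline parameterized by its values at ``k`` knots.

    The evaluation matrix maps knot values g to f(x) (natural-spline
    interpolation inside the knot range, linear extrapolation outside); the
    penalty is the integrated squared second derivative, a quadratic form in
    g with null space equal to the linear functions.
    """

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, float)
        if len(knots) < 3 or np.any(np.diff(knots) <= 0):
            raise ValueError("need >= 3 strictly increasing knots")
        self.knots = knots
        k = len(knots)
        h = np.diff(knots)
        # Green & Silverman tridiagonal construction: gamma = W^{-1} Delta g
        delta = np.zeros((k - 2, k))
        W = np.zeros((k - 2, k - 2))
        for i in range(k - 2):
            delta[i, i] = 1.0 / h[i]
            delta[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            delta[i, i + 2] = 1.0 / h[i + 1]
            W[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
        self._gamma_map = np.zeros((k, k))          # g -> second derivatives at knots
        self._gamma_map[1:-1] = np.linalg.solve(W, delta)
        self.penalty = delta.T @ np.linalg.solve(W, delta)

    @property
    def k(self) -> int:
        return len(self.knots)

    def design(self, x: np.ndarray) -> np.ndarray:
        """Evaluation matrix E with f(x) = E @ g."""
        x = np.asarray(x, float)
        xi = self.knots
        k = len(xi)
        h = np.diff(xi)
        E = np.zeros((len(x), k))
        G = self._gamma_map
        idx = np.clip(np.searchsorted(xi, x, side="right") - 1, 0, k - 2)
        inside = (x >= xi[0]) & (x <= xi[-1])
        for r, (xv, i) in enumerate(zip(x, idx)):
            if inside[r]:
                hi = h[i]
                a = (xi[i + 1] - xv) / hi
                b = (xv - xi[i]) / hi
                row = np.zeros(k)
                row[i] += a
                row[i + 1] += b
                # f(x) = a g_i + b g_{i+1} + ((a^3 - a) gamma_i + (b^3 - b) gamma_{i+1}) h^2/6
                row = row + ((a**3 - a) * G[i] + (b**3 - b) * G[i + 1]) * hi**2 / 6.0
                E[r] = row
            else:
                # linear extrapolation using boundary value and slope
                if xv < xi[0]:
                    j, hj, sgn = 0, h[0], 1.0
                    # f'(xi_0) = (g1 - g0)/h0 - h0/6 (2 gamma_0 + gamma_1)
                    slope = np.zeros(k)
                    slope[0] -= 1.0 / hj
                    slope[1] += 1.0 / hj
                    slope = slope - hj / 6.0 * (2.0 * G[0] + G[1])
                    base = np.zeros(k)
                    base[0] = 1.0
                    E[r] = base + (xv - xi[0]) * slope
                else:
                    hj = h[-1]
                    slope = np.zeros(k)
                    slope[k - 2] -= 1.0 / hj
                    slope[k - 1] += 1.0 / hj
                    slope = slope + hj / 6.0 * (2.0 * G[k - 1] + G[k - 2])
                    base = np.zeros(k)
                    base[k - 1] = 1.0
                    E[r] = base + (xv - xi[-1]) * slope
        return E


def build_basis(x: np.ndarray, k: int = 3) -> Tuple[np.ndarray, np.ndarray, CubicSplineBasis, np.ndarray]:
    """Centered spline design for the data ``x``.

    Returns ``(X_c, S_c, basis, Zc)`` where ``X_c`` is the n x (k-1)
    sum-to-zero-constrained design, ``S_c`` the matching penalty, ``basis``
    the underlying spline object and ``Zc`` the k x (k-1) constraint
    null-space map (g = Zc @ alpha).
    """
    x = np.asarray(x, float)
    uniq = np.unique(x)
    if len(uniq) < k:
        raise ValueError(f"need at least {k} distinct covariate values, got {len(uniq)}")
    knots = np.quantile(uniq, np.linspace(0.0, 1.0, k))
    basis = CubicSplineBasis(knots)
    E = basis.design(x)
    c = E.sum(axis=0)[:, None]          # sum-to-zero over the data
    q, _ = np.linalg.qr(c, mode="complete")
    Zc = q[:, 1:]
    return E @ Zc, Zc.T @ basis.penalty @ Zc, basis, Zc


@dataclass(frozen=True)
class SmoothSpec:
    """One penalized smooth: ``f(variable)`` or ``f(variable) * by``."""

    variable: str
    k: int = 3
    by: Optional[str] = None

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("basis dimension k must be >= 3")

    @property
    def name(self) -> str:
        return f"s({self.variable})" if self.by is None else f"s({self.variable}):{self.by}"


@dataclass(frozen=True)
class GAMMSpec:
    """Model layout: response, unpenalized linear covariates, smooths, grouping."""

    response: str
    linear: Tuple[str, ...] = ("sex", "visit")
    smooths: Tuple[SmoothSpec, ...] = (SmoothSpec("age"),)
    group: Optional[str] = "subject"

    def __post_init__(self) -> None:
        names = [s.name for s in self.smooths]
        if len(set(names)) != len(names):
            raise ValueError("duplicate smooth terms")


@dataclass
class _TermBlock:
    name: str
    kind: str                      # "linear" | "smooth" | "by" | "re"
    fixed_idx: List[int]
    random_idx: List[int]          # indices into the random (penalized) part
    lambda_idx: Optional[int]      # which smoothing parameter
    basis: Optional[CubicSplineBasis] = None
    # maps stacked term coefficients (fixed then random) to knot values g
    coef_to_g: Optional[np.ndarray] = None
    by: Optional[str] = None
    by_sd: Optional[float] = None


@dataclass
class GAMMFit:
    """Fitted penalized-spline mixed model."""

    spec: GAMMSpec
    method: str
    coefficients: np.ndarray       # stacked (fixed part, random part)
    cov: np.ndarray                # Bayesian posterior covariance of coefficients
    sigma2: float                  # residual variance
    ranef_var: float               # subject random-intercept variance (0 if no group)
    lambdas: np.ndarray            # smoothing parameters (per smooth, then group)
    edf: Dict[str, float]          # per-term effective degrees of freedom
    edf_total: float
    loglik: float                  # exact marginal Gaussian log-likelihood (ML scale)
    criterion: float               # value of the optimized criterion (REML or ML)
    converged: bool
    n: int
    p_fixed: int
    terms: List[_TermBlock] = field(default_factory=list)
    column_names: List[str] = field(default_factory=list)
    age_range: Optional[Tuple[float, float]] = None
    data_means: Dict[str, float] = field(default_factory=dict)

    # ---- derived quantities -------------------------------------------------
    @property
    def aic(self) -> float:
        # ML-scale AIC with the effective parameter count (+1 for the scale)
        return -2.0 * self.loglik + 2.0 * (self.edf_total + 1.0)

    def term(self, name: str) -> _TermBlock:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r}; have {[t.name for t in self.terms]}")

    def term_indices(self, name: str) -> np.ndarray:
        t = self.term(name)
        return np.array(t.fixed_idx + [self.p_fixed + j for j in t.random_idx], dtype=int)

    def smooth_curve_matrix(self, name: str, x_new: np.ndarray) -> np.ndarray:
        """Matrix L with f(x_new) = L @ coefficients[term columns]."""
        t = self.term(name)
        if t.basis is None:
            raise ValueError(f"term {name!r} is not a smooth")
        return t.basis.design(np.asarray(x_new, float)) @ t.coef_to_g

    def predict_terms(self, data: pd.DataFrame) -> Dict[str, np.ndarray]:
        """Per-term contributions to the linear predictor for new data."""
        out: Dict[str, np.ndarray] = {}
        beta = self.coefficients
        for t in self.terms:
            if t.kind == "linear":
                X = _linear_design(data, self.spec.linear)
                out[t.name] = X @ beta[t.fixed_idx]
            elif t.kind in ("smooth", "by"):
                if t.basis is None:  # dropped empty term
                    continue
                idx = self.term_indices(t.name)
                curve = self.smooth_curve_matrix(t.name, data[_smooth_var(t.name)].to_numpy()) @ beta[idx]
                if t.kind == "by":
                    curve = curve * data[t.by].to_numpy(float)
                out[t.name] = curve
            # random effects omitted from population-level predictions
        return out

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return np.sum(list(self.predict_terms(data).values()), axis=0)


def _smooth_var(name: str) -> str:
    return name.split("(", 1)[1].split(")", 1)[0]


def _linear_design(data: pd.DataFrame, linear: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(data))]
    for c in linear:
        cols.append(data[c].to_numpy(float))
    return np.column_stack(cols)


def _assemble(spec: GAMMSpec, data: pd.DataFrame):
    """Build fixed/random designs, penalty layout and term bookkeeping."""
    n = len(data)
    y = data[spec.response].to_numpy(float)
    fixed_cols: List[np.ndarray] = []
    fixed_names: List[str] = []
    random_cols: List[np.ndarray] = []
    lam_of_col: List[int] = []
    terms: List[_TermBlock] = []

    X_lin = _linear_design(data, spec.linear)
    idx = list(range(X_lin.shape[1]))
    fixed_cols.extend(X_lin.T)
    fixed_names.extend(["intercept"] + list(spec.linear))
    terms.append(_TermBlock("linear", "linear", idx, [], None))

    lam_count = 0
    for sm in spec.smooths:
        x = data[sm.variable].to_numpy(float)
        if sm.by is None:
            Xc, Sc, basis, Zc = build_basis(x, sm.k)
            evals, evecs = np.linalg.eigh(Sc)
            pos = evals > max(evals.max(), 1.0) * 1e-10
            U0, Up = evecs[:, ~pos], evecs[:, pos]
            scale = np.sqrt(evals[pos])
            f_idx = list(range(len(fixed_cols), len(fixed_cols) + U0.shape[1]))
            fixed_cols.extend((Xc @ U0).T)
            fixed_names.extend([f"{sm.name}.null{i}" for i in range(U0.shape[1])])
            r_idx = list(range(len(random_cols), len(random_cols) + Up.shape[1]))
            random_cols.extend((Xc @ Up / scale).T)
            lam_of_col.extend([lam_count] * Up.shape[1])
            coef_to_g = Zc @ np.column_stack([U0, Up / scale])
            terms.append(_TermBlock(sm.name, "smooth", f_idx, r_idx, lam_count,
                                    basis, coef_to_g))
        elif np.allclose(data[sm.by].to_numpy(float), 0.0):
            # a by-variable that is identically zero contributes nothing;
            # keep an empty term so the fit reduces to the base model
            warnings.warn(f"by-variable {sm.by!r} is identically zero; "
                          f"term {sm.name} dropped from the design")
            terms.append(_TermBlock(sm.name, "by", [], [], None, by=sm.by, by_sd=0.0))
            continue  # no smoothing parameter for an empty term
        else:
            b = data[sm.by].to_numpy(float)
            uniq = np.unique(x)
            if len(uniq) < sm.k:
                raise ValueError("too few distinct values for varying-coefficient smooth")
            knots = np.quantile(uniq, np.linspace(0.0, 1.0, sm.k))
            basis = CubicSplineBasis(knots)
            E = basis.design(x)
            K = basis.penalty
            evals, evecs = np.linalg.eigh(K)
            pos = evals > max(evals.max(), 1.0) * 1e-10
            U0, Up = evecs[:, ~pos], evecs[:, pos]
            scale = np.sqrt(evals[pos])
            Xb = E * b[:, None]
            f_idx = list(range(len(fixed_cols), len(fixed_cols) + U0.shape[1]))
            fixed_cols.extend((Xb @ U0).T)
            fixed_names.extend([f"{sm.name}.null{i}" for i in range(U0.shape[1])])
            r_idx = list(range(len(random_cols), len(random_cols) + Up.shape[1]))
            random_cols.extend((Xb @ Up / scale).T)
            lam_of_col.extend([lam_count] * Up.shape[1])
            coef_to_g = np.column_stack([U0, Up / scale])
            terms.append(_TermBlock(sm.name, "by", f_idx, r_idx, lam_count,
                                    basis, coef_to_g, by=sm.by,
                                    by_sd=float(np.std(b))))
        lam_count += 1

    if spec.group is not None:
        g = data[spec.group].to_numpy()
        labels, codes = np.unique(g, return_inverse=True)
        Zg = np.zeros((n, len(labels)))
        Zg[np.arange(n), codes] = 1.0
        r_idx = list(range(len(random_cols), len(random_cols) + len(labels)))
        random_cols.extend(Zg.T)
        lam_of_col.extend([lam_count] * len(labels))
        terms.append(_TermBlock(f"re({spec.group})", "re", [], r_idx, lam_count))
        lam_count += 1

    Xf = np.column_stack(fixed_cols) if fixed_cols else np.empty((n, 0))
    Z = np.column_stack(random_cols) if random_cols else np.empty((n, 0))
    # collinearity guard on the unpenalized block
    if Xf.shape[1] > 0:
        s = np.linalg.svd(Xf, compute_uv=False)
        if s[-1] < s[0] * 1e-10:
            raise ValueError(
                f"singular fixed-effect design; check columns {fixed_names}"
            )
    return y, Xf, Z, np.array(lam_of_col, int), lam_count, terms, fixed_names


def _criterion(rho, y, Xf, Z, lam_of_col, method):
    """Negative (restricted) profile log-likelihood at log smoothing params rho."""
    n, pf = Xf.shape
    lam = np.exp(np.clip(rho, -30.0, 30.0))[lam_of_col]
    M = Z.T @ Z + np.diag(lam)
    try:
        cM = linalg.cho_factor(M, lower=True)
    except linalg.LinAlgError:
        return np.inf, None
    ZtY = Z.T @ y
    ZtX = Z.T @ Xf

    def vinv(q_t, q):  # q_t' V^{-1} q  given Z' q pieces
        return q_t.T @ q - (Z.T @ q_t).T @ linalg.cho_solve(cM, Z.T @ q)

    A = Xf.T @ Xf - ZtX.T @ linalg.cho_solve(cM, ZtX)
    a = Xf.T @ y - ZtX.T @ linalg.cho_solve(cM, ZtY)
    try:
        b = np.linalg.solve(A, a)
    except np.linalg.LinAlgError:
        return np.inf, None
    yVy = y @ y - ZtY @ linalg.cho_solve(cM, ZtY)
    rss = float(yVy - a @ b)
    if rss <= 0:
        return np.inf, None
    logdet_V = 2.0 * np.sum(np.log(np.diag(cM[0]))) - np.sum(np.log(lam))
    if method == "ML":
        sigma2 = rss / n
        nll = 0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet_V + n)
    else:
        df = n - pf
        sigma2 = rss / df
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, None
        nll = 0.5 * (df * np.log(2.0 * np.pi * sigma2) + logdet_V + logdet_A + df)
    return float(nll), {"b": b, "cM": cM, "sigma2": sigma2, "rss": rss,
                        "logdet_V": logdet_V, "M": M}


def loglik_exact(fit_or_parts, y, Xf, Z, lam_of_col, lam_log) -> float:
    """Exact ML marginal log-likelihood at given log smoothing parameters."""
    nll, _ = _criterion(np.asarray(lam_log, float), y, Xf, Z, lam_of_col, "ML")
    return -nll


def fit_gamm(
    spec: GAMMSpec,
    data: pd.DataFrame,
    method: str = "REML",
    rho0: Optional[np.ndarray] = None,
) -> GAMMFit:
    """Fit the model; ``method`` is ``"REML"`` (summaries) or ``"ML"`` (comparisons)."""
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    y, Xf, Z, lam_of_col, n_lam, terms, fixed_names = _assemble(spec, data)
    n, pf = Xf.shape

    if n_lam == 0:
        raise ValueError("model has no penalized terms; use plain regression")
    x0 = np.zeros(n_lam) if rho0 is None else np.asarray(rho0, float)
    res = optimize.minimize(
        lambda r: _criterion(r, y, Xf, Z, lam_of_col, method)[0],
        x0, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 200 * n_lam},
    )
    rho = np.clip(res.x, -30.0, 30.0)
    nll, parts = _criterion(rho, y, Xf, Z, lam_of_col, method)
    if parts is None:
        raise RuntimeError("GAMM criterion not finite at optimum")
    lam = np.exp(rho)
    sigma2 = parts["sigma2"]
    b = parts["b"]
    u = linalg.cho_solve(parts["cM"], Z.T @ (y - Xf @ b))
    coefficients = np.concatenate([b, u])

    # joint posterior covariance of (b, u): sigma2 * inv([[Xf'Xf, Xf'Z],[Z'Xf, M]])
    top = np.hstack([Xf.T @ Xf, Xf.T @ Z])
    bottom = np.hstack([Z.T @ Xf, parts["M"]])
    Pi = np.vstack([top, bottom])
    Pi_inv = np.linalg.inv(Pi + 1e-12 * np.eye(Pi.shape[0]) * max(1.0, np.trace(Pi) / Pi.shape[0]))
    cov = sigma2 * Pi_inv

    # per-column edf: 1 - [Pi^{-1} S]_jj with S = blockdiag(0, diag(lam per col))
    S_diag = np.concatenate([np.zeros(pf), lam[lam_of_col]])
    edf_cols = 1.0 - np.diag(Pi_inv) * S_diag
    edf: Dict[str, float] = {}
    for t in terms:
        cols = np.array(t.fixed_idx + [pf + j for j in t.random_idx], int)
        edf[t.name] = float(np.sum(edf_cols[cols])) if len(cols) else 0.0
    edf_total = float(np.sum(edf_cols))

    ml_ll = -_criterion(rho, y, Xf, Z, lam_of_col, "ML")[0]

    re_var = 0.0
    for t in terms:
        if t.kind == "re":
            re_var = sigma2 / lam[t.lambda_idx]

    ages = None
    for sm in spec.smooths:
        if sm.variable == "age" and "age" in data.columns:
            ages = data["age"].to_numpy(float)
    means = {c: float(np.mean(data[c].to_numpy(float)))
             for c in data.columns if np.issubdtype(np.asarray(data[c]).dtype, np.number)}

    fit = GAMMFit(
        spec=spec, method=method,
        coefficients=coefficients, cov=cov,
        sigma2=float(sigma2), ranef_var=float(re_var), lambdas=lam,
        edf=edf, edf_total=edf_total,
        loglik=float(ml_ll), criterion=float(-nll),
        converged=bool(res.success), n=n, p_fixed=pf, terms=terms,
        column_names=fixed_names,
        age_range=(float(ages.min()), float(ages.max())) if ages is not None else None,
        data_means=means,
    )
    return fit


def smooth_significance(fit: GAMMFit, name: str) -> Tuple[float, float, float]:
    """Wald-type test that the named smooth is zero; returns (edf, F, p).

    The statistic contrasts the term's coefficients against their Bayesian
    covariance with the rank tied to the rounded effective degrees of
    freedom, following the convention of penalized-spline software summaries.
    """
    idx = fit.term_indices(name)
    c = fit.coefficients[idx]
    Vc = fit.cov[np.ix_(idx, idx)]
    edf = fit.edf[name]
    evals, evecs = np.linalg.eigh(Vc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    r = int(min(len(idx), max(1, round(edf))))
    proj = evecs[:, :r].T @ c
    T = float(np.sum(proj**2 / np.clip(evals[:r], 1e-300, None)))
    df_res = max(fit.n - fit.edf_total, 1.0)
    F = T / r
    p = float(stats.f.sf(F, r, df_res))
    return float(edf), float(F), p


def residualize_age(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Residuals of a simple linear regression of the values on age."""
    values = np.asarray(values, float)
    ages = np.asarray(ages, float)
    if values.shape != ages.shape:
        raise ValueError("values and ages must have equal length")
    if np.std(ages) == 0:
        raise ValueError("age vector is constant")
    X = np.column_stack([np.ones_like(ages), ages])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise adjusted per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def compare_model_ladder(
    data: pd.DataFrame,
    response: str,
    behaviors: Sequence[str] = ("fss", "mb", "mf"),
    linear: Sequence[str] = ("sex", "visit"),
    group: Optional[str] = "subject",
    k: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Fit the nested four-model ladder by ML and apply the conjunctive rule.

    Model 1: f(age); Models 2-4 add centered smooths of the behavioral
    indices in the stated order.  A more complex model is retained only when
    both the analysis-of-deviance test (chi-squared on the difference in
    effective degrees of freedom, rounded to one decimal) and a lower AIC
    favor it.
    """
    specs = []
    for m in range(4):
        smooths = [SmoothSpec("age", k=k)]
        smooths += [SmoothSpec(b, k=k) for b in behaviors[:m]]
        specs.append(GAMMSpec(response=response, linear=tuple(linear),
                              smooths=tuple(smooths), group=group))
    fits: List[GAMMFit] = []
    for m, s in enumerate(specs):
        rho0 = None
        if m > 0:
            prev = np.log(fits[-1].lambdas)
            # previous lambdas: [age, behaviors..., random intercept]
            rho0 = np.concatenate([prev[:-1], [0.0], prev[-1:]])
        fits.append(fit_gamm(s, data, method="ML", rho0=rho0))
    rows = []
    retained = 0
    for m in range(4):
        rows.append({"model": m + 1, "loglik": fits[m].loglik,
                     "aic": fits[m].aic, "edf": fits[m].edf_total})
    tests = []
    for m in range(1, 4):
        cur, nxt = fits[retained], fits[m]
        dev = 2.0 * (nxt.loglik - cur.loglik)
        # df: effective degrees of freedom of the terms absent from the
        # smaller model (the total-edf difference is confounded by how much
        # subject-level variance the new terms absorb from the random
        # intercept, and can even be negative)
        added = [t.name for t in nxt.terms
                 if t.kind == "smooth" and t.name not in cur.edf]
        df = round(max(sum(nxt.edf[a] for a in added), 0.5), 1)
        p = float(stats.chi2.sf(max(dev, 0.0), df))
        aic_better = nxt.aic < cur.aic
        accept = bool(aic_better and p < alpha)
        tests.append({"comparison": f"Model {retained + 1} vs Model {m + 1}",
                      "deviance": float(dev), "df": df, "p": p,
                      "aic_favors": aic_better, "accepted": accept})
        if accept:
            retained = m
    return {
        "retained": retained + 1,
        "models": pd.DataFrame(rows),
        "tests": pd.DataFrame(tests),
        "fits": fits,
    }


def fit_varying_coefficient(
    data: pd.DataFrame,
    response: str,
    behavior: str,
    linear: Sequence[str] = ("sex", "visit"),
    group: Optional[str] = "subject",
    k: int = 3,
    method: str = "REML",
    extra_smooths: Sequence[SmoothSpec] = (),
) -> GAMMFit:
    """Time-varying coefficient model: response ~ ... + f(age) + f(age)*behavior."""
    smooths = (SmoothSpec("age", k=k),) + tuple(extra_smooths) + (
        SmoothSpec("age", k=k, by=behavior),)
    spec = GAMMSpec(response=response, linear=tuple(linear),
                    smooths=smooths, group=group)
    return fit_gamm(spec, data, method=method)


@dataclass
class WindowResult:
    """Significance windows of a monitored age-varying quantity."""

    ages: np.ndarray
    estimate: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    windows: List[Tuple[float, float]]
    mode: str
    level: float
    simultaneous: bool


def _runs_excluding_zero(ages, lo, hi) -> List[Tuple[float, float]]:
    sig = (lo > 0) | (hi < 0)
    windows = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = ages[i]
        elif not s and start is not None:
            windows.append((float(start), float(ages[i - 1])))
            start = None
    if start is not None:
        windows.append((float(start), float(ages[-1])))
    return windows


def derivative_windows(
    fit: GAMMFit,
    term: str,
    n_sims: int = 10000,
    grid_size: int = 200,
    level: float = 0.95,
    mode: str = "coefficient",
    seed: Optional[int] = None,
    simultaneous: bool = False,
) -> WindowResult:
    """Posterior-simulation confidence bands and significance windows.

    Coefficient vectors are drawn from the Gaussian posterior implied by the
    fit; the monitored quantity is the term's coefficient curve over an even
    age grid (``mode="coefficient"``) or its first derivative by central
    finite differences at the grid spacing (``mode="derivative"``).  Windows
    are the maximal grid runs whose pointwise (or simultaneous max-t)
    interval excludes zero.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if mode not in ("coefficient", "derivative"):
        raise ValueError("mode must be 'coefficient' or 'derivative'")
    t = fit.term(term)
    if t.basis is None:
        raise ValueError(f"term {term!r} has no smooth curve")
    lo_age, hi_age = (fit.age_range if fit.age_range is not None
                      else (t.basis.knots[0], t.basis.knots[-1]))
    ages = np.linspace(lo_age, hi_age, grid_size)
    L = fit.smooth_curve_matrix(term, ages)
    idx = fit.term_indices(term)
    mean = fit.coefficients[idx]
    Vc = fit.cov[np.ix_(idx, idx)]
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, Vc, size=n_sims, method="svd")
    curves = draws @ L.T                       # (n_sims, grid)
    est = L @ mean
    if mode == "derivative":
        h = ages[1] - ages[0]
        curves = np.gradient(curves, h, axis=1)
        est = np.gradient(est, h)
    a = (1.0 - level) / 2.0
    if simultaneous:
        mu = curves.mean(axis=0)
        sd = curves.std(axis=0, ddof=1)
        tmax = np.max(np.abs((curves - mu) / np.clip(sd, 1e-300, None)), axis=1)
        crit = np.quantile(tmax, level)
        lo, hi = est - crit * sd, est + crit * sd
    else:
        lo = np.quantile(curves, a, axis=0)
        hi = np.quantile(curves, 1.0 - a, axis=0)
    return WindowResult(
        ages=ages, estimate=est, lo=lo, hi=hi,
        windows=_runs_excluding_zero(ages, lo, hi),
        mode=mode, level=level, simultaneous=simultaneous,
    )


def marginal_trajectories(
    fit: GAMMFit,
    term: str,
    levels_sd: Sequence[float] = (-2.0, -1.0, 0.0, 1.0, 2.0),
    grid_size: int = 100,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted response-age curves at fixed behavior levels (in SD units).

    Sex and visit are held at their data means; the subject effect is zero.
    Returns a tidy frame with pointwise confidence bounds.
    """
    t = fit.term(term)
    if t.kind != "by":
        raise ValueError(f"term {term!r} is not a varying-coefficient smooth")
    by_sd = t.by_sd or 1.0
    lo_age, hi_age = fit.age_range
    ages = np.linspace(lo_age, hi_age, grid_size)
    rows = []
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    # design rows for the population-level prediction
    for lv in levels_sd:
        b_val = lv * by_sd
        if abs(lv) > 2.5:
            warnings.warn(f"behavior level {lv} SD is outside the data-supported range")
        Lfull = np.zeros((grid_size, len(fit.coefficients)))
        # linear block at covariate means
        lin = fit.term("linear")
        means = [1.0] + [fit.data_means.get(c, 0.0) for c in fit.spec.linear]
        for j, col in enumerate(lin.fixed_idx):
            Lfull[:, col] = means[j]
        for blk in fit.terms:
            if blk.kind == "smooth":
                idx = fit.term_indices(blk.name)
                var = _smooth_var(blk.name)
                Xs = fit.smooth_curve_matrix(blk.name, ages) if var == "age" else None
                if Xs is None:
                    # non-age smooth held at behavior value 0 (its data mean region)
                    continue
                Lfull[:, idx] += Xs
            elif blk.kind == "by":
                idx = fit.term_indices(blk.name)
                Lfull[:, idx] += fit.smooth_curve_matrix(blk.name, ages) * b_val
        pred = Lfull @ fit.coefficients
        se = np.sqrt(np.einsum("ij,jk,ik->i", Lfull, fit.cov, Lfull))
        for age_v, p_v, s_v in zip(ages, pred, se):
            rows.append({"age": age_v, "level_sd": lv, "predicted": p_v,
                         "lo": p_v - zcrit * s_v, "hi": p_v + zcrit * s_v})
    return pd.DataFrame(rows)
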
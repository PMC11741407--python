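"""MAP fitting of the hybrid RL variants and parameter-recovery harnesses.

Per-session maximum a posteriori estimation stands in for hierarchical
Bayesian fitting: weakly-informative priors (Beta(1.2,1.2) on learning rates
and the model-based weight, Gamma(1.5, 2) on inverse temperatures, Normal(0,1)
on the perseveration weight), quasi-Newton optimization on an unconstrained
transformed scale (logit for unit-interval parameters, log for temperatures),
and Latin-hypercube multi-start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from .agents import (AgentParams, ModelVariant, VARIANTS, _loglik_arrays,
                     records_to_arrays)
from .task import TaskConfig, TrialRecord

_UNIT = {"alpha1", "alpha2", "lam", "w"}
_POS = {"beta1", "beta2"}

# prior hyperparameters (natural scale)
_BETA_A = _BETA_B = 1.2
_GAMMA_SHAPE, _GAMMA_SCALE = 1.5, 2.0
_PI_SD = 1.0

# multi-start boxes on the transformed scale
_START_BOX = {"unit": (-2.0, 2.0), "pos": (np.log(0.5), np.log(10.0)), "real": (-1.0, 1.0)}


def _kind(name: str) -> str:
    if name in _UNIT:
        return "unit"
    if name in _POS:
        return "pos"
    return "real"


def _to_natural(eta: np.ndarray, names: Sequence[str]) -> np.ndarray:
    out = np.empty_like(eta)
    for i, name in enumerate(names):
        kind = _kind(name)
        if kind == "unit":
            out[i] = 1.0 / (1.0 + np.exp(-eta[i]))
        elif kind == "pos":
            out[i] = np.exp(eta[i])
        else:
            out[i] = eta[i]
    return out


def _log_prior(theta: np.ndarray, names: Sequence[str]) -> float:
    """Natural-scale log prior density (the transform serves only to make
    the optimization unconstrained; the MAP is the natural-scale mode)."""
    lp = 0.0
    for i, name in enumerate(names):
        kind = _kind(name)
        if kind == "unit":
            x = theta[i]
            lp += (_BETA_A - 1.0) * np.log(max(x, 1e-12)) \
                + (_BETA_B - 1.0) * np.log(max(1.0 - x, 1e-12))
        elif kind == "pos":
            x = theta[i]
            lp += (_GAMMA_SHAPE - 1.0) * np.log(max(x, 1e-12)) - x / _GAMMA_SCALE
        else:
            lp += -0.5 * (theta[i] / _PI_SD) ** 2
    return lp


@dataclass
class FitResult:
    """One session's MAP fit under one variant."""

    variant: str
    params_hat: AgentParams
    loglik: float            # data log-likelihood at the MAP (no prior)
    log_posterior: float     # optimized objective value
    aic: float
    bic: float
    n_restarts: int
    converged: bool
    n_trials_used: int
    se_transformed: Optional[np.ndarray] = None
    free_names: Tuple[str, ...] = ()
    free_transformed: Optional[np.ndarray] = None


def fit_map(
    records: Sequence[TrialRecord],
    variant: str | ModelVariant = "hybrid7",
    n_restarts: int = 10,
    seed: Optional[int] = None,
    config: Optional[TaskConfig] = None,
    extra_starts: Optional[Sequence[np.ndarray]] = None,
) -> FitResult:
    """MAP estimate of a variant's free parameters for one session.

    ``extra_starts`` accepts transformed-scale vectors appended to the
    Latin-hypercube starts (used to warm-start nested-model comparisons).
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    names = variant.free
    k = len(names)
    p_common = (config or TaskConfig()).p_common
    arrs = records_to_arrays(records)
    n_used = int(np.sum((arrs[0] >= 0) & (arrs[2] >= 0)))
    if n_used < 10:
        warnings.warn(f"only {n_used} complete trials; fit may be unreliable")

    def neg_obj(eta):
        theta = _to_natural(np.asarray(eta, float), names)
        full = variant.expand(theta).to_array()
        ll = _loglik_arrays(full, *arrs, p_common)
        return -(ll + _log_prior(theta, names))

    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=k, seed=rng.integers(2**31 - 1))
    unit = sampler.random(n=n_restarts)
    lo = np.array([_START_BOX[_kind(n)][0] for n in names])
    hi = np.array([_START_BOX[_kind(n)][1] for n in names])
    starts = [lo + u * (hi - lo) for u in unit]
    if extra_starts is not None:
        starts.extend(np.asarray(s, float) for s in extra_starts)

    best = None
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(neg_obj, x0, method="L-BFGS-B")
        if not np.isfinite(res.fun):
            continue
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise RuntimeError("all restarts produced non-finite objectives")

    eta_hat = best.x
    theta_hat = _to_natural(eta_hat, names)
    params_hat = variant.expand(theta_hat)
    ll_hat = float(_loglik_arrays(params_hat.to_array(), *arrs, p_common))
    # transformed-scale SEs from a finite-difference Hessian of the objective
    se = None
    try:
        h = 1e-4
        H = np.zeros((k, k))
        f0 = neg_obj(eta_hat)
        for i in range(k):
            for j in range(i, k):
                ei, ej = np.zeros(k), np.zeros(k)
                ei[i] = h
                ej[j] = h
                H[i, j] = H[j, i] = (
                    neg_obj(eta_hat + ei + ej) - neg_obj(eta_hat + ei)
                    - neg_obj(eta_hat + ej) + f0
                ) / h**2
        se = np.sqrt(np.clip(np.diag(np.linalg.inv(H)), 0, None))
    except np.linalg.LinAlgError:
        pass
    return FitResult(
        variant=variant.name,
        params_hat=params_hat,
        loglik=ll_hat,
        log_posterior=-float(best.fun),
        aic=2.0 * k - 2.0 * ll_hat,
        bic=k * np.log(max(n_used, 1)) - 2.0 * ll_hat,
        n_restarts=len(starts),
        converged=bool(any_ok),
        n_trials_used=n_used,
        se_transformed=se,
        free_names=names,
        free_transformed=eta_hat.copy(),
    )


def _to_transformed(params: AgentParams, names: Sequence[str]) -> np.ndarray:
    out = np.empty(len(names))
    for i, name in enumerate(names):
        v = getattr(params, name)
        kind = _kind(name)
        if kind == "unit":
            v = np.clip(v, 1e-6, 1 - 1e-6)
            out[i] = np.log(v / (1 - v))
        elif kind == "pos":
            out[i] = np.log(max(v, 1e-6))
        else:
            out[i] = v
    return out


NESTING = [("hybrid4", "hybrid6"), ("hybrid6", "hybrid7"), ("hybrid4", "hybrid7")]


def fit_all_variants(
    records: Sequence[TrialRecord],
    n_restarts: int = 10,
    seed: Optional[int] = None,
    config: Optional[TaskConfig] = None,
    variants: Sequence[str] = ("hybrid4", "hybrid6", "hybrid7"),
) -> Dict[str, FitResult]:
    """Fit every variant, warm-starting richer variants at simpler optima so
    generalized likelihood-ratio statistics respect nesting."""
    fits: Dict[str, FitResult] = {}
    for i, vname in enumerate(variants):
        variant = VARIANTS[vname]
        extra = []
        for done in fits.values():
            extra.append(_to_transformed(done.params_hat, variant.free))
        fits[vname] = fit_map(
            records, variant, n_restarts=n_restarts,
            seed=None if seed is None else seed + i,
            config=config, extra_starts=extra,
        )
    return fits


def compare_variants(
    session_fits: Dict[object, Dict[str, FitResult]],
    alpha: float = 0.05,
) -> Dict[str, pd.DataFrame]:
    """Per-session and summed AIC/BIC comparison plus nested GLRTs.

    ``session_fits`` maps session label -> {variant name -> FitResult}.
    Sessions missing any variant are dropped with a warning.
    """
    variants = sorted({v for fits in session_fits.values() for v in fits})
    rows = []
    for session, fits in session_fits.items():
        if set(variants) - set(fits):
            warnings.warn(f"session {session} missing variants; excluded")
            continue
        for v in variants:
            f = fits[v]
            rows.append(
                {"session": session, "variant": v, "loglik": f.loglik,
                 "aic": f.aic, "bic": f.bic, "k": VARIANTS[v].k}
            )
    table = pd.DataFrame(rows)
    per_session = table.pivot(index="session", columns="variant", values="aic")
    per_session["winner"] = per_session.idxmin(axis=1)
    summed = table.groupby("variant")[["loglik", "aic", "bic"]].sum()
    summed["winner"] = ""
    summed.loc[summed["aic"].idxmin(), "winner"] = "*"
    glrt_rows = []
    for red, full in NESTING:
        if red not in variants or full not in variants:
            continue
        sub = table.pivot(index="session", columns="variant", values="loglik")
        stat = 2.0 * (sub[full] - sub[red]).clip(lower=0.0).sum()
        df = len(sub) * (VARIANTS[full].k - VARIANTS[red].k)
        glrt_rows.append(
            {"reduced": red, "full": full, "glrt": float(stat), "df": df,
             "p": float(stats.chi2.sf(stat, df))}
        )
    return {
        "per_session": per_session.reset_index(),
        "summed": summed.reset_index(),
        "glrt": pd.DataFrame(glrt_rows),
        "long": table,
    }


@dataclass
class RecoveryReport:
    """Parameter-recovery summary over a simulated cohort."""

    per_param: pd.DataFrame   # columns: param, correlation, bias, rmse
    n_sessions: int
    n_trials: int
    seed: Optional[int]


def recovery_report(
    true_params: Sequence[AgentParams],
    fits: Sequence[FitResult],
    seed: Optional[int] = None,
) -> RecoveryReport:
    names = fits[0].free_names
    rows = []
    for name in names:
        t = np.array([getattr(p, name) for p in true_params])
        e = np.array([getattr(f.params_hat, name) for f in fits])
        corr = np.nan if t.std() == 0 or e.std() == 0 else float(np.corrcoef(t, e)[0, 1])
        rows.append(
            {"param": name, "correlation": corr,
             "bias": float(np.mean(e - t)),
             "rmse": float(np.sqrt(np.mean((e - t) ** 2)))}
        )
    return RecoveryReport(
        per_param=pd.DataFrame(rows),
        n_sessions=len(fits),
        n_trials=fits[0].n_trials_used,
        seed=seed,
    )


def validate_fss_vs_perseveration(
    fss: Sequence[float],
    pi_hat: Sequence[float],
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> dict:
    """Correlate the habit index with the fitted perseveration weight.

    Returns Pearson and Spearman correlations with a bootstrap 95% CI on the
    Pearson value; flags the report degenerate when either input is constant.
    """
    fss = np.asarray(fss, float)
    pi_hat = np.asarray(pi_hat, float)
    if len(fss) < 10:
        raise ValueError("need at least 10 sessions")
    if fss.std() == 0 or pi_hat.std() == 0:
        return {"pearson": np.nan, "spearman": np.nan, "ci": (np.nan, np.nan),
                "degenerate": True, "n": len(fss)}
    pearson = float(np.corrcoef(fss, pi_hat)[0, 1])
    spearman = float(stats.spearmanr(fss, pi_hat).statistic)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(fss)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if fss[idx].std() == 0 or pi_hat[idx].std() == 0:
            continue
        boots.append(np.corrcoef(fss[idx], pi_hat[idx])[0, 1])
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    return {"pearson": pearson, "spearman": spearman, "ci": (float(lo), float(hi)),
            "degenerate": False, "n": n}
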
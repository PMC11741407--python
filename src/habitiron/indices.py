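"""Stay-probability table, hierarchical logistic model, and behavioral indices.

First-stage choices are coded stay = 1 / switch = 0 against the previous
trial, and regressed on the previous trial's reward (+1/-1), transition type
(common = +1 / rare = -1) and their interaction, with a random effect for
every term grouped by session (subject-visit).  Three per-session indices are
assembled from the fit:

* ``mb``  (model-based)   = fixed interaction + session interaction BLUP
* ``mf``  (model-free)    = fixed reward      + session reward BLUP
* ``fss`` (first-stage stay, the habit/perseveration index)
                          = fixed intercept   + session intercept BLUP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd

from .mixedlogit import MixedLogitFit, fit_mixed_logit
from .task import COMMON, TrialRecord, stay_indicator

STAY_COLUMNS = ["subject", "visit", "session", "stay", "prev_reward", "prev_transition"]
_TERMS = ["intercept", "prev_reward", "prev_transition", "reward_x_transition"]


@dataclass
class StayModelFit:
    """Hierarchical stay-probability model fit (wraps the mixed-logit result)."""

    fixed: Dict[str, float]
    ranef_cov: np.ndarray
    blups: Dict[object, np.ndarray]   # session -> 4-vector, ordered as _TERMS
    converged: bool
    loglik: float
    n_sessions: int
    n_rows: int
    raw: MixedLogitFit = None


def build_stay_table(
    sessions: Iterable[Tuple[dict, Sequence[TrialRecord]]],
    cross_blocks: bool = True,
) -> pd.DataFrame:
    """One row per analyzable trial across sessions.

    ``sessions`` yields ``(meta, records)`` pairs where ``meta`` supplies
    ``subject``, ``visit`` and ``session`` keys.  A row requires the current
    trial's first-stage choice and a fully completed previous trial; missed
    responses remove the trial and the following trial's lagged regressors.
    """
    rows: List[dict] = []
    for meta, records in sessions:
        stays = stay_indicator(records, cross_blocks=cross_blocks)
        kept = 0
        for i, stay in enumerate(stays):
            # a row needs a defined stay AND a fully completed current trial
            # (missed second-stage responses remove the whole trial)
            if stay is None or not records[i].complete:
                continue
            prev = records[i - 1]
            rows.append(
                {
                    "subject": meta.get("subject"),
                    "visit": meta.get("visit"),
                    "session": meta.get("session"),
                    "stay": int(stay),
                    "prev_reward": 1 if prev.reward == 1 else -1,
                    "prev_transition": 1 if prev.transition == COMMON else -1,
                    "age": meta.get("age"),
                }
            )
            kept += 1
        if kept == 0:
            warnings.warn(
                f"session {meta.get('session')} has no analyzable trial pairs",
                stacklevel=2,
            )
    df = pd.DataFrame(rows, columns=STAY_COLUMNS + ["age"])
    if df["age"].isna().all():
        df = df.drop(columns="age")
    return df


def _design(table: pd.DataFrame) -> np.ndarray:
    r = table["prev_reward"].to_numpy(float)
    t = table["prev_transition"].to_numpy(float)
    return np.column_stack([np.ones(len(table)), r, t, r * t])


def fit_stay_mlm(
    table: pd.DataFrame,
    cov_structure: str = "auto",
    ridge_sd: float = 10.0,
) -> StayModelFit:
    """Fit stay ~ prev_reward * prev_transition with per-session random effects."""
    if table["session"].nunique() < 2:
        raise ValueError("need at least 2 sessions to fit the multilevel model")
    fit = fit_mixed_logit(
        _design(table),
        table["stay"].to_numpy(float),
        table["session"].to_numpy(),
        fixed_names=_TERMS,
        cov_structure=cov_structure,
        ridge_sd=ridge_sd,
    )
    if not fit.converged:
        warnings.warn("stay-model fit did not fully converge; inspect diagnostics")
    return StayModelFit(
        fixed=dict(zip(_TERMS, map(float, fit.fixed))),
        ranef_cov=fit.ranef_cov,
        blups=fit.blups,
        converged=fit.converged,
        loglik=fit.loglik,
        n_sessions=fit.n_groups,
        n_rows=fit.n_obs,
        raw=fit,
    )


def extract_indices(
    fit: StayModelFit, meta: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-session mb / mf / fss indices (fixed effect + session BLUP).

    ``meta``, when given, is joined on ``session`` to carry subject, visit,
    age etc. alongside the indices.
    """
    rows = []
    for session, u in fit.blups.items():
        rows.append(
            {
                "session": session,
                "mb": fit.fixed["reward_x_transition"] + u[3],
                "mf": fit.fixed["prev_reward"] + u[1],
                "fss": fit.fixed["intercept"] + u[0],
            }
        )
    out = pd.DataFrame(rows)
    if meta is not None:
        out = meta.merge(out, on="session", validate="one_to_one")
    return out


def session_stay_logodds(fit: StayModelFit, session, prev_reward: int, prev_transition: int) -> float:
    """Predicted stay log-odds for one session at given +-1 codings."""
    u = fit.blups[session]
    x = np.array([1.0, prev_reward, prev_transition, prev_reward * prev_transition])
    beta = np.array([fit.fixed[k] for k in _TERMS])
    return float(x @ (beta + u))


def fit_supplementary_mlms(
    table: pd.DataFrame,
    rt_table: Optional[pd.DataFrame] = None,
    ridge_sd: float = 10.0,
) -> Dict[str, pd.DataFrame]:
    """Replication-style supplementary regressions.

    (a) The stay model augmented with a z-scored age main effect and all
        age x reward x transition interactions (random effects kept on the
        four base terms).
    (b) A Gaussian mixed model of second-stage response time on transition
        type (rare = 1) and its age interaction, with session random
        intercepts; fitted with statsmodels MixedLM.

    Returns tidy coefficient tables keyed ``"stay_age"`` and ``"rt"``.
    """
    out: Dict[str, pd.DataFrame] = {}
    if "age" not in table.columns:
        raise ValueError("stay table must carry an 'age' column")
    age = table["age"].to_numpy(float)
    if np.nanstd(age) == 0:
        raise ValueError("age has no variance")
    z_age = (age - np.nanmean(age)) / np.nanstd(age)
    base = _design(table)
    X = np.column_stack([base, z_age[:, None] * base])
    names = _TERMS + [f"age_x_{t}" if t != "intercept" else "age" for t in _TERMS]
    fit = fit_mixed_logit(
        X,
        table["stay"].to_numpy(float),
        table["session"].to_numpy(),
        Z=base,
        fixed_names=names,
        ridge_sd=ridge_sd,
    )
    cov = fit.diagnostics["fixed_cov"]
    se = np.sqrt(np.diag(cov))
    z = fit.fixed / se
    from scipy import stats

    out["stay_age"] = pd.DataFrame(
        {"term": names, "estimate": fit.fixed, "se": se, "z": z,
         "p": 2 * stats.norm.sf(np.abs(z))}
    )

    if rt_table is not None:
        import statsmodels.formula.api as smf

        rt = rt_table.dropna(subset=["rt2"]).copy()
        rt["rare"] = (rt["transition"] != COMMON).astype(float)
        formula = "rt2 ~ rare"
        if "age" in rt.columns and rt["age"].notna().any() and rt["age"].std() > 0:
            rt["z_age"] = (rt["age"] - rt["age"].mean()) / rt["age"].std()
            formula = "rt2 ~ rare * z_age"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, rt, groups=rt["session"]).fit(reml=True)
        out["rt"] = pd.DataFrame(
            {
                "term": model.params.index,
                "estimate": model.params.values,
                "se": model.bse.values,
                "z": model.tvalues.values,
                "p": model.pvalues.values,
            }
        )
        out["rt"] = out["rt"][~out["rt"]["term"].str.contains("Group")]
    return out


def sessions_rt_table(
    sessions: Iterable[Tuple[dict, Sequence[TrialRecord]]]
) -> pd.DataFrame:
    """Tidy second-stage RT table for the supplementary RT regression."""
    rows = []
    for meta, records in sessions:
        for rec in records:
            if rec.complete and rec.rt2 is not None:
                rows.append(
                    {
                        "session": meta.get("session"),
                        "age": meta.get("age"),
                        "transition": rec.transition,
                        "rt2": rec.rt2,
                    }
                )
    return pd.DataFrame(rows)
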
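"""End-to-end analysis pipeline on a synthetic cohort.

Reproduces the full analysis sequence: cohort generation, stay-table and
hierarchical-logistic behavioral indices, optional RL-based validation of
the habit index, batch harmonization of ROI nT2*w, age-trajectory models per
region and behavior, the four-model selection ladder, time-varying
coefficient models with windows of significance, and marginal-effect
trajectories — all logged, seeded and reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, CohortData, generate_cohort
from .gamm import (GAMMSpec, SmoothSpec, bonferroni, compare_model_ladder,
                   derivative_windows, fit_gamm, fit_varying_coefficient,
                   marginal_trajectories, residualize_age, smooth_significance)
from .indices import build_stay_table, extract_indices, fit_stay_mlm
from .iron import PRIMARY_ROIS, PUTAMEN_SUBDIVISIONS, harmonize_batches
from .rl_fitting import fit_map, validate_fss_vs_perseveration
from .task import frame_to_records

log = logging.getLogger("habitiron")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one full pipeline run."""

    cohort: CohortConfig = CohortConfig()
    level: str = "trials"                 # "trials" (full) or "indices" (fast)
    rois: Tuple[str, ...] = PRIMARY_ROIS
    subdivisions: Tuple[str, ...] = PUTAMEN_SUBDIVISIONS
    behaviors: Tuple[str, ...] = ("fss", "mb", "mf")
    alpha: float = 0.05
    window_mode: str = "coefficient"      # default window report; derivative also run
    window_sims: int = 10000
    window_grid: int = 200
    rl_subsample: int = 50                # sessions fitted by MAP (0 disables)
    rl_restarts: int = 5
    analyze_subdivisions: bool = True
    harmonize: bool = True
    seed: int = 0
    outdir: Optional[str] = None


@dataclass
class RunReport:
    """Machine-readable results of a pipeline run."""

    config: PipelineConfig
    indices: pd.DataFrame
    iron_wide: pd.DataFrame
    descriptives: pd.DataFrame
    roi_trajectories: pd.DataFrame
    behavior_trajectories: pd.DataFrame
    ladder: Dict[str, dict]
    windows: pd.DataFrame
    marginal: Dict[str, pd.DataFrame]
    rl_validation: Optional[dict]
    stage_log: List[str]

    def summary_dict(self) -> dict:
        return {
            "version": __version__,
            "seed": self.config.seed,
            "n_sessions": int(len(self.indices)),
            "roi_trajectories": self.roi_trajectories.to_dict(orient="records"),
            "behavior_trajectories": self.behavior_trajectories.to_dict(orient="records"),
            "ladder_retained": {roi: lad["retained"] for roi, lad in self.ladder.items()},
            "windows": self.windows.to_dict(orient="records"),
            "rl_validation": self.rl_validation,
            "stages": self.stage_log,
        }

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.indices.to_csv(outdir / "indices.csv", index=False)
        self.iron_wide.to_csv(outdir / "iron_wide.csv", index=False)
        self.descriptives.to_csv(outdir / "descriptives.csv", index=False)
        self.roi_trajectories.to_csv(outdir / "roi_trajectories.csv", index=False)
        self.behavior_trajectories.to_csv(outdir / "behavior_trajectories.csv", index=False)
        self.windows.to_csv(outdir / "windows.csv", index=False)
        for key, df in self.marginal.items():
            df.to_csv(outdir / f"marginal_{key}.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(self.summary_dict(), indent=1, default=_jsonify)
        )
        (outdir / "report.md").write_text(render_markdown(self))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    return str(x)


def compute_indices(cohort: CohortData, seed: int = 0) -> pd.DataFrame:
    """Session-level mb/mf/fss merged with the design table."""
    if cohort.trials is not None:
        sessions = []
        for sess, df in cohort.trials.groupby("session", sort=True):
            meta_row = cohort.design[cohort.design.session == sess].iloc[0]
            meta = {"subject": meta_row.subject, "visit": int(meta_row.visit),
                    "session": sess, "age": float(meta_row.age)}
            sessions.append((meta, frame_to_records(df)))
        table = build_stay_table(sessions)
        fit = fit_stay_mlm(table)
        idx = extract_indices(fit)
    elif cohort.indices is not None:
        idx = cohort.indices[["session", "fss", "mb", "mf"]]
    else:
        raise ValueError("cohort carries neither trials nor indices")
    return cohort.design.merge(idx, on="session", validate="one_to_one")


def summarize_descriptives(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Zero-order correlation matrix with mean/SD columns appended."""
    sub = df[list(variables)].astype(float)
    corr = sub.corr()
    out = corr.copy()
    out["M"] = sub.mean()
    out["SD"] = sub.std()
    return out.reset_index(names="variable")


def run_pipeline(config: Optional[PipelineConfig] = None) -> RunReport:
    config = config or PipelineConfig()
    stage_log: List[str] = []

    def stage(msg: str) -> None:
        stage_log.append(msg)
        log.info(msg)

    rng = np.random.default_rng(config.seed)
    stage(f"pipeline start: seed={config.seed} version={__version__} level={config.level}")

    cohort_cfg = replace(config.cohort, seed=config.seed)
    cohort = generate_cohort(cohort_cfg, seed=config.seed, level=config.level)
    stage(f"cohort: {cohort.design.subject.nunique()} subjects, {len(cohort.design)} sessions")

    data = compute_indices(cohort, seed=config.seed)
    stage("behavioral indices computed")

    rl_validation = None
    if config.rl_subsample >= 10 and cohort.trials is not None:
        sessions = list(cohort.trials["session"].unique())
        take = min(config.rl_subsample, len(sessions))
        chosen = list(rng.choice(sessions, size=take, replace=False))
        pis, fsses = [], []
        for i, sess in enumerate(chosen):
            recs = frame_to_records(cohort.trials[cohort.trials.session == sess])
            fit = fit_map(recs, "hybrid7", n_restarts=config.rl_restarts,
                          seed=int(rng.integers(2**31 - 1)))
            pis.append(fit.params_hat.pi_persev)
            fsses.append(float(data.loc[data.session == sess, "fss"].iloc[0]))
        rl_validation = validate_fss_vs_perseveration(
            fsses, pis, seed=int(rng.integers(2**31 - 1)))
        stage(f"RL validation on {take} sessions: r={rl_validation['pearson']:.3f}")

    iron = cohort.iron
    if config.harmonize:
        merged = iron.merge(cohort.design[["session", "age", "sex"]], on="session")
        iron = harmonize_batches(merged, covariates=("age", "sex"))[iron.columns]
        stage("batch harmonization applied")
    iron_wide = iron.pivot(index="session", columns="region", values="nt2w").reset_index()
    data = data.merge(iron_wide, on="session", validate="one_to_one")

    desc_vars = ["age", "mb", "mf", "fss"] + [r for r in config.rois if r in data]
    descriptives = summarize_descriptives(data, desc_vars)
    stage("descriptives computed")

    # age-residualized behavior for all association models
    ages = data["age"].to_numpy()
    for b in config.behaviors:
        data[f"{b}_resid"] = residualize_age(data[b].to_numpy(), ages)

    alpha_roi = bonferroni(config.alpha, len(config.rois))
    roi_rows = []
    for roi in config.rois:
        spec = GAMMSpec(response=roi, linear=("sex", "visit"),
                        smooths=(SmoothSpec("age"),), group="subject")
        fit = fit_gamm(spec, data, method="REML")
        edf, F, p = smooth_significance(fit, "s(age)")
        roi_rows.append({"region": roi, "edf": edf, "F": F, "p": p,
                         "significant": p < alpha_roi, "alpha": alpha_roi})
    roi_trajectories = pd.DataFrame(roi_rows)
    stage("ROI age trajectories fitted")

    alpha_beh = bonferroni(config.alpha, len(config.behaviors))
    beh_rows = []
    for b in config.behaviors:
        spec = GAMMSpec(response=b, linear=("sex", "visit"),
                        smooths=(SmoothSpec("age"),), group="subject")
        fit = fit_gamm(spec, data, method="REML")
        edf, F, p = smooth_significance(fit, "s(age)")
        beh_rows.append({"behavior": b, "edf": edf, "F": F, "p": p,
                         "significant": p < alpha_beh, "alpha": alpha_beh})
    behavior_trajectories = pd.DataFrame(beh_rows)
    stage("behavioral age trajectories fitted")

    resid_order = tuple(f"{b}_resid" for b in config.behaviors)
    ladder: Dict[str, dict] = {}
    analyze = list(config.rois)
    if config.analyze_subdivisions:
        analyze += [r for r in config.subdivisions if r in data.columns]
    for roi in config.rois:
        lad = compare_model_ladder(data, roi, behaviors=resid_order,
                                   alpha=config.alpha)
        lad.pop("fits")
        ladder[roi] = lad
    stage(f"ladder selection: { {r: ladder[r]['retained'] for r in ladder} }")

    window_rows = []
    marginal: Dict[str, pd.DataFrame] = {}
    for roi in config.rois:
        retained = ladder[roi]["retained"]
        if retained < 2:
            continue
        for b_resid in resid_order[: retained - 1]:
            # time-varying form: f(age) + f(age)*behavior, one behavior at a time
            fit = fit_varying_coefficient(data, roi, b_resid)
            term = f"s(age):{b_resid}"
            for mode in ("coefficient", "derivative"):
                w = derivative_windows(
                    fit, term, n_sims=config.window_sims,
                    grid_size=config.window_grid, mode=mode,
                    seed=int(rng.integers(2**31 - 1)),
                )
                for lo, hi in w.windows:
                    window_rows.append({"region": roi, "behavior": b_resid,
                                        "mode": mode, "lo": lo, "hi": hi})
                if not w.windows:
                    window_rows.append({"region": roi, "behavior": b_resid,
                                        "mode": mode, "lo": np.nan, "hi": np.nan})
            marginal[f"{roi}_{b_resid}"] = marginal_trajectories(fit, term)
    stage("time-varying models and windows computed for retained models")

    if config.analyze_subdivisions:
        alpha_sub = bonferroni(config.alpha, len(config.subdivisions))
        for roi in config.subdivisions:
            if roi not in data.columns:
                continue
            fit = fit_varying_coefficient(data, roi, "fss_resid")
            term = "s(age):fss_resid"
            edf, F, p = smooth_significance(fit, term)
            w = derivative_windows(fit, term, n_sims=config.window_sims,
                                   grid_size=config.window_grid,
                                   mode=config.window_mode,
                                   seed=int(rng.integers(2**31 - 1)))
            sig = p < alpha_sub
            for lo, hi in (w.windows or [(np.nan, np.nan)]):
                window_rows.append({"region": roi, "behavior": "fss_resid",
                                    "mode": config.window_mode, "lo": lo, "hi": hi,
                                    "edf": edf, "F": F, "p": p, "significant": sig})
        stage("putamen-subdivision exploratory models computed")

    windows = pd.DataFrame(window_rows)
    report = RunReport(
        config=config, indices=data, iron_wide=iron_wide,
        descriptives=descriptives, roi_trajectories=roi_trajectories,
        behavior_trajectories=behavior_trajectories, ladder=ladder,
        windows=windows, marginal=marginal, rl_validation=rl_validation,
        stage_log=stage_log,
    )
    if config.outdir:
        report.save(config.outdir)
        stage(f"report written to {config.outdir}")
    return report


def render_markdown(report: RunReport) -> str:
    """Human-readable run summary (nT2*w axes described, never sign-flipped)."""
    lines = ["# habitiron pipeline report", ""]
    lines.append(f"seed: {report.config.seed}; sessions: {len(report.indices)}")
    lines.append("")
    lines.append("## ROI age trajectories (nT2*w; lower = more iron)")
    lines.append(report.roi_trajectories.to_markdown(index=False))
    lines.append("")
    lines.append("## Behavioral age trajectories")
    lines.append(report.behavior_trajectories.to_markdown(index=False))
    lines.append("")
    lines.append("## Model ladder")
    for roi, lad in report.ladder.items():
        lines.append(f"- {roi}: retained Model {lad['retained']}")
    lines.append("")
    if len(report.windows):
        lines.append("## Windows of significance (age, years)")
        lines.append(report.windows.to_markdown(index=False))
    if report.rl_validation:
        lines.append("")
        lines.append(
            f"## Habit-index validation: Pearson r = {report.rl_validation['pearson']:.3f} "
            f"(CI {report.rl_validation['ci']})"
        )
    lines.append("")
    lines.append("_Display convention: plots of nT2*w reverse the y-axis so that"
                 " higher tissue iron sits higher; stored values are never flipped._")
    return "\n".join(lines)


def plot_reversed_axis(ax) -> None:
    """Apply the display-only reversed-axis convention for nT2*w plots."""
    ax.invert_yaxis()


def plot_marginal_trajectories(marginal: pd.DataFrame, ax=None,
                               reverse_iron_axis: bool = True):
    """Plot predicted nT2*w-vs-age curves at fixed behavior levels.

    With ``reverse_iron_axis`` the y-axis is inverted so that higher tissue
    iron (lower nT2*w) sits higher; the data themselves are untouched.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for level, sub in marginal.groupby("level_sd"):
        ax.plot(sub["age"], sub["predicted"], label=f"{level:+.0f} SD")
        ax.fill_between(sub["age"], sub["lo"], sub["hi"], alpha=0.15)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("nT2*w (lower = more iron)")
    if reverse_iron_axis:
        plot_reversed_axis(ax)
    ax.legend(title="behavior level")
    return ax
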
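"""Accelerated-longitudinal synthetic cohort with known ground truth.

Emulates a two-study developmental cohort: 217 subjects aged roughly 10-33,
one to three visits about 1.5 years apart, two scanner batches (a 156-subject
longitudinal study and a 61-subject cross-sectional one), task sessions
generated by hybrid RL agents whose model-based weight and perseveration
increase with age, and ROI-level nT2*w values that decrease with age
(exponential approach, i.e. iron accrues fastest in childhood) with subject
random intercepts, batch offsets and Gaussian noise.

The scientific hook is the coupling: a subject-and-visit-level perseveration
residual (deviation from the age trend) shifts putamen nT2*w downward (more
iron) through an age-varying coefficient that is constant below age ``a0``,
ramps linearly to zero at ``a1`` (defaults 14 and 23), and vanishes above —
the ground truth against which window-of-significance recovery is judged.

Two generation levels are offered: ``"trials"`` simulates full task sessions
for downstream index estimation, while ``"indices"`` emits the behavioral
indices directly with measurement noise, which is what the trajectory-model
experiments need and is orders of magnitude faster.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import iron as iron_mod
from .agents import AgentParams, make_policy
from .task import TaskConfig, TrialRecord, records_to_frame, simulate_session


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class AgeMap:
    """Logistic-in-age parameter trajectory: lo + (hi-lo)*sigmoid((age-mid)/width)."""

    lo: float
    hi: float
    midpoint: float = 16.0
    width: float = 4.0

    def __call__(self, age) -> np.ndarray:
        age = np.asarray(age, float)
        return self.lo + (self.hi - self.lo) * _logistic((age - self.midpoint) / self.width)


@dataclass(frozen=True)
class IronTrajectory:
    """Exponential-approach nT2*w trajectory: asymptote + amplitude*exp(-rate*(age-10)).

    Amplitude > 0 and rate > 0 give the canonical monotone decrease of nT2*w
    (monotone iron increase); ``quadratic`` adds a bend for non-monotone
    regions such as the caudate.
    """

    asymptote: float
    amplitude: float
    rate: float
    quadratic: float = 0.0

    def __call__(self, age) -> np.ndarray:
        age = np.asarray(age, float)
        out = self.asymptote + self.amplitude * np.exp(-self.rate * (age - 10.0))
        if self.quadratic:
            out = out + self.quadratic * (age - 21.0) ** 2
        return out


@dataclass(frozen=True)
class CouplingConfig:
    """Age-varying effect of the perseveration residual on putamen nT2*w.

    Applied to the whole putamen and its posterior subdivisions, emulating a
    posterior-specific substrate of the habit-iron association.
    """

    amplitude: float = -0.12     # nT2*w units per unit perseveration residual
    a0: float = 14.0             # constant below this age
    a1: float = 23.0             # zero above this age
    rois: Tuple[str, ...] = (
        "putamen", "putamen_posterior_dorsal", "putamen_posterior_ventral",
    )


def coupling_beta(age, config: CouplingConfig) -> np.ndarray:
    """Piecewise-linear ramp: amplitude below a0, linear to 0 at a1, 0 above."""
    age = np.asarray(age, float)
    amp, a0, a1 = config.amplitude, config.a0, config.a1
    out = np.where(
        age <= a0, amp,
        np.where(age >= a1, 0.0, amp * (a1 - age) / (a1 - a0)),
    )
    return out if out.ndim else float(out)


_DEFAULT_ROIS: Dict[str, IronTrajectory] = {
    "putamen": IronTrajectory(0.855, 0.075, 0.12),
    "globus_pallidus": IronTrajectory(0.545, 0.075, 0.12),
    "nucleus_accumbens": IronTrajectory(0.865, 0.090, 0.10),
    "caudate": IronTrajectory(0.900, 0.020, 0.30, quadratic=0.00008),
    "putamen_anterior_dorsal": IronTrajectory(0.860, 0.070, 0.12),
    "putamen_anterior_ventral": IronTrajectory(0.865, 0.070, 0.12),
    "putamen_posterior_dorsal": IronTrajectory(0.850, 0.080, 0.12),
    "putamen_posterior_ventral": IronTrajectory(0.845, 0.080, 0.12),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and generative settings for one synthetic cohort."""

    n_subjects: int = 217
    n_longitudinal: int = 156            # batch A, 1-3 visits
    visit_probs: Tuple[float, float, float] = (0.50, 0.34, 0.16)  # P(1,2,3 visits), batch A
    age_range: Tuple[float, float] = (10.17, 33.22)
    female_ratio: float = 0.53
    visit_gap_years: float = 1.5
    visit_gap_sd: float = 0.2
    # agent-parameter age maps
    w_map: AgeMap = AgeMap(0.25, 0.65, midpoint=17.0, width=5.0)
    persev_map: AgeMap = AgeMap(0.05, 0.55, midpoint=16.0, width=4.0)
    persev_subject_sd: float = 0.20      # subject deviation from the age trend
    w_subject_sd: float = 0.10
    alpha: float = 0.45
    beta_softmax: float = 5.0
    lam: float = 0.6
    # behavioral-index emission (level="indices")
    index_noise_sd: Dict[str, float] = field(
        default_factory=lambda: {"fss": 0.15, "mb": 0.20, "mf": 0.15}
    )
    # iron generation
    rois: Dict[str, IronTrajectory] = field(default_factory=lambda: dict(_DEFAULT_ROIS))
    iron_subject_sd: float = 0.030
    iron_noise_sd: float = 0.020
    batch_offsets: Dict[str, float] = field(default_factory=lambda: {"A": 0.0, "B": 0.05})
    batch_scales: Dict[str, float] = field(default_factory=lambda: {"A": 1.0, "B": 1.1})
    coupling: CouplingConfig = CouplingConfig()
    # age-constant behavior->iron couplings: region -> {index: nT2*w per index unit},
    # applied to the subject's true index deviation from its age trend
    main_couplings: Dict[str, Dict[str, float]] = field(default_factory=dict)
    task: TaskConfig = TaskConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.visit_probs), 1.0):
            raise ValueError("visit_probs must sum to 1")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        for name in ("persev_subject_sd", "w_subject_sd", "iron_subject_sd", "iron_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Everything needed to regenerate the cohort and score recovery."""

    config: CohortConfig
    seed: int
    subject_params: pd.DataFrame     # per-session agent parameters and residuals
    batch_offsets: Dict[str, float]
    coupling: CouplingConfig

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "batch_offsets": self.batch_offsets,
            "coupling": asdict(self.coupling),
            "config": _config_dict(self.config),
            "subject_params": self.subject_params.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=1, default=float)


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["rois"] = {k: asdict(v) if not isinstance(v, dict) else v for k, v in config.rois.items()}
    return d


@dataclass
class CohortData:
    """Generated cohort: design, behavior, iron, and ground truth."""

    design: pd.DataFrame             # subject, session, visit, age, sex, batch
    indices_true: pd.DataFrame       # noiseless generative index values per session
    indices: Optional[pd.DataFrame]  # noisy measured indices (level="indices")
    trials: Optional[pd.DataFrame]   # tidy trial table (level="trials")
    iron: pd.DataFrame               # session x region nT2*w
    truth: GroundTruth

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.design.to_csv(outdir / "design.csv", index=False)
        self.iron.to_csv(outdir / "iron.csv", index=False)
        self.indices_true.to_csv(outdir / "indices_true.csv", index=False)
        if self.indices is not None:
            self.indices.to_csv(outdir / "indices.csv", index=False)
        if self.trials is not None:
            self.trials.to_csv(outdir / "sessions.csv", index=False)
        (outdir / "truth.json").write_text(self.truth.to_json())


def _sample_design(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.age_range
    rows = []
    for i in range(config.n_subjects):
        subject = f"sub-{i:04d}"
        longitudinal = i < config.n_longitudinal
        batch = "A" if longitudinal else "B"
        n_visits = (1 + rng.choice(3, p=config.visit_probs)) if longitudinal else 1
        # keep all visits inside the age range
        span = (n_visits - 1) * (config.visit_gap_years + 3 * config.visit_gap_sd)
        base_age = rng.uniform(lo, max(hi - span, lo + 0.1))
        sex = int(rng.random() < config.female_ratio)  # 1 = female
        age = base_age
        for v in range(1, n_visits + 1):
            rows.append(
                {"subject": subject, "session": f"{subject}_v{v}", "visit": v,
                 "age": round(min(age, hi), 2), "sex": sex, "batch": batch}
            )
            gap = max(rng.normal(config.visit_gap_years, config.visit_gap_sd), 0.5)
            age += gap
    return pd.DataFrame(rows)


def generate_cohort(
    config: Optional[CohortConfig] = None,
    seed: Optional[int] = None,
    level: str = "indices",
) -> CohortData:
    """Generate a full cohort; ``level`` is ``"indices"`` or ``"trials"``.

    Reproducible: the same config and seed give identical tables.
    """
    config = config or CohortConfig()
    if seed is None:
        seed = config.seed
    if level not in ("indices", "trials"):
        raise ValueError("level must be 'indices' or 'trials'")
    rng = np.random.default_rng(seed)
    design = _sample_design(config, rng)
    n_sessions = len(design)

    # per-subject deviations (constant across that subject's visits)
    subjects = design["subject"].unique()
    dev_p = dict(zip(subjects, rng.normal(0.0, config.persev_subject_sd, len(subjects))))
    dev_w = dict(zip(subjects, rng.normal(0.0, config.w_subject_sd, len(subjects))))

    age = design["age"].to_numpy()
    persev_mean = config.persev_map(age)
    w_mean = config.w_map(age)
    persev_resid = design["subject"].map(dev_p).to_numpy()
    pi_true = persev_mean + persev_resid
    w_true = np.clip(w_mean + design["subject"].map(dev_w).to_numpy(), 0.0, 1.0)

    subject_params = design[["subject", "session", "visit", "age"]].copy()
    subject_params["pi_persev"] = pi_true
    subject_params["persev_resid"] = persev_resid
    subject_params["w"] = w_true
    subject_params["alpha"] = config.alpha
    subject_params["beta"] = config.beta_softmax
    subject_params["lam"] = config.lam

    # noiseless generative index values: the agent-level quantities the
    # stay model estimates (log-odds scale trends driven by pi and w)
    indices_true = design[["subject", "session", "visit", "age"]].copy()
    indices_true["fss"] = config.beta_softmax * pi_true  # softmax bonus -> log-odds
    indices_true["mb"] = 1.8 * w_true
    indices_true["mf"] = 0.9 * (1.0 - 0.5 * w_true)

    indices = None
    trials = None
    if level == "indices":
        indices = indices_true.copy()
        for col in ("fss", "mb", "mf"):
            indices[col] = indices[col] + rng.normal(
                0.0, config.index_noise_sd[col], n_sessions
            )
    else:
        frames = []
        for row, pi_v, w_v in zip(design.itertuples(index=False), pi_true, w_true):
            params = AgentParams(
                alpha1=config.alpha, alpha2=config.alpha,
                beta1=config.beta_softmax, beta2=config.beta_softmax,
                lam=config.lam, w=float(w_v), pi_persev=float(pi_v),
            )
            session_rng = np.random.default_rng(rng.integers(2**31 - 1))
            records, _ = simulate_session(
                make_policy(params, rng=session_rng, p_common=config.task.p_common),
                config.task, session_rng,
            )
            frames.append(
                records_to_frame(records, subject=row.subject, visit=row.visit,
                                 session=row.session)
            )
        trials = pd.concat(frames, ignore_index=True)

    # iron table
    iron_rows = []
    offsets = config.batch_offsets
    scales = config.batch_scales
    subj_int = dict(zip(subjects, rng.normal(0.0, config.iron_subject_sd, len(subjects))))
    index_resid_true = {
        "fss": config.beta_softmax * persev_resid,
        "mb": 1.8 * (w_true - np.clip(w_mean, 0.0, 1.0)),
        "mf": -0.45 * (w_true - np.clip(w_mean, 0.0, 1.0)),
    }
    for region, traj in config.rois.items():
        base = traj(age)
        coup = (coupling_beta(age, config.coupling) * persev_resid
                if region in config.coupling.rois else 0.0)
        for b, coef in config.main_couplings.get(region, {}).items():
            coup = coup + coef * index_resid_true[b]
        noise = rng.normal(0.0, config.iron_noise_sd, n_sessions)
        b_off = design["batch"].map(offsets).to_numpy()
        b_scale = design["batch"].map(scales).to_numpy()
        value = base + design["subject"].map(subj_int).to_numpy() + coup + b_off + b_scale * noise
        for sess, batch, v in zip(design["session"], design["batch"], value):
            iron_rows.append({"session": sess, "region": region, "nt2w": float(v),
                              "batch": batch})
    iron = pd.DataFrame(iron_rows)

    truth = GroundTruth(
        config=config, seed=seed, subject_params=subject_params,
        batch_offsets=dict(offsets), coupling=config.coupling,
    )
    return CohortData(design=design, indices_true=indices_true, indices=indices,
                      trials=trials, iron=iron, truth=truth)


# ---------------------------------------------------------------------------
# volume phantoms for end-to-end preprocessing tests


def default_phantom_atlas(shape: Tuple[int, int, int] = (12, 12, 8)) -> Tuple[np.ndarray, Dict[str, List[int]]]:
    """Small labeled grid with two hemispheric labels per primary region."""
    atlas = np.zeros(shape, int)
    half = shape[0] // 2
    # four regions, two hemisphere labels each (left: 1..4, right: 11..14)
    zones = [(slice(0, 3), 1), (slice(3, 6), 2), (slice(6, 9), 3), (slice(9, 12), 4)]
    for ysl, lab in zones:
        atlas[:half, ysl, 2:6] = lab
        atlas[half:, ysl, 2:6] = lab + 10
    labels = {
        "caudate": [1, 11], "putamen": [2, 12],
        "globus_pallidus": [3, 13], "nucleus_accumbens": [4, 14],
    }
    return atlas, labels


def make_volume_phantoms(
    roi_values: pd.DataFrame,
    atlas: Optional[np.ndarray] = None,
    region_labels: Optional[Dict[str, List[int]]] = None,
    n_volumes: int = 20,
    high_fd_fraction: float = 0.0,
    drift: bool = True,
    seed: Optional[int] = None,
) -> Dict[str, iron_mod.VolumeSeries]:
    """4D phantoms whose z-scored ROI means equal the given nT2*w values.

    ``roi_values`` needs columns session, region, nt2w (at most 10 sessions).
    Volumes get per-volume positive-affine intensity drift and, optionally, a
    fraction of junk volumes with FD above the censoring threshold.
    """
    sessions = roi_values["session"].unique()
    if len(sessions) > 10:
        raise ValueError("phantom generation is for small subsets (<= 10 sessions)")
    if atlas is None:
        atlas, region_labels = default_phantom_atlas()
    assert region_labels is not None
    rng = np.random.default_rng(seed)
    out = {}
    for sess in sessions:
        sub = roi_values[roi_values["session"] == sess]
        missing = set(sub["region"]) - set(region_labels)
        if missing:
            raise ValueError(f"no atlas labels for regions {sorted(missing)}")
        pattern = np.zeros(atlas.shape, float)
        roi_mask = np.zeros(atlas.shape, bool)
        for region, labels in region_labels.items():
            sel = np.isin(atlas, labels)
            row = sub[sub["region"] == region]
            if len(row):
                pattern[sel] = row["nt2w"].iloc[0]
                roi_mask |= sel
        # fill background so the whole-mask mean is 0 and SD is 1:
        # alternate background voxels around the compensating mean
        bg = ~roi_mask
        n_bg, n_roi = int(bg.sum()), int(roi_mask.sum())
        roi_sum = pattern[roi_mask].sum()
        roi_sq = (pattern[roi_mask] ** 2).sum()
        c = -roi_sum / n_bg                     # background mean for overall mean 0
        n_tot = n_bg + n_roi
        # choose background spread d so overall variance is 1 (population SD)
        need = n_tot - roi_sq - n_bg * c**2
        if need <= 0:
            raise ValueError("planted ROI values too large for this phantom size")
        d = np.sqrt(need / n_bg)
        signs = np.ones(n_bg)
        signs[1::2] = -1.0
        if n_bg % 2 == 1:
            signs[-1] = 0.0                      # keep the mean exact for odd counts
            scale = np.sqrt(n_bg / (n_bg - 1.0))
            signs[:-1] *= scale
        pattern[bg] = c + d * signs
        # exact re-centering guard (numerical)
        pattern -= pattern.mean()
        pattern /= pattern.std()
        # rebuild the ROI plant exactness by construction check happens in tests
        vols = np.empty(atlas.shape + (n_volumes,))
        fd = rng.uniform(0.03, 0.15, n_volumes)
        n_bad = int(round(high_fd_fraction * n_volumes))
        bad = rng.choice(n_volumes, size=n_bad, replace=False) if n_bad else np.array([], int)
        for t in range(n_volumes):
            if t in bad:
                fd[t] = rng.uniform(0.35, 1.0)
                vols[..., t] = rng.normal(5.0, 3.0, atlas.shape)  # motion-corrupted junk
                vols[..., t][vols[..., t] == 0] = 1e-3
            else:
                a = rng.uniform(0.5, 3.0) if drift else 1.0
                b = rng.normal(0.0, 5.0) if drift else 10.0
                v = a * pattern + b
                v[v == 0] = 1e-9                 # keep the coverage mask full
                vols[..., t] = v
        out[sess] = iron_mod.VolumeSeries(vols, fd, session=str(sess))
    return out
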
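"""Generative model of the two-stage sequential decision-making task.

A first-stage choice between two options leads probabilistically (70/30 by
default) to one of two second-stage states, where a second choice is rewarded
according to slowly drifting probabilities.  The drift is a bounded Gaussian
random walk, which forces continued exploration and makes first-stage stay
behavior informative about the learner's strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Protocol, Sequence, Tuple

import numpy as np
import pandas as pd

COMMON = "common"
RARE = "rare"


@dataclass(frozen=True)
class TaskConfig:
    """Task structure and randomization settings.

    ``walk_bounds`` defaults to (0.25, 0.75); the wider (0.2, 0.8) dialect
    used by some variants of the task is available by overriding it.
    ``boundary`` chooses how the reward walk treats its bounds: ``"reflect"``
    (default) or ``"clamp"``.
    """

    n_trials: int = 200
    n_blocks: int = 3
    p_common: float = 0.7
    walk_sd: float = 0.025
    walk_bounds: Tuple[float, float] = (0.25, 0.75)
    boundary: str = "reflect"
    choice_deadline: float = 3.0
    omission_rate: float = 0.0
    seed: Optional[int] = None
    # response-time generator (lognormal), used only to furnish plausible RTs
    rt_mean_log: float = np.log(0.8)
    rt_sd_log: float = 0.3
    rt2_rare_shift: float = 0.0  # seconds added to stage-2 RT after rare transitions

    def __post_init__(self) -> None:
        lo, hi = self.walk_bounds
        if not (0.5 < self.p_common <= 1.0):
            raise ValueError(f"p_common must be in (0.5, 1], got {self.p_common}")
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be non-negative")
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"walk_bounds must satisfy 0 <= lo < hi <= 1, got {self.walk_bounds}")
        if self.n_blocks < 1 or self.n_trials < self.n_blocks:
            raise ValueError("need at least one trial per block")
        if self.boundary not in ("reflect", "clamp"):
            raise ValueError(f"boundary must be 'reflect' or 'clamp', got {self.boundary!r}")
        if not (0.0 <= self.omission_rate <= 1.0):
            raise ValueError("omission_rate must be a probability")


@dataclass
class RewardWalk:
    """Reward probabilities indexed by (second-stage state, option)."""

    p_reward: np.ndarray  # shape (2, 2)

    def __post_init__(self) -> None:
        self.p_reward = np.asarray(self.p_reward, dtype=float)
        if self.p_reward.shape != (2, 2):
            raise ValueError("p_reward must be 2x2")

    @classmethod
    def initial(cls, config: TaskConfig, rng: np.random.Generator) -> "RewardWalk":
        lo, hi = config.walk_bounds
        return cls(rng.uniform(lo, hi, size=(2, 2)))


@dataclass(frozen=True)
class TrialRecord:
    """One trial; ``None`` marks a missed response and everything downstream of it."""

    trial_index: int
    block: int
    s1_choice: Optional[int]
    transition: Optional[str]
    s2_state: Optional[int]
    s2_choice: Optional[int]
    reward: Optional[int]
    rt1: Optional[float] = None
    rt2: Optional[float] = None

    @property
    def complete(self) -> bool:
        return self.s1_choice is not None and self.s2_choice is not None


def _reflect(p: float, lo: float, hi: float) -> float:
    # fold back into [lo, hi]; loop handles (pathological) multi-width steps
    width = hi - lo
    for _ in range(64):
        if p > hi:
            p = 2 * hi - p
        elif p < lo:
            p = 2 * lo - p
        else:
            return p
        if width <= 0:
            break
    return float(np.clip(p, lo, hi))


def step_reward_walk(walk: RewardWalk, config: TaskConfig, rng: np.random.Generator) -> RewardWalk:
    """Advance all four reward probabilities by one Gaussian step within bounds."""
    p = walk.p_reward
    if not np.all(np.isfinite(p)):
        raise ValueError("reward walk contains non-finite probabilities")
    lo, hi = config.walk_bounds
    if np.any(p < lo) or np.any(p > hi):
        raise ValueError("reward walk violates its bounds")
    proposed = p + rng.normal(0.0, config.walk_sd, size=(2, 2))
    if config.boundary == "clamp":
        out = np.clip(proposed, lo, hi)
    else:
        out = np.array([[_reflect(v, lo, hi) for v in row] for row in proposed])
    return RewardWalk(out)


def draw_transition(
    s1_choice: int, config: TaskConfig, rng: np.random.Generator
) -> Tuple[int, str]:
    """Sample the second-stage state; choice i commonly leads to state i."""
    if s1_choice not in (0, 1):
        raise ValueError(f"s1_choice must be 0 or 1, got {s1_choice}")
    if rng.random() < config.p_common:
        return s1_choice, COMMON
    return 1 - s1_choice, RARE


def block_labels(n_trials: int, n_blocks: int) -> np.ndarray:
    """Contiguous block index per trial; remainders go to the earliest blocks
    (200 trials in 3 blocks -> sizes 67/67/66)."""
    base, extra = divmod(n_trials, n_blocks)
    sizes = [base + (1 if b < extra else 0) for b in range(n_blocks)]
    return np.repeat(np.arange(n_blocks), sizes)


class AgentPolicy(Protocol):
    """Callback contract for :func:`simulate_session`."""

    def choose_stage1(self) -> int: ...

    def choose_stage2(self, s2_state: int) -> int: ...

    def observe(self, trial: TrialRecord) -> None: ...


def simulate_session(
    policy: AgentPolicy,
    config: TaskConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[TrialRecord], RewardWalk]:
    """Run one session of ``config.n_trials`` trials under ``policy``.

    Omissions are drawn by the simulator at ``config.omission_rate`` per
    response stage; a missed stage voids the rest of the trial.  The reward
    walk advances once per trial regardless of completion.  The policy is
    notified of every trial (including incomplete ones) via ``observe``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    walk = RewardWalk.initial(config, rng)
    blocks = block_labels(config.n_trials, config.n_blocks)
    records: List[TrialRecord] = []
    for t in range(config.n_trials):
        block = blocks[t]
        rt1 = rt2 = None
        s1 = transition = s2 = c2 = reward = None
        if rng.random() >= config.omission_rate:
            s1 = int(policy.choose_stage1())
            if s1 not in (0, 1):
                raise ValueError(f"policy returned out-of-range stage-1 choice {s1}")
            rt1 = min(float(rng.lognormal(config.rt_mean_log, config.rt_sd_log)), config.choice_deadline)
            s2, transition = draw_transition(s1, config, rng)
            if rng.random() >= config.omission_rate:
                c2 = int(policy.choose_stage2(s2))
                if c2 not in (0, 1):
                    raise ValueError(f"policy returned out-of-range stage-2 choice {c2}")
                rt2 = float(rng.lognormal(config.rt_mean_log, config.rt_sd_log))
                if transition == RARE:
                    rt2 += config.rt2_rare_shift
                rt2 = min(rt2, config.choice_deadline)
                reward = int(rng.random() < walk.p_reward[s2, c2])
        rec = TrialRecord(
            trial_index=t, block=block, s1_choice=s1, transition=transition,
            s2_state=s2, s2_choice=c2, reward=reward, rt1=rt1, rt2=rt2,
        )
        records.append(rec)
        policy.observe(rec)
        walk = step_reward_walk(walk, config, rng)
    return records, walk


def stay_indicator(
    records: Sequence[TrialRecord], cross_blocks: bool = True
) -> List[Optional[int]]:
    """Per-trial stay (1) / switch (0) relative to the previous first-stage choice.

    ``None`` for the first analyzable trial of a session (or block, when
    ``cross_blocks`` is False) and whenever the current or previous trial has
    a missed response anywhere (missed trials are removed together with the
    following trial's lagged regressors).
    """
    out: List[Optional[int]] = []
    for i, rec in enumerate(records):
        if i == 0:
            out.append(None)
            continue
        prev = records[i - 1]
        if not cross_blocks and rec.block != prev.block:
            out.append(None)
            continue
        if rec.s1_choice is None or not prev.complete:
            out.append(None)
            continue
        out.append(int(rec.s1_choice == prev.s1_choice))
    return out


def records_to_frame(
    records: Sequence[TrialRecord],
    subject: Optional[str] = None,
    visit: Optional[int] = None,
    session: Optional[str] = None,
) -> pd.DataFrame:
    """Tidy one-row-per-trial table with nullable integer codings."""
    df = pd.DataFrame(
        {
            "trial_index": [r.trial_index for r in records],
            "block": [r.block for r in records],
            "s1_choice": pd.array([r.s1_choice for r in records], dtype="Int64"),
            "transition": [r.transition for r in records],
            "s2_state": pd.array([r.s2_state for r in records], dtype="Int64"),
            "s2_choice": pd.array([r.s2_choice for r in records], dtype="Int64"),
            "reward": pd.array([r.reward for r in records], dtype="Int64"),
            "rt1": [np.nan if r.rt1 is None else r.rt1 for r in records],
            "rt2": [np.nan if r.rt2 is None else r.rt2 for r in records],
        }
    )
    meta = {"subject": subject, "visit": visit, "session": session}
    for key in reversed(list(meta)):
        if meta[key] is not None:
            df.insert(0, key, meta[key])
    return df


def frame_to_records(df: pd.DataFrame) -> List[TrialRecord]:
    """Inverse of :func:`records_to_frame` (metadata columns ignored)."""

    def _opt(v):
        return None if pd.isna(v) else v

    records = []
    for row in df.itertuples(index=False):
        records.append(
            TrialRecord(
                trial_index=int(row.trial_index),
                block=int(row.block),
                s1_choice=None if pd.isna(row.s1_choice) else int(row.s1_choice),
                transition=_opt(row.transition),
                s2_state=None if pd.isna(row.s2_state) else int(row.s2_state),
                s2_choice=None if pd.isna(row.s2_choice) else int(row.s2_choice),
                reward=None if pd.isna(row.reward) else int(row.reward),
                rt1=None if pd.isna(row.rt1) else float(row.rt1),
                rt2=None if pd.isna(row.rt2) else float(row.rt2),
            )
        )
    return records
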
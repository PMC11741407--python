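"""Hybrid model-based / model-free reinforcement-learning agents.

The agent family is the canonical hybrid account of two-stage task behavior:
a SARSA(lambda) model-free branch, a Bellman model-based branch that assumes
the true transition probabilities, a softmax mixture weighted by ``w``, and a
perseveration bonus ``pi_persev`` for repeating the previous first-stage
choice.  Three nested variants are exposed: hybrid4 (tied learning rates and
temperatures, lambda fixed at 1), hybrid6 (frees lambda and the learning-rate
tie), and hybrid7 (all seven parameters free).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .task import COMMON, TaskConfig, TrialRecord

_PARAM_ORDER = ("alpha1", "alpha2", "beta1", "beta2", "lam", "w", "pi_persev")


@dataclass(frozen=True)
class AgentParams:
    """Hybrid-agent parameters; ``pi_persev`` is the habit/stickiness weight."""

    alpha1: float = 0.5
    alpha2: float = 0.5
    beta1: float = 4.0
    beta2: float = 4.0
    lam: float = 1.0
    w: float = 0.5
    pi_persev: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "lam", "w"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("beta1", "beta2"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _PARAM_ORDER], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "AgentParams":
        return cls(**dict(zip(_PARAM_ORDER, map(float, arr))))

    def to_dict(self) -> Dict[str, float]:
        return {k: float(getattr(self, k)) for k in _PARAM_ORDER}


@dataclass(frozen=True)
class ModelVariant:
    """A named restriction of the seven-parameter hybrid family.

    ``free`` lists the names optimized during fitting; ``ties`` maps a bound
    parameter to the free parameter it copies; ``fixed`` pins parameters to
    constants.
    """

    name: str
    free: Tuple[str, ...]
    ties: Dict[str, str] = field(default_factory=dict)
    fixed: Dict[str, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.free)

    def expand(self, free_values: Sequence[float]) -> AgentParams:
        """Full AgentParams from the variant's free-parameter vector."""
        vals = dict(zip(self.free, map(float, free_values)))
        for bound, src in self.ties.items():
            vals[bound] = vals[src]
        vals.update(self.fixed)
        missing = set(_PARAM_ORDER) - set(vals)
        if missing:
            raise ValueError(f"variant {self.name} leaves parameters unset: {missing}")
        return AgentParams(**vals)

    def restrict(self, params: AgentParams) -> np.ndarray:
        return np.array([getattr(params, k) for k in self.free], dtype=float)


VARIANTS: Dict[str, ModelVariant] = {
    "hybrid4": ModelVariant(
        name="hybrid4",
        free=("alpha1", "beta1", "w", "pi_persev"),
        ties={"alpha2": "alpha1", "beta2": "beta1"},
        fixed={"lam": 1.0},
    ),
    "hybrid6": ModelVariant(
        name="hybrid6",
        free=("alpha1", "alpha2", "beta1", "lam", "w", "pi_persev"),
        ties={"beta2": "beta1"},
    ),
    "hybrid7": ModelVariant(name="hybrid7", free=_PARAM_ORDER),
}


@dataclass
class AgentState:
    """Evolving value estimates and the previous first-stage choice."""

    q_mf_s1: np.ndarray = field(default_factory=lambda: np.zeros(2))
    q_s2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    prev_s1_choice: Optional[int] = None

    def copy(self) -> "AgentState":
        return AgentState(self.q_mf_s1.copy(), self.q_s2.copy(), self.prev_s1_choice)


def _softmax2(pref0: float, pref1: float) -> Tuple[float, float]:
    m = max(pref0, pref1)
    e0, e1 = np.exp(pref0 - m), np.exp(pref1 - m)
    z = e0 + e1
    return e0 / z, e1 / z


def stage1_choice_probs(
    state: AgentState, params: AgentParams, p_common: float = 0.7
) -> np.ndarray:
    """Softmax over the hybrid first-stage values plus the perseveration bonus.

    Q_mb(a) = P(common) * max_a' q2[a, a'] + (1 - P(common)) * max_a' q2[1-a, a'];
    Q(a) = w * Q_mb(a) + (1 - w) * q_mf(a); preference = beta1 * (Q + pi * rep).
    """
    if not (np.all(np.isfinite(state.q_mf_s1)) and np.all(np.isfinite(state.q_s2))):
        raise ValueError("agent state contains non-finite values")
    best = state.q_s2.max(axis=1)  # max over stage-2 options, per state
    prefs = np.empty(2)
    for a in (0, 1):
        q_mb = p_common * best[a] + (1.0 - p_common) * best[1 - a]
        q = params.w * q_mb + (1.0 - params.w) * state.q_mf_s1[a]
        rep = 1.0 if state.prev_s1_choice == a else 0.0
        prefs[a] = params.beta1 * (q + params.pi_persev * rep)
    return np.array(_softmax2(prefs[0], prefs[1]))


def stage2_choice_probs(state: AgentState, params: AgentParams, s2_state: int) -> np.ndarray:
    p0, p1 = _softmax2(params.beta2 * state.q_s2[s2_state, 0], params.beta2 * state.q_s2[s2_state, 1])
    return np.array([p0, p1])


def update(state: AgentState, params: AgentParams, trial: TrialRecord) -> AgentState:
    """SARSA(lambda) value update; returns a new state.

    Incomplete trials leave the value tables untouched and clear
    ``prev_s1_choice`` so the next trial carries no perseveration bonus,
    mirroring the removal of incomplete trials from the lagged analysis.
    """
    new = state.copy()
    if not trial.complete:
        new.prev_s1_choice = None
        return new
    if trial.reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {trial.reward}")
    a1, s2, a2, r = trial.s1_choice, trial.s2_state, trial.s2_choice, trial.reward
    delta1 = new.q_s2[s2, a2] - new.q_mf_s1[a1]
    new.q_mf_s1[a1] += params.alpha1 * delta1
    delta2 = r - new.q_s2[s2, a2]
    new.q_s2[s2, a2] += params.alpha2 * delta2
    new.q_mf_s1[a1] += params.alpha1 * params.lam * delta2
    new.prev_s1_choice = a1
    return new


def session_loglik(
    params: AgentParams,
    records: Sequence[TrialRecord],
    config: Optional[TaskConfig] = None,
) -> float:
    """Log-likelihood of one session's choices under the hybrid agent.

    Sum over completed trials of the log stage-1 and log stage-2 choice
    probabilities; incomplete trials contribute zero (but still clear the
    perseveration carrier).  The agent assumes the task's true common-
    transition probability.
    """
    if len(records) == 0:
        raise ValueError("empty session")
    p_common = (config or TaskConfig()).p_common
    arrs = records_to_arrays(records)
    return float(_loglik_arrays(params.to_array(), *arrs, p_common))


def records_to_arrays(records: Sequence[TrialRecord]) -> Tuple[np.ndarray, ...]:
    """Integer arrays (s1, s2_state, s2_choice, reward) with -1 for missing."""
    n = len(records)
    s1 = np.full(n, -1, dtype=np.int64)
    s2s = np.full(n, -1, dtype=np.int64)
    s2c = np.full(n, -1, dtype=np.int64)
    rew = np.full(n, -1, dtype=np.int64)
    for i, r in enumerate(records):
        if r.s1_choice is not None:
            s1[i] = r.s1_choice
        if r.s2_state is not None:
            s2s[i] = r.s2_state
        if r.s2_choice is not None:
            s2c[i] = r.s2_choice
        if r.reward is not None:
            rew[i] = r.reward
    return s1, s2s, s2c, rew


def _loglik_arrays_py(theta, s1, s2s, s2c, rew, p_common):
    alpha1, alpha2, beta1, beta2, lam, w, pi = theta
    q_mf0 = 0.0
    q_mf1 = 0.0
    q2 = [[0.0, 0.0], [0.0, 0.0]]
    prev = -1
    ll = 0.0
    n = s1.shape[0]
    for t in range(n):
        a1 = s1[t]
        a2 = s2c[t]
        if a1 < 0 or a2 < 0:
            prev = -1
            continue
        st = s2s[t]
        r = rew[t]
        best0 = q2[0][0] if q2[0][0] > q2[0][1] else q2[0][1]
        best1 = q2[1][0] if q2[1][0] > q2[1][1] else q2[1][1]
        qmb0 = p_common * best0 + (1.0 - p_common) * best1
        qmb1 = p_common * best1 + (1.0 - p_common) * best0
        v0 = w * qmb0 + (1.0 - w) * q_mf0
        v1 = w * qmb1 + (1.0 - w) * q_mf1
        pref0 = beta1 * (v0 + (pi if prev == 0 else 0.0))
        pref1 = beta1 * (v1 + (pi if prev == 1 else 0.0))
        m = pref0 if pref0 > pref1 else pref1
        z = np.exp(pref0 - m) + np.exp(pref1 - m)
        chosen = pref0 if a1 == 0 else pref1
        ll += chosen - m - np.log(z)
        # stage 2
        g0 = beta2 * q2[st][0]
        g1 = beta2 * q2[st][1]
        m2 = g0 if g0 > g1 else g1
        z2 = np.exp(g0 - m2) + np.exp(g1 - m2)
        chosen2 = g0 if a2 == 0 else g1
        ll += chosen2 - m2 - np.log(z2)
        # updates
        q1 = q_mf0 if a1 == 0 else q_mf1
        d1 = q2[st][a2] - q1
        q1 += alpha1 * d1
        d2 = r - q2[st][a2]
        q2[st][a2] += alpha2 * d2
        q1 += alpha1 * lam * d2
        if a1 == 0:
            q_mf0 = q1
        else:
            q_mf1 = q1
        prev = a1
    return ll


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _loglik_arrays = njit(cache=False, fastmath=False)(_loglik_arrays_py)
    # warm the JIT with a tiny call at import so timing stays predictable
    _loglik_arrays(
        np.array([0.5, 0.5, 1.0, 1.0, 1.0, 0.5, 0.0]),
        np.array([0], dtype=np.int64), np.array([0], dtype=np.int64),
        np.array([0], dtype=np.int64), np.array([1], dtype=np.int64), 0.7,
    )
    HAVE_NUMBA = True
except Exception:  # numba absent or failed to compile
    _loglik_arrays = _loglik_arrays_py
    HAVE_NUMBA = False


def session_loglik_reference(
    params: AgentParams,
    records: Sequence[TrialRecord],
    config: Optional[TaskConfig] = None,
) -> float:
    """Naive per-trial recomputation through the object-level API.

    Independent of the array kernel; used to cross-check it.
    """
    if len(records) == 0:
        raise ValueError("empty session")
    p_common = (config or TaskConfig()).p_common
    state = AgentState()
    ll = 0.0
    for trial in records:
        if trial.complete:
            p1 = stage1_choice_probs(state, params, p_common)
            ll += np.log(p1[trial.s1_choice])
            p2 = stage2_choice_probs(state, params, trial.s2_state)
            ll += np.log(p2[trial.s2_choice])
        state = update(state, params, trial)
    return float(ll)


class HybridPolicy:
    """Simulator callback wrapping the hybrid agent's choice and update rules."""

    def __init__(
        self,
        params: AgentParams,
        rng: np.random.Generator,
        p_common: float = 0.7,
    ) -> None:
        self.params = params
        self.rng = rng
        self.p_common = p_common
        self.state = AgentState()

    def choose_stage1(self) -> int:
        p = stage1_choice_probs(self.state, self.params, self.p_common)
        return int(self.rng.random() < p[1])

    def choose_stage2(self, s2_state: int) -> int:
        p = stage2_choice_probs(self.state, self.params, s2_state)
        return int(self.rng.random() < p[1])

    def observe(self, trial: TrialRecord) -> None:
        self.state = update(self.state, self.params, trial)


def make_policy(
    params: AgentParams,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    p_common: float = 0.7,
) -> HybridPolicy:
    """Seeded agent policy for :func:`habitiron.task.simulate_session`."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return HybridPolicy(params, rng, p_common)
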
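# habitiron

Simulation and analysis tools for studying how **habitual decision-making**
matures alongside **striatal tissue iron** from late childhood into
adulthood. The package covers the full analysis chain for an accelerated
longitudinal cohort performing the two-stage sequential decision-making
task:

- a generative model of the task (70/30 probabilistic transitions, reward
  probabilities drifting by a bounded Gaussian random walk, 200 trials in
  three blocks);
- hybrid model-based / model-free reinforcement-learning agents with a
  perseveration (choice-stickiness) weight, with exact likelihoods and MAP
  fitting;
- the hierarchical stay-probability analysis: a multilevel logistic model
  `stay ~ prev_reward * prev_transition` with per-session random effects,
  from which three per-session indices are assembled —
  **mb** (model-based: interaction fixed effect + random effect),
  **mf** (model-free: reward fixed effect + random effect), and
  **fss** (first-stage stay, the habit index: intercept + random intercept);
- nT2*w tissue-iron quantification from 4D echo-planar series (coverage-mask
  z-normalization, FD > 0.3 mm censoring, voxelwise median, bilateral ROI
  means, simplified location–scale batch harmonization);
- penalized-spline mixed models (GAMMs) of developmental trajectories:
  `y_it = β0 + β1·sex + β2·visit + f(age) + b_0i + ε`, with a four-model
  selection ladder adding `f(FSS)`, `f(MB)`, `f(MF)`, time-varying
  coefficient models `f(age)·Behavior`, and posterior-simulation **windows
  of significance** on the coefficient curve or its first derivative;
- a synthetic-cohort generator with full ground truth (agent parameters,
  iron trajectories, batch effects, and a tunable age-varying coupling
  between perseveration and putamen iron) for parameter-recovery testing.

Because nT2*w is *inversely* related to tissue iron, stored values are never
sign-flipped; plotting helpers expose a reversed-axis display convention
instead.

## Worked example

```python
import numpy as np
from habitiron import (AgentParams, TaskConfig, make_policy,
                       simulate_session, build_stay_table, fit_stay_mlm,
                       extract_indices)

# 60 sessions from agents whose perseveration weight varies across the cohort
rng = np.random.default_rng(0)
sessions, true_pi = [], []
for j in range(60):
    pi = float(rng.normal(0.3, 0.2))
    params = AgentParams(alpha1=0.5, alpha2=0.5, beta1=5, beta2=5,
                         lam=0.6, w=0.5, pi_persev=pi)
    records, _ = simulate_session(make_policy(params, rng=rng), TaskConfig(), rng)
    sessions.append(({"subject": f"s{j:02d}", "visit": 1, "session": f"s{j:02d}"}, records))
    true_pi.append(pi)

fit = fit_stay_mlm(build_stay_table(sessions))
idx = extract_indices(fit).set_index("session")
fss = [idx.loc[m["session"], "fss"] for m, _ in sessions]
print({k: round(v, 3) for k, v in fit.fixed.items()})
print("r(fss, true pi) =", round(np.corrcoef(fss, true_pi)[0, 1], 3))
```

prints

```
{'intercept': 2.029, 'prev_reward': 0.415, 'prev_transition': 0.004, 'reward_x_transition': 0.229}
r(fss, true pi) = 0.946
```

The positive reward effect and reward-by-transition interaction are the
model-free and model-based signatures of the mixed (w = 0.5) cohort; the
intercept is the cohort's average habit strength on the log-odds scale, and
the per-session `fss` index recovers the generative perseveration ordering
almost perfectly (r ≈ 0.95).

The full pipeline — cohort generation, indices, RL validation,
harmonization, trajectory models, ladder selection, windows — runs from the
shell:

```bash
habitiron run-all --seed 0 --out results/run0
```

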
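# Methods

This note documents the models implemented in `habitiron`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not establish.

## Two-stage task

Each trial offers a binary first-stage choice; choice *i* leads to
second-stage state *i* with probability `p_common = 0.7` and to the other
state otherwise. A second binary choice is rewarded with a probability that
drifts across trials as a Gaussian random walk (mean 0, SD 0.025 per trial)
confined to [0.25, 0.75]. Sessions have 200 trials in three blocks
(67/67/66). Two conventions in the task literature are ambiguous and both
are configurable:

- **Walk boundary handling.** Reflection is the default (it preserves
  near-uniform long-run coverage of the interval; a clamped walk piles mass
  at the bounds). Clamping is available via `TaskConfig(boundary="clamp")`,
  and the wider (0.2, 0.8) bound dialect via `walk_bounds`.
- **Block boundaries.** Lagged stay regressors cross block breaks by
  default (`cross_blocks=True`); a per-block reset is available.
- **Missed responses.** A missed first- or second-stage response voids the
  trial and the following trial's lagged regressors, and clears the
  agent's one-trial perseveration carrier.

## Hybrid agents

The agent family is the canonical hybrid account of two-step behavior:
a SARSA(λ) model-free branch over first-stage values and second-stage
Q-values, a Bellman model-based branch that assumes the true transition
probabilities (learning them is out of scope; the assumption is
configurable), a mixture weight `w`, and a perseveration bonus `pi_persev`
added to the previous first-stage choice inside the stage-1 softmax:

    P(a) ∝ exp{ β1 [ w·Q_mb(a) + (1−w)·Q_mf(a) + π·1(a = a_prev) ] }

Updates: δ1 = Q2(s,c) − Q1(a); Q1 += α1 δ1; δ2 = r − Q2(s,c);
Q2 += α2 δ2; Q1 += α1 λ δ2, with δ2 evaluated **before** the stage-2 update
(the standard eligibility-trace convention). Three nested variants are
fitted: hybrid4 (α and β tied, λ = 1), hybrid6 (frees λ and the learning-
rate tie), hybrid7 (all seven parameters).

The session log-likelihood is implemented twice: an array kernel (optionally
numba-compiled; a pure-Python fallback is selected automatically and is
bit-identical) and a naive object-level recomputation used only as a test
oracle.

## MAP fitting

Hierarchical Bayesian fitting is replaced by per-session MAP: the
natural-scale posterior mode under weakly-informative priors —
Beta(1.2, 1.2) on learning rates, λ and w; Gamma(shape 1.5, scale 2) on
inverse temperatures (mode 1, mean 3); Normal(0, 1) on the perseveration
weight — maximized by L-BFGS on a transformed scale (logit / log /
identity) from 10 Latin-hypercube starts by default. Near-flat Beta priors
were chosen deliberately: priors with stronger boundary repulsion (e.g.
Beta(2,2)) bias the model-based weight away from the extremes strongly
enough to spoil recovery of fully model-based agents at 200 trials per
session. When variants are compared, richer variants are additionally
warm-started at the optima of nested ones, which guarantees non-negative
generalized likelihood-ratio statistics. AIC (2k − 2ℓ) is the headline
comparison; BIC is reported alongside. MAP point estimates are expected to
agree with hierarchical estimates in ordering, not value; the package's
validation experiments only ever use correlations and orderings.

## Stay-probability model and behavioral indices

First-stage stays (1 = repeat, 0 = switch) are regressed on the previous
trial's reward (+1/−1), transition type (common +1 / rare −1) and their
interaction. Random effects for all four terms are grouped by **session**
(subject-visit), matching an index that is unique per visit; per-subject
grouping is an option. Estimation is Laplace-approximate maximum marginal
likelihood, written for this package because no installed Python library
fits logistic mixed models with correlated random slopes: an inner Newton
solver for the joint (β, u) mode exploiting the arrowhead Hessian, an outer
quasi-Newton loop over the Cholesky factor of the random-effect covariance
(unstructured by default, diagonal below 30 sessions), and a weak ridge
(SD 10 log-odds) on the fixed effects against separation. The fit is
cross-checked against lme4's `glmer` in the test suite; small numeric
differences from any particular mixed-model package are expected and
tolerated at the ~0.05 log-odds level.

Indices: `mb` = interaction fixed effect + session BLUP; `mf` = reward
fixed effect + BLUP; `fss` = intercept + random intercept, which with ±1
codings is the session's predicted stay log-odds at the predictor
midpoint — the outcome-insensitive habit measure.

## nT2*w preprocessing

Per session: coverage mask = voxels non-zero in every volume; volumes with
FD > 0.3 mm (strictly greater) are excluded; each retained volume is
z-scored over the mask; the voxelwise median (lower median for even counts)
forms the nT2*w map; region values are means over all labeled voxels with
hemispheres pooled. The per-volume z-score makes the map exactly invariant
to positive-affine intensity drift, which is the tested contract. The batch
harmonizer is deliberately simple — per-region location–scale adjustment
with covariates (age, sex) preserved and batch parameters shrunk toward
their across-region means with weight n/(n+10) — and is documented as such;
it is not an empirical-Bayes reimplementation of neuroCombat.

## Trajectory models

Smooths are natural cubic regression splines parameterized by their values
at k = 3 quantile-placed knots ("maximum number of knots 3" is read as
basis dimension 3), with the integrated-squared-second-derivative penalty
(null space = linear functions) and a sum-to-zero constraint over the data;
a k = 3 smooth therefore has 1–2 effective degrees of freedom. The subject
random intercept is absorbed as one more quadratic penalty. Smoothing
parameters and variance components maximize the exact Gaussian REML
(single-model summaries) or ML (all model comparisons) criterion, computed
in the mixed-model reparameterization via the Woodbury identity and
optimized by Nelder-Mead on the log scale. The engine reproduces mgcv
(`bs="cr"` + `s(subject, bs="re")`) coefficients, edf, σ² and smooth curves
to ~1e-3 and its ML score to 1e-2 on test fixtures.

Smooth significance is a Wald-type test on the term's coefficients using
the Bayesian covariance with rank = rounded edf, reported as (edf, F, p).
Under a pure-noise smooth its rejection rate at α = 0.05 measures 0.05–0.06
over 500 replicates.

**Model ladder.** Models 1–4 add, cumulatively, centered smooths of the
age-residualized fss, mb and mf indices to the age model. All four are fit
by ML; a more complex model is retained only when both a lower AIC
(−2ℓ + 2(edf + 1)) and an analysis-of-deviance test (χ² on 2Δℓ) favor it.
The deviance df is the effective df of the **added** smooths (rounded to
0.1): the difference in total edf is confounded by how much subject-level
variance the new terms absorb from the random intercept (it can even be
negative) and is not a usable df. This is an approximation, documented as
such.

**Time-varying coefficients.** `f(age)·Behavior` augments the design with
the (unconstrained) age basis multiplied elementwise by the behavior value;
its penalty null space contains the constant and linear-in-age coefficient,
so a separate linear behavior main effect is neither needed nor
identifiable alongside it. The behavior is always age-residualized first
(simple linear regression) to break the concurvity between the age smooth
and age-trending indices.

**Windows of significance.** Coefficient vectors are drawn from the
Gaussian posterior N(β̂, V̂); the monitored quantity — the coefficient curve
β(age), or its first derivative by central finite differences at the grid
spacing (200-point grid, 10,000 draws by default) — gets pointwise 95%
intervals, and windows are maximal grid runs whose interval excludes zero.
Both modes are provided because the reporting convention is ambiguous:
derivative mode tests where the coupling *changes*, coefficient mode where
it *differs from zero*; coefficient mode is the default window report.
Pointwise bands are anti-conservative for excursion claims: under a global
null the expected fraction of flagged gridpoints measures ≈ 2.5× the
nominal 5% (concurvity leakage through the residualized index accounts for
the excess over the ≈ 3× seen with an exchangeable regressor), and the
probability of at least one window is higher still. A simultaneous max-t
option (critical value from the same draws) controls the family-wise rate
near nominal and should be preferred for confirmatory claims.

Marginal trajectories evaluate the fitted model at behavior fixed at 0, ±1,
±2 SD with covariates at their means and the subject effect at zero.

## Synthetic cohort

The generator emulates a two-study accelerated longitudinal design: 217
subjects (156 longitudinal, 1–3 visits ≈ 1.5 ± 0.2 y apart, batch A; 61
cross-sectional, batch B), ages 10.17–33.22, 53% female, ≈ 320 sessions in
expectation. Agent parameters follow logistic age maps (w: 0.25→0.65;
π: 0.05→0.55) with subject-level deviations (SD 0.20 for π, 0.10 for w);
these slopes were set once so that cohort-level age effects are detectable
at this sample size, not to reproduce any particular statistic. ROI nT2*w
follows exponential-approach curves (asymptote + amplitude·e^(−rate·(age−10)),
asymptotes near the descriptive means of the adult literature), with a
subject intercept (SD 0.03), batch offset (+0.05) and scale (×1.1) for
batch B, and residual SD 0.02; the caudate gets a small quadratic term to
emulate its non-monotone report. The scientific hook is the coupling: the
subject's perseveration residual shifts putamen (and posterior-putamen
subdivision) nT2*w by β*(age) · residual, where β*(age) = −0.12 below age
14, ramps linearly to 0 at age 23, and vanishes above. Optional
age-constant `main_couplings` (behavior → region) support the
Model-2/3/4-truth selection experiments. Two output levels: `"trials"`
simulates every task session for the full pipeline; `"indices"` emits the
index values directly with measurement noise (SD 0.15/0.20/0.15 for
fss/mb/mf) and is used for the trajectory-model experiments, where the
behavioral estimation step would add nothing but runtime.

What the generator does **not** emulate: attrition and practice effects,
learning the transition structure, RT dynamics beyond a lognormal with an
optional rare-transition shift, spatial MRI noise, registration error, or
realistic motion structure. Passing recovery tests therefore shows the
estimators are correct and calibrated under the stated generative
assumptions, not that the scientific conclusions transfer to real cohorts.

## Problem sizes and numerical settings

The shipped experiments use cohorts of ≈ 310 sessions for trajectory
models, 100 sessions for behavioral-signature and index-validity
experiments, 20–40 replicate cohorts for selection/window experiments, and
500 replicates for null calibration; the full trials-level pipeline run
uses the complete 217-subject design with the MAP-RL validation on a
50-session subsample (RL fitting is validation-only and the slowest stage;
a flag extends it to all sessions). Reward/choice codings are exact
integers; optimizer tolerances: inner Newton 1e-9 relative, outer L-BFGS
ftol 1e-9 (mixed logit), Nelder-Mead fatol 1e-7 (GAMM). Degenerate inputs
(constant age, all-zero by-variable, empty coverage mask, all-censored
series, constant-input correlations) raise or warn explicitly rather than
propagating NaNs. All randomness flows through seeded
`numpy.random.Generator` instances; every pipeline stage logs its seed, and
rerunning with the same seed reproduces every output table byte for byte.
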
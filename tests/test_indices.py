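"""Stay table construction, hierarchical stay model, and index extraction."""

import numpy as np
import pandas as pd
import pytest

from habitiron.agents import AgentParams
from habitiron.indices import (build_stay_table, extract_indices,
                               fit_stay_mlm, fit_supplementary_mlms,
                               session_stay_logodds, sessions_rt_table)
from habitiron.mixedlogit import fit_mixed_logit
from habitiron.task import COMMON, RARE, TaskConfig, TrialRecord

from conftest import simulate_cohort_sessions


def _rec(i, s1, transition, reward, s2c=0):
    complete = s1 is not None and s2c is not None
    return TrialRecord(
        trial_index=i, block=0, s1_choice=s1,
        transition=transition if complete else None,
        s2_state=(s1 if transition == COMMON else 1 - s1) if complete else None,
        s2_choice=s2c if complete else None,
        reward=reward if complete else None,
    )


class TestBuildStayTable:
    def test_four_trial_coding(self):
        recs = [
            _rec(0, 0, COMMON, 1),
            _rec(1, 0, RARE, 0),
            _rec(2, 1, COMMON, 1),
            _rec(3, 1, COMMON, 0),
        ]
        table = build_stay_table([({"subject": "a", "visit": 1, "session": "a1"}, recs)])
        assert list(table["stay"]) == [1, 0, 1]
        assert list(table["prev_reward"]) == [1, -1, 1]
        assert list(table["prev_transition"]) == [1, -1, 1]

    def test_missing_stage2_removes_two_rows(self):
        recs = [_rec(i, 0, COMMON, 1) for i in range(5)]
        recs[2] = _rec(2, 0, COMMON, 1, s2c=None)
        table = build_stay_table([({"session": "x"}, recs)])
        # trials 1 and 4 remain; trials 2 (incomplete) and 3 (lagged) removed
        assert len(table) == 2

    def test_complete_session_yields_n_minus_one_rows(self, hybrid_session):
        _, records, _ = hybrid_session
        table = build_stay_table([({"session": "s"}, records)])
        assert len(table) == 199

    def test_tiny_session_warns_and_yields_nothing(self):
        with pytest.warns(UserWarning, match="no analyzable"):
            table = build_stay_table([({"session": "t"}, [_rec(0, 0, COMMON, 1)])])
        assert len(table) == 0


@pytest.fixture(scope="module")
def persev_cohort():
    """100 sessions with heterogeneous perseveration, fixed other params."""
    def params_fn(j, rng):
        return AgentParams(alpha1=0.5, alpha2=0.5, beta1=5.0, beta2=5.0,
                           lam=0.6, w=0.5, pi_persev=float(rng.normal(0.3, 0.2)))

    sessions = simulate_cohort_sessions(params_fn, 100, seed=314)
    table = build_stay_table([(m, r) for m, r, _ in sessions])
    fit = fit_stay_mlm(table)
    true_pi = {m["session"]: p.pi_persev for m, _, p in sessions}
    return table, fit, true_pi


class TestFitStayMlm:
    def test_null_cohort_recovers_zero_effects(self):
        # stay ~ Bernoulli(0.5) independent of the predictors
        rng = np.random.default_rng(0)
        rows = []
        for j in range(100):
            n = 199
            rows.append(pd.DataFrame({
                "subject": f"s{j}", "visit": 1, "session": f"s{j}",
                "stay": rng.integers(0, 2, n),
                "prev_reward": rng.choice([-1, 1], n),
                "prev_transition": rng.choice([-1, 1], n),
            }))
        fit = fit_stay_mlm(pd.concat(rows, ignore_index=True))
        se = fit.raw.fixed_se
        for i, term in enumerate(["intercept", "prev_reward", "prev_transition",
                                  "reward_x_transition"]):
            assert abs(fit.fixed[term]) < 3 * se[i], term

    def test_transition_sign_flip_symmetry(self, persev_cohort):
        table, fit, _ = persev_cohort
        flipped = table.assign(prev_transition=-table["prev_transition"])
        fit2 = fit_stay_mlm(flipped)
        assert fit2.fixed["prev_reward"] == pytest.approx(
            fit.fixed["prev_reward"], abs=0.02)
        assert fit2.fixed["prev_transition"] == pytest.approx(
            -fit.fixed["prev_transition"], abs=0.02)
        assert fit2.fixed["reward_x_transition"] == pytest.approx(
            -fit.fixed["reward_x_transition"], abs=0.02)

    def test_strategy_cohorts_recover_fig2_signatures(self):
        mk = lambda w: (lambda j, rng: AgentParams(
            alpha1=0.5, alpha2=0.5, beta1=5.0, beta2=5.0, lam=1.0, w=w,
            pi_persev=0.0))
        s0 = simulate_cohort_sessions(mk(0.0), 60, seed=61)
        f0 = fit_stay_mlm(build_stay_table([(m, r) for m, r, _ in s0]))
        se0 = f0.raw.fixed_se
        assert f0.fixed["prev_reward"] > 3 * se0[1]
        assert abs(f0.fixed["reward_x_transition"]) < 3 * se0[3]
        s1 = simulate_cohort_sessions(mk(1.0), 60, seed=62)
        f1 = fit_stay_mlm(build_stay_table([(m, r) for m, r, _ in s1]))
        assert f1.fixed["reward_x_transition"] > 3 * f1.raw.fixed_se[3]

    def test_single_session_rejected(self, hybrid_session):
        _, records, _ = hybrid_session
        table = build_stay_table([({"session": "only"}, records)])
        with pytest.raises(ValueError, match="2 sessions"):
            fit_stay_mlm(table)


class TestExtractIndices:
    def test_definitional_sums(self, persev_cohort):
        _, fit, _ = persev_cohort
        idx = extract_indices(fit)
        sess = idx["session"].iloc[0]
        u = fit.blups[sess]
        row = idx[idx.session == sess].iloc[0]
        assert row["mb"] == pytest.approx(fit.fixed["reward_x_transition"] + u[3])
        assert row["mf"] == pytest.approx(fit.fixed["prev_reward"] + u[1])
        assert row["fss"] == pytest.approx(fit.fixed["intercept"] + u[0])

    def test_fss_is_centered_stay_logodds(self, persev_cohort):
        # with +-1 codings, fss equals the session's predicted log-odds at
        # reward = transition = 0
        _, fit, _ = persev_cohort
        idx = extract_indices(fit)
        sess = idx["session"].iloc[3]
        assert idx.set_index("session").loc[sess, "fss"] == pytest.approx(
            session_stay_logodds(fit, sess, 0, 0))

    def test_persev_recovery_rank_correlation(self, persev_cohort):
        from scipy.stats import spearmanr

        _, fit, true_pi = persev_cohort
        idx = extract_indices(fit).set_index("session")
        sessions = sorted(true_pi)
        rho = spearmanr([true_pi[s] for s in sessions],
                        [idx.loc[s, "fss"] for s in sessions]).statistic
        assert rho >= 0.7

    def test_missing_session_rejected(self, persev_cohort):
        _, fit, _ = persev_cohort
        with pytest.raises(KeyError):
            session_stay_logodds(fit, "no-such-session", 0, 0)

    def test_index_assembly_identity(self, persev_cohort):
        # mb + mf + fss equals the session's predicted stay log-odds at
        # (reward=+1, transition=+1) minus the transition contributions
        _, fit, _ = persev_cohort
        idx = extract_indices(fit).set_index("session")
        for sess in list(fit.blups)[:5]:
            u = fit.blups[sess]
            lhs = idx.loc[sess, ["mb", "mf", "fss"]].sum()
            rhs = (session_stay_logodds(fit, sess, +1, +1)
                   - (fit.fixed["prev_transition"] + u[2]))
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_blups_approach_per_session_ml_with_long_sessions(self):
        # shrinkage vanishes as rows per session grow: BLUP-implied session
        # coefficients converge to independent per-session logistic fits
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n_per, n_sess = 2000, 12
        frames, truths = [], []
        for j in range(n_sess):
            beta_j = np.array([1.0, 0.5, 0.0, 0.4]) + rng.normal(0, 0.3, 4)
            rew = rng.choice([-1.0, 1.0], n_per)
            tr = rng.choice([-1.0, 1.0], n_per)
            X = np.column_stack([np.ones(n_per), rew, tr, rew * tr])
            y = (rng.random(n_per) < 1 / (1 + np.exp(-X @ beta_j))).astype(int)
            frames.append(pd.DataFrame({
                "subject": f"s{j}", "visit": 1, "session": f"s{j:02d}",
                "stay": y, "prev_reward": rew.astype(int),
                "prev_transition": tr.astype(int)}))
            truths.append((f"s{j:02d}", X, y))
        fit = fit_stay_mlm(pd.concat(frames, ignore_index=True),
                           cov_structure="diagonal")
        beta_fixed = np.array([fit.fixed[k] for k in
                               ("intercept", "prev_reward", "prev_transition",
                                "reward_x_transition")])
        for sess, X, y in truths[:6]:
            ml = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            mixed = beta_fixed + fit.blups[sess]
            assert np.abs(mixed - ml.params).max() < 0.15


class TestAgainstLme4:
    def test_fixed_effects_match_glmer(self, tmp_path, persev_cohort):
        """Independent oracle: lme4 glmer fit of the same stay model."""
        import subprocess

        table, fit, _ = persev_cohort
        csv = tmp_path / "stay.csv"
        table.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{csv}")\n'
            'm <- glmer(stay ~ prev_reward*prev_transition + '
            '(1+prev_reward*prev_transition | session), data=d, family=binomial,\n'
            '  control=glmerControl(optimizer="bobyqa", calc.derivs=FALSE))\n'
            'cat(fixef(m), sep="\\n")\n'
        )
        res = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, timeout=600)
        assert res.returncode == 0, res.stderr
        ref = [float(v) for v in res.stdout.strip().splitlines()[-4:]]
        ours = [fit.fixed["intercept"], fit.fixed["prev_reward"],
                fit.fixed["prev_transition"], fit.fixed["reward_x_transition"]]
        # different approximations (ridge, optimizer); agree to ~5% of scale
        for a, b in zip(ours, ref):
            assert a == pytest.approx(b, abs=0.08)


class TestSupplementaryModels:
    def test_rt_shift_detected(self):
        # generator plants a +50 ms second-stage RT cost after rare transitions
        cfg = TaskConfig(rt2_rare_shift=0.05)
        def params_fn(j, rng):
            return AgentParams(alpha1=0.5, alpha2=0.5, beta1=3.0, beta2=3.0,
                               lam=0.6, w=0.5, pi_persev=0.2)
        sessions = simulate_cohort_sessions(params_fn, 60, seed=777, config=cfg)
        pairs = [(dict(m, age=20.0 + j * 0.1), r)
                 for j, (m, r, _) in enumerate(sessions)]
        table = build_stay_table(pairs)
        rt = sessions_rt_table(pairs)
        out = fit_supplementary_mlms(table, rt)
        rare = out["rt"].set_index("term").loc["rare"]
        assert rare["estimate"] > 0 and rare["p"] < 0.05

    def test_age_interaction_recovered(self):
        # age linearly scales the generative model-based weight
        def params_fn_with_age(j, rng):
            return AgentParams(alpha1=0.5, alpha2=0.5, beta1=5.0, beta2=5.0,
                               lam=1.0, w=min(j / 60.0, 1.0), pi_persev=0.1)
        sessions = simulate_cohort_sessions(params_fn_with_age, 60, seed=88)
        pairs = [(dict(m, age=10.0 + 20.0 * j / 60.0), r)
                 for j, (m, r, _) in enumerate(sessions)]
        table = build_stay_table(pairs)
        out = fit_supplementary_mlms(table)
        coefs = out["stay_age"].set_index("term")
        assert coefs.loc["age_x_reward_x_transition", "estimate"] > 0
        assert coefs.loc["age_x_reward_x_transition", "p"] < 0.05
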
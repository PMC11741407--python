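"""Penalized-spline mixed models: basis, fitting, tests, ladder, windows."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline

from habitiron.gamm import (CubicSplineBasis, GAMMSpec, SmoothSpec,
                            WindowResult, bonferroni, build_basis,
                            compare_model_ladder, derivative_windows,
                            fit_gamm, fit_varying_coefficient,
                            marginal_trajectories, residualize_age,
                            smooth_significance)


class TestBasis:
    def test_matches_scipy_natural_spline(self):
        knots = np.array([0.0, 1.5, 4.0, 7.0])
        basis = CubicSplineBasis(knots)
        g = np.array([0.3, -1.0, 2.0, 0.5])
        x = np.linspace(0, 7, 57)
        oracle = CubicSpline(knots, g, bc_type="natural")(x)
        assert np.abs(basis.design(x) @ g - oracle).max() < 1e-8

    def test_penalty_null_space_is_linear(self):
        basis = CubicSplineBasis(np.array([1.0, 2.0, 5.0]))
        linear = 3.0 * basis.knots - 2.0
        assert abs(linear @ basis.penalty @ linear) < 1e-10
        curved = basis.knots**2
        assert curved @ basis.penalty @ curved > 0

    def test_centered_columns_sum_to_zero(self):
        x = np.random.default_rng(0).uniform(10, 33, 400)
        Xc, Sc, basis, Zc = build_basis(x, k=3)
        assert np.abs(Xc.sum(axis=0)).max() < 1e-10
        assert Xc.shape == (400, 2)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            build_basis(np.array([1.0, 1.0, 2.0, 2.0]), k=3)


def _cohortish_frame(rng, n=400, f=None, noise=0.3, re_sd=0.5):
    n_subj = n // 2
    subj = np.repeat(np.arange(n_subj), 2)
    age = rng.uniform(10, 33, n)
    sex = rng.integers(0, 2, n).astype(float)
    visit = np.tile([1.0, 2.0], n_subj)
    re = rng.normal(0, re_sd, n_subj)[subj]
    y = (f(age) if f else 0.0) + 0.2 * sex - 0.05 * visit + re + rng.normal(0, noise, n)
    return pd.DataFrame({"y": y, "age": age, "sex": sex, "visit": visit,
                         "subject": subj})


class TestFitGamm:
    def test_null_smooth_near_linear_and_insignificant(self):
        rng = np.random.default_rng(1)
        df = _cohortish_frame(rng, f=lambda a: 3.0, re_sd=0.0, noise=1.0)
        spec = GAMMSpec("y", ("sex", "visit"), (SmoothSpec("age"),), "subject")
        fit = fit_gamm(spec, df)
        edf, F, p = smooth_significance(fit, "s(age)")
        assert edf < 1.6
        assert p > 0.01
        # intercept recovered
        assert fit.coefficients[0] == pytest.approx(3.0, abs=0.3)

    def test_linear_truth_matches_ols(self):
        # in the exactly-linear limit the penalized fit equals least squares
        rng = np.random.default_rng(2)
        n = 500
        age = rng.uniform(10, 33, n)
        y = 1.0 + 0.3 * age + rng.normal(0, 1e-3, n)
        df = pd.DataFrame({"y": y, "age": age, "subject": np.arange(n)})
        spec = GAMMSpec("y", (), (SmoothSpec("age"),), None)
        fit = fit_gamm(spec, df)
        X = np.column_stack([np.ones(n), age])
        ols_pred = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        rmse = np.sqrt(np.mean((fit.predict(df) - ols_pred) ** 2))
        assert rmse < 1e-3

    def test_random_intercept_recovery(self):
        # two subjects with true offsets +-1 over many replicates
        rng = np.random.default_rng(3)
        n_rep = 80
        subj = np.repeat([0, 1], n_rep)
        age = rng.uniform(10, 33, 2 * n_rep)
        y = np.where(subj == 0, 1.0, -1.0) + 0.01 * age + rng.normal(0, 0.3, 2 * n_rep)
        df = pd.DataFrame({"y": y, "age": age, "subject": subj})
        spec = GAMMSpec("y", (), (SmoothSpec("age"),), "subject")
        fit = fit_gamm(spec, df)
        assert fit.ranef_var > 0.3
        re_block = fit.term("re(subject)")
        offsets = fit.coefficients[[fit.p_fixed + j for j in re_block.random_idx]]
        assert offsets[0] == pytest.approx(1.0, abs=0.2)
        assert offsets[1] == pytest.approx(-1.0, abs=0.2)

    def test_strong_signal_detected(self):
        rng = np.random.default_rng(4)
        df = _cohortish_frame(rng, f=lambda a: np.sin(a / 3.5), re_sd=0.0,
                              noise=0.3)
        spec = GAMMSpec("y", ("sex", "visit"), (SmoothSpec("age", k=8),), None)
        fit = fit_gamm(spec, df)
        edf, F, p = smooth_significance(fit, "s(age)")
        assert p < 1e-6

    def test_edf_bounded_by_basis(self):
        rng = np.random.default_rng(5)
        df = _cohortish_frame(rng, f=lambda a: 0.1 * (a - 20) ** 2)
        spec = GAMMSpec("y", ("sex", "visit"), (SmoothSpec("age"),), "subject")
        fit = fit_gamm(spec, df)
        assert 1.0 - 1e-6 <= fit.edf["s(age)"] <= 2.0 + 1e-6

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(6)
        df = _cohortish_frame(rng)
        df["visit"] = 1.0  # collinear with intercept
        spec = GAMMSpec("y", ("sex", "visit"), (SmoothSpec("age"),), "subject")
        with pytest.raises(ValueError, match="singular"):
            fit_gamm(spec, df)

    def test_ml_vs_reml_criteria_differ(self):
        rng = np.random.default_rng(7)
        df = _cohortish_frame(rng, f=lambda a: np.sin(a / 5))
        spec = GAMMSpec("y", ("sex", "visit"), (SmoothSpec("age"),), "subject")
        ml = fit_gamm(spec, df, method="ML")
        reml = fit_gamm(spec, df, method="REML")
        assert ml.method == "ML" and reml.method == "REML"
        assert ml.loglik == pytest.approx(reml.loglik, rel=0.05)


@pytest.fixture(scope="module")
def fixture_frame():
    rng = np.random.default_rng(3)
    n = 300
    subj = np.repeat(np.arange(100), 3)
    age = rng.uniform(10, 33, n)
    sex = rng.integers(0, 2, n).astype(float)
    visit = np.tile([1.0, 2.0, 3.0], 100)
    re = rng.normal(0, 0.5, 100)[subj]
    y = 2 + 0.3 * sex - 0.1 * visit + np.sin(age / 6) + re + rng.normal(0, 0.4, n)
    return pd.DataFrame({"y": y, "age": age, "sex": sex, "visit": visit,
                         "subject": subj})


class TestAgainstMgcv:
    def test_reml_fit_matches_mgcv(self, fixture_frame, tmp_path):
        """Independent oracle: mgcv gam with a cr(k=3) smooth + re(subject)."""
        import subprocess

        csv = tmp_path / "d.csv"
        fixture_frame.to_csv(csv, index=False)
        script = tmp_path / "m.R"
        script.write_text(
            'suppressMessages(library(mgcv))\n'
            f'd <- read.csv("{csv}"); d$subject <- factor(d$subject)\n'
            'm <- gam(y ~ sex + visit + s(age, k=3, bs="cr") + s(subject, bs="re"),'
            ' data=d, method="REML")\n'
            'cat(coef(m)[1:3], "\\n")\n'
            'cat(summary(m)$s.table["s(age)", c("edf","F")], "\\n")\n'
            'cat(m$sig2, "\\n")\n'
            'grid <- data.frame(age=seq(10,33,length.out=7), sex=0, visit=0,'
            ' subject=d$subject[1])\n'
            'cat(as.numeric(predict(m, grid, type="terms", terms="s(age)")), "\\n")\n'
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=600)
        assert res.returncode == 0, res.stderr
        lines = [np.array(l.split(), float) for l in res.stdout.strip().splitlines()]
        spec = GAMMSpec("y", ("sex", "visit"), (SmoothSpec("age"),), "subject")
        fit = fit_gamm(spec, fixture_frame, "REML")
        assert np.allclose(fit.coefficients[:3], lines[0], atol=1e-3)
        edf, F, p = smooth_significance(fit, "s(age)")
        assert edf == pytest.approx(lines[1][0], abs=0.02)
        assert fit.sigma2 == pytest.approx(lines[2][0], rel=0.01)
        grid = np.linspace(10, 33, 7)
        idx = fit.term_indices("s(age)")
        ours = fit.smooth_curve_matrix("s(age)", grid) @ fit.coefficients[idx]
        assert np.allclose(ours, lines[3], atol=2e-3)

    def test_ml_score_matches_mgcv(self, fixture_frame, tmp_path):
        import subprocess

        csv = tmp_path / "d.csv"
        fixture_frame.to_csv(csv, index=False)
        script = tmp_path / "m.R"
        script.write_text(
            'suppressMessages(library(mgcv))\n'
            f'd <- read.csv("{csv}"); d$subject <- factor(d$subject)\n'
            'm <- gam(y ~ sex + visit + s(age, k=3, bs="cr") + s(subject, bs="re"),'
            ' data=d, method="ML")\n'
            'cat(m$gcv.ubre, "\\n")\n'
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=600)
        assert res.returncode == 0, res.stderr
        ref_neg_ml = float(res.stdout.split()[0])
        spec = GAMMSpec("y", ("sex", "visit"), (SmoothSpec("age"),), "subject")
        fit = fit_gamm(spec, fixture_frame, "ML")
        assert -fit.loglik == pytest.approx(ref_neg_ml, abs=0.01)


class TestPenaltyLimits:
    """Behavior of the penalized fit at fixed smoothing parameters."""

    @staticmethod
    def _edf_at(rho, df):
        from habitiron.gamm import _assemble, _criterion

        spec = GAMMSpec("y", (), (SmoothSpec("age", k=6),), None)
        y, Xf, Z, lam_of_col, n_lam, terms, names = _assemble(spec, df)
        nll, parts = _criterion(np.array([rho]), y, Xf, Z, lam_of_col, "REML")
        lam = np.exp(np.clip(rho, -30, 30))
        top = np.hstack([Xf.T @ Xf, Xf.T @ Z])
        bottom = np.hstack([Z.T @ Xf, parts["M"]])
        Pi_inv = np.linalg.inv(np.vstack([top, bottom]))
        S_diag = np.concatenate([np.zeros(Xf.shape[1]),
                                 np.full(Z.shape[1], lam)])
        return float(np.sum(1.0 - np.diag(Pi_inv) * S_diag)), parts

    def test_edf_monotone_in_lambda(self):
        rng = np.random.default_rng(12)
        n = 300
        age = rng.uniform(10, 33, n)
        df = pd.DataFrame({"y": np.sin(age / 4) + rng.normal(0, 0.3, n),
                           "age": age})
        edfs = [self._edf_at(r, df)[0] for r in (-8.0, -3.0, 0.0, 5.0, 20.0)]
        assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))
        # both limits: full basis dimension down to the linear fit
        assert edfs[0] == pytest.approx(6.0, abs=0.05)
        assert edfs[-1] == pytest.approx(2.0, abs=0.05)

    def test_zero_penalty_limit_matches_unpenalized_regression(self):
        rng = np.random.default_rng(13)
        n = 300
        age = rng.uniform(10, 33, n)
        y = np.sin(age / 4) + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"y": y, "age": age})
        from habitiron.gamm import _assemble, _criterion
        from scipy import linalg as sla

        spec = GAMMSpec("y", (), (SmoothSpec("age", k=6),), None)
        yv, Xf, Z, lam_of_col, *_ = _assemble(spec, df)
        nll, parts = _criterion(np.full(1, -25.0), yv, Xf, Z, lam_of_col, "REML")
        X = np.hstack([Xf, Z])
        ols = X @ np.linalg.lstsq(X, yv, rcond=None)[0]
        b = parts["b"]
        u = sla.cho_solve(parts["cM"], Z.T @ (yv - Xf @ b))
        pen_pred = Xf @ b + Z @ u
        assert np.abs(pen_pred - ols).max() < 1e-6


class TestResidualizeAndBonferroni:
    def test_exact_linear_gives_zero_residuals(self):
        ages = np.linspace(10, 30, 50)
        assert np.abs(residualize_age(2.0 * ages, ages)).max() < 1e-10

    def test_orthogonal_to_age(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(10, 33, 200)
        vals = 0.5 * ages + rng.normal(0, 1, 200)
        resid = residualize_age(vals, ages)
        assert abs(np.corrcoef(resid, ages)[0, 1]) < 1e-10
        assert abs(resid.mean()) < 1e-10

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            residualize_age(np.arange(5.0), np.full(5, 20.0))

    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 4, 0.0125), (0.05, 3, 0.05 / 3), (0.05, 1, 0.05)])
    def test_bonferroni(self, alpha, m, expected):
        assert bonferroni(alpha, m) == pytest.approx(expected)
        assert round(bonferroni(0.05, 3), 4) == 0.0167


class TestLadder:
    def test_zero_noise_degenerate_keeps_model1(self):
        # identical response under all models: the conjunctive rule cannot
        # accept a more complex model
        rng = np.random.default_rng(8)
        n = 200
        age = rng.uniform(10, 33, n)
        df = pd.DataFrame({
            "y": 1.0 + 0.01 * age, "age": age,
            "sex": rng.integers(0, 2, n).astype(float),
            "visit": rng.integers(1, 4, n).astype(float),
            "subject": np.arange(n),
            "fss_resid": rng.normal(0, 1, n),
            "mb_resid": rng.normal(0, 1, n),
            "mf_resid": rng.normal(0, 1, n),
        })
        out = compare_model_ladder(df, "y",
                                   behaviors=("fss_resid", "mb_resid", "mf_resid"))
        assert out["retained"] == 1

    def test_behavior_effect_advances_ladder(self):
        rng = np.random.default_rng(9)
        n = 300
        age = rng.uniform(10, 33, n)
        fss = rng.normal(0, 1, n)
        df = pd.DataFrame({
            "y": 1.0 - 0.01 * age + 0.3 * fss + rng.normal(0, 0.2, n),
            "age": age, "sex": rng.integers(0, 2, n).astype(float),
            "visit": rng.integers(1, 4, n).astype(float),
            "subject": np.arange(n), "fss_resid": fss,
            "mb_resid": rng.normal(0, 1, n), "mf_resid": rng.normal(0, 1, n),
        })
        out = compare_model_ladder(df, "y",
                                   behaviors=("fss_resid", "mb_resid", "mf_resid"))
        assert out["retained"] == 2
        assert bool(out["tests"].iloc[0]["accepted"]) is True


@pytest.fixture(scope="module")
def constant_beta_fit():
    rng = np.random.default_rng(10)
    n = 500
    age = rng.uniform(10, 33, n)
    beh = rng.normal(0, 1, n)
    y = 1.0 + 0.02 * age + 0.4 * beh + rng.normal(0, 0.3, n)
    df = pd.DataFrame({"y": y, "age": age, "beh": beh,
                       "sex": rng.integers(0, 2, n).astype(float),
                       "visit": rng.integers(1, 4, n).astype(float),
                       "subject": np.arange(n)})
    return fit_varying_coefficient(df, "y", "beh", group=None), df


class TestVaryingCoefficientAndWindows:
    def test_constant_coefficient_recovered(self, constant_beta_fit):
        fit, _ = constant_beta_fit
        grid = np.linspace(10, 33, 50)
        idx = fit.term_indices("s(age):beh")
        curve = fit.smooth_curve_matrix("s(age):beh", grid) @ fit.coefficients[idx]
        assert np.abs(curve - 0.4).max() < 0.1

    def test_zero_behavior_column_matches_base_model(self):
        # an identically-zero by-variable contributes nothing: the fit must
        # coincide with the model that omits the interaction entirely
        rng = np.random.default_rng(11)
        df = _cohortish_frame(rng, f=lambda a: np.sin(a / 5))
        df["beh"] = 0.0
        with pytest.warns(UserWarning, match="identically zero"):
            fit = fit_varying_coefficient(df, "y", "beh")
        base = fit_gamm(GAMMSpec("y", ("sex", "visit"), (SmoothSpec("age"),),
                                 "subject"), df)
        assert fit.loglik == pytest.approx(base.loglik, abs=1e-6)
        assert np.allclose(fit.predict(df), base.predict(df), atol=1e-6)

    def test_derivative_mode_silent_for_constant_truth(self, constant_beta_fit):
        fit, _ = constant_beta_fit
        w = derivative_windows(fit, "s(age):beh", n_sims=2000, seed=1,
                               mode="derivative")
        assert w.windows == []

    def test_coefficient_mode_flags_constant_truth(self, constant_beta_fit):
        fit, _ = constant_beta_fit
        w = derivative_windows(fit, "s(age):beh", n_sims=2000, seed=1,
                               mode="coefficient")
        total = sum(hi - lo for lo, hi in w.windows)
        assert total > 0.8 * (33 - 10) * 0.8  # windows cover most of the range

    def test_windows_sorted_disjoint_within_range(self, constant_beta_fit):
        fit, _ = constant_beta_fit
        w = derivative_windows(fit, "s(age):beh", n_sims=500, seed=2,
                               mode="coefficient")
        prev_hi = -np.inf
        for lo, hi in w.windows:
            assert lo <= hi and lo >= w.ages[0] - 1e-9 and hi <= w.ages[-1] + 1e-9
            assert lo > prev_hi
            prev_hi = hi

    def test_nsims_guard(self, constant_beta_fit):
        fit, _ = constant_beta_fit
        with pytest.raises(ValueError):
            derivative_windows(fit, "s(age):beh", n_sims=10)

    def test_marginal_trajectories_linear_in_level(self, constant_beta_fit):
        # +1 SD and -1 SD curves are mirror-symmetric about the level-0 curve
        fit, _ = constant_beta_fit
        mt = marginal_trajectories(fit, "s(age):beh", levels_sd=(-1, 0, 1),
                                   grid_size=20)
        p = mt.pivot(index="age", columns="level_sd", values="predicted")
        assert np.allclose(p[1.0] + p[-1.0], 2 * p[0.0], atol=1e-10)

    def test_marginal_matches_design_matrix_oracle(self, constant_beta_fit):
        # brute-force prediction from the assembled design at one age
        fit, df = constant_beta_fit
        mt = marginal_trajectories(fit, "s(age):beh", levels_sd=(1.0,),
                                   grid_size=3)
        t = fit.term("s(age):beh")
        age0 = mt["age"].iloc[0]
        b_val = 1.0 * t.by_sd
        means = [1.0, fit.data_means["sex"], fit.data_means["visit"]]
        pred = 0.0
        lin = fit.term("linear")
        for m, c in zip(means, lin.fixed_idx):
            pred += m * fit.coefficients[c]
        for name in ("s(age)", "s(age):beh"):
            idx = fit.term_indices(name)
            val = (fit.smooth_curve_matrix(name, np.array([age0]))
                   @ fit.coefficients[idx])[0]
            pred += val * (b_val if name == "s(age):beh" else 1.0)
        assert mt["predicted"].iloc[0] == pytest.approx(pred, abs=1e-10)
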
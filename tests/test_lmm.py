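"""Mixed-model estimation: likelihood correctness, oracles, contrasts."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from equirest.design import generate_schedule
from equirest.lmm import (
    CELLS,
    CrossedLMM,
    ModelSpec,
    SingularDesignError,
    _LMMProblem,
    _random_design,
    build_fixed_design,
    contrast_estimate,
    fit_lmm,
    loglik_at,
    marginal_condition_contrasts,
)
from equirest.simulate import ExperimentSimParams, simulate_experiment


@pytest.fixture(scope="module")
def fitted(bouts_table):
    table, _ = bouts_table
    return fit_lmm(table, ModelSpec(outcome="n_bouts_per_h", offset=0.0), method="REML")


def dense_reml_criterion(X, Zh, Zd, y, gamma, reml=True):
    """Independent dense-matrix evaluation of the profiled deviance."""
    n, p = X.shape
    V0 = np.eye(n) + gamma[0] * Zh @ Zh.T + gamma[1] * Zd @ Zd.T
    Vi = np.linalg.inv(V0)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    prss = r @ Vi @ r
    sld = np.linalg.slogdet(V0)[1]
    if reml:
        df = n - p
        crit = sld + np.linalg.slogdet(XtViX)[1] + df * (1 + np.log(2 * np.pi) + np.log(prss / df))
    else:
        crit = sld + n * (1 + np.log(2 * np.pi) + np.log(prss / n))
    return crit, beta


class TestProfiledDeviance:
    @pytest.mark.parametrize("gamma", [(0.25, 0.09), (0.0, 1.44), (4.0, 1e-4)])
    @pytest.mark.parametrize("reml", [True, False])
    def test_matches_dense_matrix_formulation(self, bouts_table, gamma, reml):
        table, _ = bouts_table
        y = np.log(table["n_bouts_per_h"].to_numpy())
        X, _ = build_fixed_design(table, "full", "cell_means")
        (_, Zh), (_, Zd) = _random_design(table)
        prob = _LMMProblem(X, Zh, Zd)
        s = np.sqrt(np.array(gamma))
        crit, beta, *_ = prob.deviance(s, prob.rhs(y), reml)
        want_crit, want_beta = dense_reml_criterion(X, Zh, Zd, y, np.array(gamma), reml)
        assert crit == pytest.approx(want_crit, abs=1e-8)
        np.testing.assert_allclose(beta, want_beta, atol=1e-10)

    def test_refitting_at_returned_estimates_reproduces_loglik(self, fitted):
        ll = loglik_at(fitted, fitted.sigma2_horse, fitted.sigma2_date, fitted.sigma2_resid)
        assert ll == pytest.approx(fitted.loglik, abs=1e-6)

    def test_local_optimality_probe(self, fitted, rng):
        """The returned optimum beats 100 random perturbations of the
        variance components."""
        best = fitted.loglik
        for _ in range(100):
            f = np.exp(rng.normal(0, 0.5, size=3))
            ll = loglik_at(
                fitted,
                max(fitted.sigma2_horse, 1e-4) * f[0],
                max(fitted.sigma2_date, 1e-4) * f[1],
                fitted.sigma2_resid * f[2],
            )
            assert ll <= best + 1e-8


class TestAgainstReferences:
    def test_zero_variance_limit_matches_ols(self, study_schedule):
        """At the zero boundary of both random-effect variances the profiled
        fixed effects collapse to ordinary least squares on the cell dummies
        (with freely estimated variances the fit may legitimately absorb a
        little sampling variance, so the boundary is pinned explicitly)."""
        params = ExperimentSimParams.bouts_defaults(sigma2_horse=0.0, sigma2_date=0.0, sigma2_resid=0.4)
        table, _ = simulate_experiment(study_schedule, params, rng=np.random.default_rng(3))
        y = np.log(table["n_bouts_per_h"].to_numpy())
        X, _ = build_fixed_design(table, "full", "cell_means")
        (_, Zh), (_, Zd) = _random_design(table)
        prob = _LMMProblem(X, Zh, Zd)
        _, beta, *_ = prob.deviance(np.zeros(2), prob.rhs(y), True)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-6)
        # and the free fit estimates (near-)zero variance ratios
        fit = fit_lmm(table, ModelSpec(outcome="n_bouts_per_h", offset=0.0))
        assert fit.sigma2_horse < 0.05 and fit.sigma2_date < 0.05

    def test_noiseless_fixed_effect_data_recovers_cell_means(self, study_schedule):
        params = ExperimentSimParams.bouts_defaults(sigma2_horse=0.0, sigma2_date=0.0, sigma2_resid=1e-12)
        table, _ = simulate_experiment(study_schedule, params, rng=np.random.default_rng(4))
        fit = fit_lmm(table, ModelSpec(outcome="n_bouts_per_h", offset=0.0))
        np.testing.assert_allclose(fit.beta.to_numpy(), params.cell_means, atol=1e-5)
        assert fit.sigma2_horse < 1e-8 and fit.sigma2_date < 1e-8

    def test_agreement_with_lme4(self, bouts_table, tmp_path):
        """lmer(ylog ~ 0 + cell + (1|horse) + (1|date), REML) is the
        field-standard fit of the same model; estimates and restricted
        log-likelihood must agree."""
        table, _ = bouts_table
        fit = fit_lmm(table, ModelSpec(outcome="n_bouts_per_h", offset=0.0), method="REML")
        d = table.copy()
        d["ylog"] = np.log(d["n_bouts_per_h"])
        d["cell"] = d["condition"] + ":" + d["window"]
        csv = tmp_path / "d.csv"
        d.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{csv}")\n'
            'm <- lmer(ylog ~ 0 + cell + (1|horse_id) + (1|date), data=d, REML=TRUE)\n'
            'vc <- as.data.frame(VarCorr(m))\n'
            'out <- list(fe=as.list(fixef(m)), vc=setNames(as.list(vc$vcov), vc$grp), ll=logLik(m)[1])\n'
            'cat(jsonlite::toJSON(out, digits=12, auto_unbox=TRUE))\n'
        )
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        ref = json.loads(proc.stdout)
        assert fit.loglik == pytest.approx(ref["ll"], abs=1e-6)
        assert fit.sigma2_horse == pytest.approx(ref["vc"]["horse_id"], abs=1e-5)
        assert fit.sigma2_date == pytest.approx(ref["vc"]["date"], abs=1e-5)
        assert fit.sigma2_resid == pytest.approx(ref["vc"]["Residual"], abs=1e-5)
        cells = fit.cell_means()
        for key, value in ref["fe"].items():
            c, w = key.removeprefix("cell").split(":")
            assert cells.loc[c, w] == pytest.approx(value, abs=1e-5)


class TestCodingInvariance:
    def test_cell_means_and_treatment_codings_agree(self, bouts_table):
        table, _ = bouts_table
        f_cm = fit_lmm(table, ModelSpec(outcome="n_bouts_per_h", offset=0.0, coding="cell_means"))
        f_tr = fit_lmm(table, ModelSpec(outcome="n_bouts_per_h", offset=0.0, coding="treatment"))
        np.testing.assert_allclose(f_cm.cell_means().to_numpy(), f_tr.cell_means().to_numpy(), atol=1e-8)
        assert f_cm.sigma2_horse == pytest.approx(f_tr.sigma2_horse, abs=1e-6)
        assert f_cm.loglik == pytest.approx(f_tr.loglik, abs=1e-6)
        for a, b in zip(marginal_condition_contrasts(f_cm), marginal_condition_contrasts(f_tr)):
            assert a.log_estimate == pytest.approx(b.log_estimate, abs=1e-8)


class TestContrasts:
    def test_identical_cell_means_give_unit_factors(self, fitted):
        flat = fitted
        flat = type(flat)(
            beta=pd.Series(np.full(6, -1.2), index=flat.beta.index),
            sigma2_horse=0.1, sigma2_date=0.1, sigma2_resid=0.3,
            loglik=0.0, converged=True, method="REML", offset=0.0,
            outcome="n_bouts_per_h", coding="cell_means", n_obs=120,
        )
        for c in marginal_condition_contrasts(flat):
            assert c.factor == pytest.approx(1.0)

    def test_uniform_night_shift_gives_factor_two(self, fitted):
        beta = pd.Series(
            [(np.log(2.0) if w == "NIGHT" else 0.0) - 1.0 for _, w in CELLS],
            index=[f"{c}:{w}" for c, w in CELLS],
        )
        shifted = type(fitted)(
            beta=beta, sigma2_horse=0.1, sigma2_date=0.1, sigma2_resid=0.3,
            loglik=0.0, converged=True, method="REML", offset=0.0,
            outcome="n_bouts_per_h", coding="cell_means", n_obs=120,
        )
        night = [c for c in marginal_condition_contrasts(shifted) if c.name == "night_vs_day"][0]
        assert night.factor == pytest.approx(2.0)

    def test_contrasts_match_direct_cell_mean_average(self, fitted, rng):
        beta = pd.Series(rng.normal(size=6), index=fitted.beta.index)
        f = type(fitted)(
            beta=beta, sigma2_horse=0.1, sigma2_date=0.1, sigma2_resid=0.3,
            loglik=0.0, converged=True, method="REML", offset=0.0,
            outcome="n_bouts_per_h", coding="cell_means", n_obs=120,
        )
        cells = {cw: beta[f"{cw[0]}:{cw[1]}"] for cw in CELLS}
        want_alone = np.mean([cells[("ALONE", w)] - cells[("BOX", w)] for w in ("DAY", "NIGHT")])
        want_night = np.mean([cells[(c, "NIGHT")] - cells[(c, "DAY")] for c in ("BOX", "ALONE", "PAIRS")])
        _, got_alone = contrast_estimate(f, "alone_vs_box")
        _, got_night = contrast_estimate(f, "night_vs_day")
        assert got_alone == pytest.approx(want_alone, abs=1e-12)
        assert got_night == pytest.approx(want_night, abs=1e-12)


class TestValidationAndOffset:
    def test_empty_cell_is_named(self, bouts_table):
        table, _ = bouts_table
        broken = table[~((table.condition == "PAIRS") & (table.window == "DAY"))]
        with pytest.raises(SingularDesignError, match="PAIRS"):
            fit_lmm(broken, ModelSpec(outcome="n_bouts_per_h", offset=0.0))

    def test_auto_offset_zero_for_positive_outcomes(self, bouts_table):
        table, _ = bouts_table
        fit = fit_lmm(table, ModelSpec(outcome="n_bouts_per_h", offset="auto"))
        assert fit.offset == 0.0

    def test_auto_offset_half_smallest_observable_bout_rate(self, bouts_table):
        table, _ = bouts_table
        table = table.copy()
        idx = table.index[table.window == "DAY"][0]
        table.loc[idx, "n_bouts_per_h"] = 0.0
        fit = fit_lmm(table, ModelSpec(outcome="n_bouts_per_h", offset="auto"))
        assert fit.offset == pytest.approx(0.5 / 14.5)

    def test_explicit_zero_offset_with_zeros_rejected(self, bouts_table):
        table, _ = bouts_table
        table = table.copy()
        table.loc[table.index[0], "n_bouts_per_h"] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            fit_lmm(table, ModelSpec(outcome="n_bouts_per_h", offset=0.0))


class TestCrossedLMMEstimator:
    def test_fit_exposes_sklearn_attributes(self, bouts_table):
        table, _ = bouts_table
        est = CrossedLMM(offset=0.0).fit(table, outcome="n_bouts_per_h")
        assert est.converged_
        assert est.sigma2_resid_ > 0
        assert len(est.beta_) == 6
        assert set(CrossedLMM().get_params()) == {"offset", "method", "coding"}

    def test_predict_returns_cell_mean_scale(self, bouts_table):
        table, _ = bouts_table
        est = CrossedLMM(offset=0.0).fit(table, outcome="n_bouts_per_h")
        pred = est.predict(table)
        assert pred.shape == (len(table),)
        assert (pred > 0).all()
        # same design cell -> same prediction
        first = table.iloc[0]
        same = (table.condition == first.condition) & (table.window == first.window)
        assert np.ptp(pred[same.to_numpy()]) == 0
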
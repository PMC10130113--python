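"""OLS / LMM fitting, R-squared decompositions and scalar statistics."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from pursuitkit.analysis import (
    SpecificationError,
    adjusted_r,
    cohort_table,
    effect_size_d,
    fit_lmm,
    fit_ols_prediction,
    marginal_conditional_r2,
    part_r2_lmm,
    part_r2_ols,
    per_participant_mae,
    run_paper_analysis,
    weighted_mae,
)


def _grouped_data(g=10, m=4, s_u=1.2, s_e=0.7, beta=(2.0, 0.8, -0.5), seed=0):
    rng = np.random.default_rng(seed)
    pid = np.repeat([f"P{i:02d}" for i in range(g)], m)
    x1 = rng.normal(size=g * m)
    x2 = rng.normal(size=g * m)
    u = rng.normal(0, s_u, g)
    y = beta[0] + beta[1] * x1 + beta[2] * x2 + np.repeat(u, m)
    y = y + rng.normal(0, s_e, g * m)
    return pd.DataFrame({"participant_id": pid, "x1": x1, "x2": x2, "y": y})


class TestOLS:
    def test_self_prediction_r2_one(self):
        df = _grouped_data(6, 1)
        df["copy"] = df["y"]
        rep = fit_ols_prediction(df, ["copy"], "y")
        assert rep.r_squared == pytest.approx(1.0)

    def test_independent_response_r2_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"x1": rng.normal(size=10_000), "y": rng.normal(size=10_000)}
        )
        rep = fit_ols_prediction(df, ["x1"], "y")
        assert rep.r_squared < 0.01

    def test_noiseless_recovery(self):
        df = _grouped_data(30, 1, s_u=0.0, s_e=1e-9)
        rep = fit_ols_prediction(df, ["x1", "x2"], "y")
        assert rep.coefficients["intercept"] == pytest.approx(2.0, abs=1e-6)
        assert rep.coefficients["x1"] == pytest.approx(0.8, abs=1e-6)
        assert rep.coefficients["x2"] == pytest.approx(-0.5, abs=1e-6)

    def test_collinear_design_rejected(self):
        df = _grouped_data(10, 1)
        df["x1_dup"] = df["x1"]
        with pytest.raises(SpecificationError, match="rank"):
            fit_ols_prediction(df, ["x1", "x1_dup"], "y")

    def test_too_few_rows_rejected(self):
        df = _grouped_data(3, 1)
        with pytest.raises(SpecificationError):
            fit_ols_prediction(df.head(3), ["x1", "x2"], "y")


class TestPartR2OLS:
    def test_orthogonal_decomposition(self):
        # with mutually orthogonal predictors, part R2 of each set equals
        # its simple contribution, and disjoint sets add up
        n = 64
        t = np.arange(n)
        X = np.column_stack(
            [np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n),
             np.cos(4 * np.pi * t / n)]
        )
        y = X @ [1.0, 0.6, 0.4] + np.random.default_rng(2).normal(0, 0.3, n)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        full = fit_ols_prediction(df, ["a", "b", "c"], "y").r_squared
        controls = fit_ols_prediction(df, ["c"], "y").r_squared
        part_a = part_r2_ols(df, ["a"], ["b", "c"], "y")
        part_b = part_r2_ols(df, ["b"], ["a", "c"], "y")
        assert part_a + part_b == pytest.approx(full - controls, abs=1e-9)

    def test_null_focal_predictor(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=5000),
                "noise": rng.normal(size=5000),
            }
        )
        df["y"] = 2 * df["x"] + rng.normal(size=5000)
        assert part_r2_ols(df, ["noise"], ["x"], "y") < 0.005

    def test_overlapping_sets_rejected(self):
        df = _grouped_data(10, 1)
        with pytest.raises(SpecificationError, match="overlap"):
            part_r2_ols(df, ["x1"], ["x1", "x2"], "y")

    def test_equals_two_fit_oracle(self):
        df = _grouped_data(20, 1, seed=5)
        got = part_r2_ols(df, ["x1"], ["x2"], "y")
        oracle = (
            fit_ols_prediction(df, ["x2", "x1"], "y").r_squared
            - fit_ols_prediction(df, ["x2"], "y").r_squared
        )
        assert got == pytest.approx(oracle, abs=1e-12)


class TestLMM:
    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        df = _grouped_data(seed=0)
        mine = fit_lmm(df, ["x1", "x2"], "y", method="REML")
        sm_fit = smf.mixedlm("y ~ x1 + x2", df, groups=df["participant_id"]).fit(
            reml=True
        )
        for i, name in enumerate(["intercept", "x1", "x2"]):
            assert mine.coefficients[name] == pytest.approx(
                sm_fit.fe_params.iloc[i], abs=1e-4
            )
            assert mine.se[name] == pytest.approx(sm_fit.bse_fe.iloc[i], rel=1e-2)
        assert mine.sigma_u**2 == pytest.approx(sm_fit.cov_re.iloc[0, 0], rel=1e-2)
        assert mine.sigma_e**2 == pytest.approx(sm_fit.scale, rel=1e-2)

    def test_satterthwaite_df_matches_lmerTest(self, tmp_path):
        # independent oracle: lme4/lmerTest via Rscript
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = _grouped_data(seed=0)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = f"""
        suppressMessages({{library(lme4); library(lmerTest)}})
        d <- read.csv("{csv}")
        m <- lmer(y ~ x1 + x2 + (1|participant_id), data=d, REML=TRUE)
        co <- coef(summary(m))
        cat(co["x1","df"], co["x2","df"], co["x1","Estimate"], sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        df_x1, df_x2, est_x1 = map(float, out.stdout.strip().splitlines()[-3:])
        mine = fit_lmm(df, ["x1", "x2"], "y", method="REML")
        assert mine.f_tests["x1"]["df_den"] == pytest.approx(df_x1, abs=0.2)
        assert mine.f_tests["x2"]["df_den"] == pytest.approx(df_x2, abs=0.2)
        assert mine.coefficients["x1"] == pytest.approx(est_x1, abs=1e-5)

    def test_zero_between_variance_matches_ols(self):
        # with no true participant variance the variance ratio collapses
        # to the boundary and the GLS step degenerates to OLS
        df = _grouped_data(150, 3, s_u=0.0, s_e=0.8, seed=4)
        lmm = fit_lmm(df, ["x1", "x2"], "y", method="ML")
        ols = fit_ols_prediction(df, ["x1", "x2"], "y")
        assert lmm.sigma_u < 0.1
        for name in ("intercept", "x1", "x2"):
            assert lmm.coefficients[name] == pytest.approx(
                ols.coefficients[name], abs=1e-3
            )

    def test_balanced_between_subject_design_recovers_classical_f(self):
        # balanced one-way layout: the Satterthwaite denominator df must
        # equal the classical g-2 and F must match the participant-mean
        # regression F
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        g, m = 10, 4
        pid = np.repeat([f"P{i}" for i in range(g)], m)
        xb = np.repeat(rng.normal(size=g), m)
        y = 1 + 0.6 * xb + np.repeat(rng.normal(0, 1.0, g), m)
        y = y + rng.normal(0, 0.7, g * m)
        df = pd.DataFrame({"participant_id": pid, "xb": xb, "y": y})
        mine = fit_lmm(df, ["xb"], "y", method="REML")
        pm = df.groupby("participant_id").mean(numeric_only=True)
        oracle = sm.OLS(pm["y"], sm.add_constant(pm["xb"])).fit()
        assert mine.f_tests["xb"]["df_den"] == pytest.approx(g - 2, abs=1e-3)
        assert mine.f_tests["xb"]["F"] == pytest.approx(oracle.fvalue, rel=1e-4)

    def test_duplicating_rows_perturbs_ml_fixed_effects_only_slightly(self):
        # exact replication is NOT a no-op for mixed models (the GLS
        # weights depend on group size; statsmodels MixedLM shows the
        # identical shift), but the estimates must stay close
        df = _grouped_data(seed=6)
        doubled = pd.concat([df, df], ignore_index=True)
        a = fit_lmm(df, ["x1", "x2"], "y", method="ML")
        b = fit_lmm(doubled, ["x1", "x2"], "y", method="ML")
        for name in ("intercept", "x1", "x2"):
            assert a.coefficients[name] == pytest.approx(b.coefficients[name], abs=0.05)

    def test_single_group_rejected(self):
        df = _grouped_data(1, 8)
        with pytest.raises(SpecificationError):
            fit_lmm(df, ["x1"], "y")


class TestR2Decompositions:
    def test_zero_random_variance_makes_r2m_equal_r2c(self):
        df = _grouped_data(12, 4, s_u=0.0, s_e=0.8, seed=4)
        rep = fit_lmm(df, ["x1", "x2"], "y")
        r2m, r2c = marginal_conditional_r2(rep)
        assert r2c - r2m < 0.05

    def test_intercept_only_model_has_zero_marginal_r2(self):
        rng = np.random.default_rng(7)
        g, m = 40, 4
        pid = np.repeat(np.arange(g).astype(str), m)
        y = np.repeat(rng.normal(0, 1.2, g), m) + rng.normal(0, 0.7, g * m)
        df = pd.DataFrame({"participant_id": pid, "y": y})
        rep = fit_lmm(df, [], "y")
        assert rep.marginal_r2 == pytest.approx(0.0, abs=1e-12)
        # ICC = 1.44 / (1.44 + 0.49) ~ 0.75
        assert rep.conditional_r2 == pytest.approx(0.75, abs=0.12)

    def test_plug_in_variance_components(self):
        # var(fixed) = 1, s2_u = 1, s2_e = 2 -> R2m = 0.25, R2c = 0.50
        rng = np.random.default_rng(9)
        g, m = 150, 6
        pid = np.repeat(np.arange(g).astype(str), m)
        x = rng.normal(size=g * m)  # unit variance, coefficient 1
        y = x + np.repeat(rng.normal(0, 1.0, g), m) + rng.normal(0, np.sqrt(2), g * m)
        df = pd.DataFrame({"participant_id": pid, "x": x, "y": y})
        rep = fit_lmm(df, ["x"], "y")
        assert rep.marginal_r2 == pytest.approx(0.25, abs=0.03)
        assert rep.conditional_r2 == pytest.approx(0.50, abs=0.03)

    def test_ordering_invariant(self):
        for seed in range(5):
            rep = fit_lmm(_grouped_data(seed=seed), ["x1", "x2"], "y")
            assert 0 <= rep.marginal_r2 <= rep.conditional_r2 <= 1


class TestPartR2LMM:
    def test_removing_all_fixed_effects_recovers_full_marginal_r2(self):
        df = _grouped_data(seed=10)
        out = part_r2_lmm(df, ["x1", "x2"], [], "y", n_boot=0)
        full = fit_lmm(df, ["x1", "x2"], "y", method="ML")
        assert out["part_r2_marginal"] == pytest.approx(full.marginal_r2, abs=1e-9)

    def test_null_focal_near_zero(self):
        rng = np.random.default_rng(11)
        g, m = 80, 4
        pid = np.repeat(np.arange(g).astype(str), m)
        x = rng.normal(size=g * m)
        noise = rng.normal(size=g * m)
        y = x + np.repeat(rng.normal(0, 0.8, g), m) + rng.normal(0, 1, g * m)
        df = pd.DataFrame({"participant_id": pid, "x": x, "noise": noise, "y": y})
        out = part_r2_lmm(df, ["noise"], ["x"], "y", n_boot=0)
        assert abs(out["part_r2_marginal"]) < 0.01

    def test_bootstrap_ci_brackets_estimate(self):
        df = _grouped_data(seed=12)
        out = part_r2_lmm(df, ["x1"], ["x2"], "y", n_boot=60, seed=1)
        lo, hi = out["ci_marginal"]
        assert lo <= hi
        assert hi > 0

    def test_centering_invariance(self):
        df = _grouped_data(seed=13)
        raw = part_r2_lmm(df, ["x1"], ["x2"], "y", n_boot=0)
        shifted = df.copy()
        shifted["x1"] = shifted["x1"] + 100.0
        shifted["x2"] = shifted["x2"] - 55.0
        cen = part_r2_lmm(shifted, ["x1"], ["x2"], "y", n_boot=0)
        assert raw["part_r2_marginal"] == pytest.approx(
            cen["part_r2_marginal"], abs=1e-6
        )


class TestScalarStatistics:
    def test_adjusted_r_examples(self):
        assert adjusted_r(0.90, 11, 2) == pytest.approx(0.87, abs=0.005)
        assert adjusted_r(1.0, 11, 2) == pytest.approx(1.0)
        assert adjusted_r(0.5, 10**6, 2) == pytest.approx(0.500, abs=1e-3)
        assert adjusted_r(-0.90, 11, 2) == pytest.approx(-0.87, abs=0.005)

    def test_adjusted_r_domain(self):
        with pytest.raises(ValueError):
            adjusted_r(0.5, 3, 2)
        with pytest.raises(ValueError):
            adjusted_r(1.5, 10, 2)

    def test_effect_size_d(self):
        assert effect_size_d(0.0) == 0.0
        assert effect_size_d(0.6) == pytest.approx(1.5)
        assert effect_size_d(np.sqrt(0.68)) == pytest.approx(2.90, abs=0.03)
        with pytest.raises(ValueError):
            effect_size_d(1.0)

    def test_weighted_mae_single_participant_is_plain_mae(self):
        pred = np.array([1.0, 2.0, 3.0])
        act = np.array([1.5, 2.5, 2.0])
        ids = np.array(["a", "a", "a"])
        assert weighted_mae(pred, act, ids) == pytest.approx(np.mean([0.5, 0.5, 1.0]))

    def test_weighted_mae_unequal_session_counts(self):
        # participant a: residuals (1, 1, 1) -> 1.0; b: (3,) -> 3.0
        pred = np.array([0.0, 0.0, 0.0, 0.0])
        act = np.array([1.0, 1.0, 1.0, 3.0])
        ids = np.array(["a", "a", "a", "b"])
        assert weighted_mae(pred, act, ids) == pytest.approx(2.0)

    def test_weighted_mae_zero_residuals(self):
        x = np.arange(4.0)
        assert weighted_mae(x, x, np.array(["a", "a", "b", "b"])) == 0.0

    def test_weighted_mae_alignment(self):
        with pytest.raises(ValueError):
            weighted_mae(np.zeros(3), np.zeros(3), np.array(["a", "b"]))

    def test_per_participant_mae_range(self):
        pred = np.array([0.0, 0.0, 0.0])
        act = np.array([1.0, 2.0, 5.0])
        ids = np.array(["a", "a", "b"])
        mae = per_participant_mae(pred, act, ids)
        assert mae["a"] == pytest.approx(1.5)
        assert mae["b"] == pytest.approx(5.0)


@pytest.fixture(scope="module")
def cohort(score_battery):
    from pursuitkit.simulator import CohortSpec, simulate_cohort

    spec = CohortSpec(seed=21)
    table, _ = simulate_cohort(spec, battery=score_battery,
                               labels=["spiralA", "zigzagA"])
    return table


class TestRunPaperAnalysis:
    def test_report_is_deterministic(self, cohort):
        a = run_paper_analysis(cohort, seed=3)
        b = run_paper_analysis(cohort, seed=3)
        assert a == b

    def test_report_structure_and_sanity(self, cohort):
        rep = run_paper_analysis(cohort)
        init = rep["rq1_initial"]
        assert init["n"] == cohort["participant_id"].nunique()
        assert 0 <= init["r_squared"] <= 1
        assert abs(init["r_adj"]) <= abs(init["r"]) + 1e-12
        repeated = rep["rq1_repeated"]
        assert repeated["df_method"] == "satterthwaite"
        assert 0 <= repeated["marginal_r2"] <= repeated["conditional_r2"] <= 1
        assert repeated["weighted_mae"] >= 0
        assert set(rep["rq2"]) == {"dir_spiralA", "dir_zigzagA",
                                   "spa_spiralA", "spa_zigzagA"}

    def test_duplicate_sessions_rejected(self, cohort):
        bad = pd.concat([cohort, cohort.head(1)], ignore_index=True)
        with pytest.raises(SpecificationError, match="duplicate"):
            cohort_table(bad)
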
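"""Severity, hurdle, ordinal, and mixed-model associations."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from keyphen import (
    CohortConfig,
    generate_cohort,
    hurdle_gamma,
    hurdle_log_likelihood,
    lmm_group_test,
    ordinal_item_model,
    severity_regression,
    symptom_item_models,
)

warnings.filterwarnings("ignore", category=UserWarning)


def _toy_clinical(labels, hamd, ymrs=None):
    n = len(labels)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": "MD",
            "diagnosis": "unipolar",
            "medication": "no",
            "hamd_total": hamd,
            "ymrs_total": ymrs if ymrs is not None else np.zeros(n),
        }
    )
    return df, pd.Series(labels, index=df.index)


class TestSeverityRegression:
    def test_noise_free_effect_recovered_exactly(self):
        labels = ["Low"] * 10 + ["Medium"] * 10
        hamd = np.array([5.0] * 10 + [7.32] * 10)
        clin, lab = _toy_clinical(labels, hamd)
        res = severity_regression(clin, lab)
        b = res.table.set_index("term")["estimate"]
        assert b["Medium"] == pytest.approx(2.32, abs=1e-12)
        assert b["const"] == pytest.approx(5.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        labels = rng.choice(["Low", "Medium", "High"], size=60)
        hamd = rng.normal(6, 3, size=60)
        clin, lab = _toy_clinical(labels, hamd)
        res = severity_regression(clin, lab)
        X = np.column_stack(
            [np.ones(60), labels == "Medium", labels == "High"]
        ).astype(float)
        beta = np.linalg.solve(X.T @ X, X.T @ hamd)
        got = res.table.set_index("term")["estimate"]
        assert got["const"] == pytest.approx(beta[0], abs=1e-8)
        assert got["Medium"] == pytest.approx(beta[1], abs=1e-8)
        assert got["High"] == pytest.approx(beta[2], abs=1e-8)

    def test_collinear_covariate_dropped_with_warning(self):
        labels = ["Low"] * 8 + ["Medium"] * 8
        clin, lab = _toy_clinical(labels, np.arange(16.0))
        # all subjects share diagnosis & medication: adjusted design is
        # rank-deficient in the constant
        with pytest.warns(UserWarning, match="collinear"):
            res = severity_regression(clin, lab, adjust=True)
        assert "Medium" in set(res.table["term"])

    def test_generating_truth_recovered_within_2se(self):
        hits = 0
        for s in range(10):
            _, clin, truth = generate_cohort(seed=200 + s)
            res = severity_regression(clin, truth["subjects"]["label"])
            row = res.table.set_index("term").loc["Medium"]
            hits += abs(row["estimate"] - 2.32) <= 2 * row["se"]
        assert hits >= 8


class TestHurdleGamma:
    def test_loglik_decomposes_exactly(self, rng):
        for _ in range(5):
            labels = rng.choice(["Low", "Medium", "High"], size=80)
            y = np.where(rng.random(80) < 0.5, 0.0, rng.gamma(2.0, 2.0, 80))
            clin, lab = _toy_clinical(labels, np.zeros(80), ymrs=y)
            res = hurdle_gamma(clin, lab)
            X = np.column_stack(
                [np.ones(80), labels == "Medium", labels == "High"]
            ).astype(float)
            total, binary, positive = hurdle_log_likelihood(
                y,
                X,
                res.extra["logit_params"],
                res.extra["gamma_params"],
                res.extra["gamma_shape"],
            )
            assert total == pytest.approx(binary + positive, abs=1e-9)
            assert binary == pytest.approx(res.extra["logit_llf"], abs=1e-6)

    def test_null_effects_covered(self):
        inside = 0
        reps = 20
        for s in range(reps):
            r = np.random.default_rng(3000 + s)
            labels = np.repeat(["Low", "Medium"], 60)
            y = np.where(r.random(120) < 0.5, 0.0, r.gamma(2.0, 1.5, 120))
            clin, lab = _toy_clinical(labels, np.zeros(120), ymrs=y)
            res = hurdle_gamma(clin, lab)
            t = res.table.set_index(["part", "term"])
            ok = True
            for part in ("nonzero", "positive"):
                row = t.loc[(part, "Medium")]
                ok &= abs(row["estimate"]) <= 2 * row["se"]
            inside += ok
        assert inside >= 0.8 * reps  # ~90% joint coverage of two 95% checks

    def test_all_zero_outcome_skips_parts(self):
        clin, lab = _toy_clinical(["Low"] * 10 + ["High"] * 10, np.zeros(20))
        res = hurdle_gamma(clin, lab)
        assert not res.converged
        assert any("skipped" in n for n in res.notes)

    def test_generating_truths_recovered_within_2se(self):
        hits_zero = hits_pos = 0
        for s in range(10):
            _, clin, truth = generate_cohort(seed=400 + s)
            res = hurdle_gamma(clin, truth["subjects"]["label"])
            t = res.table.set_index(["part", "term"])
            rz = t.loc[("nonzero", "High")]
            rp = t.loc[("positive", "High")]
            hits_zero += abs(rz["estimate"] - 1.91) <= 2 * rz["se"]
            hits_pos += abs(rp["estimate"] - 1.46) <= 2 * rp["se"]
        assert hits_zero >= 8
        assert hits_pos >= 8


class TestOrdinalItemModel:
    def test_identical_groups_give_or_near_one(self):
        r = np.random.default_rng(6)
        item = np.tile(r.integers(0, 3, size=60), 2)
        labels = np.repeat(["Low", "Medium"], 60)
        res = ordinal_item_model(item, labels)
        row = res.table.set_index("term").loc["Medium"]
        assert abs(row["estimate"]) <= 2 * row["se"]

    def test_binary_item_reduces_to_logistic_regression(self, rng):
        item = rng.integers(0, 2, size=120)
        labels = rng.choice(["Low", "Medium", "High"], size=120)
        res = ordinal_item_model(item, labels)
        X = sm.add_constant(
            np.column_stack([labels == "Medium", labels == "High"]).astype(float)
        )
        logit = sm.Logit(item, X).fit(disp=0)
        got = res.table.set_index("term")
        # cumulative logit of P(Y<=0) = -logit of P(Y=1): slopes match
        assert got.loc["Medium", "estimate"] == pytest.approx(logit.params[1], abs=1e-5)
        assert got.loc["High", "estimate"] == pytest.approx(logit.params[2], abs=1e-5)
        assert got.loc["Medium", "se"] == pytest.approx(logit.bse[1], abs=1e-4)

    def test_thresholds_strictly_increasing(self, rng):
        item = rng.integers(0, 5, size=150)
        labels = rng.choice(["Low", "Medium", "High"], size=150)
        res = ordinal_item_model(item, labels)
        th = res.extra["thresholds"]
        assert np.all(np.diff(th) > 0)

    def test_or_ci_round_trip(self, rng):
        item = rng.integers(0, 3, size=100)
        labels = rng.choice(["Low", "Medium"], size=100)
        res = ordinal_item_model(item, labels)
        t = res.table
        assert np.allclose(t["or_"], np.exp(t["estimate"]))
        assert ((t["ci_low"] <= t["or_"]) & (t["or_"] <= t["ci_high"])).all()

    def test_structural_zero_triggers_drop_and_refit(self, rng):
        item = rng.integers(0, 3, size=90)
        labels = np.repeat(["Low", "Medium", "High"], 30)
        item[labels == "High"] = 0  # structural zero in the High group
        res = ordinal_item_model(item, labels)
        assert not res.converged
        assert res.extra["dropped_groups"] == ["High"]
        keep = labels != "High"
        fresh = ordinal_item_model(item[keep], labels[keep])
        pd.testing.assert_frame_equal(res.table, fresh.table)

    def test_constant_item_gives_note_only(self):
        res = ordinal_item_model(np.zeros(40), np.repeat(["Low", "Medium"], 20))
        assert not res.converged
        assert res.table.empty
        assert "constant item" in res.notes[0]

    def test_generating_or_truth_recovered_within_2se(self):
        hits = 0
        for s in range(10):
            _, clin, truth = generate_cohort(seed=600 + s)
            res = ordinal_item_model(
                clin["hamd_5"], truth["subjects"]["label"], item_name="middle_insomnia"
            )
            row = res.table.set_index("term").loc["High"]
            hits += abs(row["estimate"] - np.log(6.82)) <= 2 * row["se"]
        assert hits >= 8

    def test_cohort_item_battery_mirrors_structural_zero_protocol(self):
        _, clin, truth = generate_cohort(seed=7)
        out = symptom_item_models(clin, truth["subjects"]["label"])
        assert out["ymrs_9"].table.empty  # nobody endorses disruptive behaviour
        assert out["hamd_2"].extra.get("dropped_groups") == ["High"]
        assert out["hamd_15"].extra.get("dropped_groups") == ["Low"]


class TestLmmGroupTest:
    def test_balanced_icc_matches_anova_oracle(self):
        r = np.random.default_rng(11)
        n_subj, n_days = 40, 8
        tau, sig = 0.03, 0.05
        u = r.normal(0, tau, n_subj)
        y = 0.15 + u[:, None] + r.normal(0, sig, (n_subj, n_days))
        daily = pd.DataFrame(
            {
                "subject_id": np.repeat([f"s{i:02d}" for i in range(n_subj)], n_days),
                "rate": y.ravel(),
            }
        )
        clin = pd.DataFrame(
            {
                "subject_id": [f"s{i:02d}" for i in range(n_subj)],
                "group": ["HC"] * 20 + ["MD"] * 20,
            }
        )
        res = lmm_group_test(daily, clin, reml=True)
        # balanced ANOVA method-of-moments variance components, with
        # subject means centered on their group mean (the fixed effect);
        # REML reproduces this estimator exactly in a balanced design
        subj_means = y.mean(axis=1)
        group_means = np.repeat([subj_means[:20].mean(), subj_means[20:].mean()], 20)
        ms_between = n_days * ((subj_means - group_means) ** 2).sum() / (n_subj - 2)
        ms_within = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (
            n_subj * (n_days - 1)
        )
        tau2_mom = (ms_between - ms_within) / n_days
        icc_mom = tau2_mom / (tau2_mom + ms_within)
        tau2 = res.extra["random_intercept_var"]
        icc = tau2 / (tau2 + res.extra["residual_var"])
        assert icc == pytest.approx(icc_mom, abs=1e-6)

    def test_null_group_effect_calibration(self):
        covered = 0
        reps = 50
        for s in range(reps):
            r = np.random.default_rng(5000 + s)
            n_subj, n_days = 40, 6
            u = r.normal(0, 0.02, n_subj)
            y = 0.16 + u[:, None] + r.normal(0, 0.05, (n_subj, n_days))
            daily = pd.DataFrame(
                {
                    "subject_id": np.repeat([f"s{i:02d}" for i in range(n_subj)], n_days),
                    "rate": y.ravel(),
                }
            )
            clin = pd.DataFrame(
                {
                    "subject_id": [f"s{i:02d}" for i in range(n_subj)],
                    "group": ["HC"] * 20 + ["MD"] * 20,
                }
            )
            res = lmm_group_test(daily, clin, reml=True)
            row = res.table.set_index("term").loc["group[MD]"]
            covered += abs(row["estimate"]) <= 2 * row["se"]
        assert covered >= 0.9 * reps

    def test_group_effect_detected_on_cohort_scale(self):
        """A 0.02 shift in daily rates at the cohort's size is detectable."""
        detected = 0
        for s in range(5):
            r = np.random.default_rng(7000 + s)
            n_subj, n_days = 128, 23
            groups = np.array(["HC"] * 27 + ["MD"] * 101)
            u = r.normal(0, 0.03, n_subj)
            shift = np.where(groups == "MD", 0.02, 0.0)
            y = 0.15 + shift[:, None] + u[:, None] + r.normal(0, 0.05, (n_subj, n_days))
            ids = [f"s{i:03d}" for i in range(n_subj)]
            daily = pd.DataFrame(
                {"subject_id": np.repeat(ids, n_days), "rate": y.ravel()}
            )
            clin = pd.DataFrame({"subject_id": ids, "group": groups})
            res = lmm_group_test(daily, clin)
            detected += res.table.set_index("term").loc["group[MD]", "p"] < 0.05
        assert detected >= 4
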
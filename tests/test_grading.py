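"""Budding-grade assignment, stepwise Cox and the grade survival report."""

import itertools

import numpy as np
import pandas as pd
import pytest

from morphome import (
    FitError,
    assign_budding_grade,
    build_clinical_design,
    cox_fit,
    cox_loglik,
    fit_selected_cox,
    grade_survival_report,
    linear_predictor,
    stepwise_cox,
)


def eta_series(values, ids=None):
    ids = ids or [f"P{i:03d}" for i in range(len(values))]
    return pd.Series(values, index=ids)


class TestGradeAssignment:
    def test_171_patients_split_86_85(self):
        rng = np.random.default_rng(0)
        grades = assign_budding_grade(eta_series(rng.normal(size=171)))
        counts = grades["grade"].value_counts()
        assert counts["low"] == 86 and counts["high"] == 85

    def test_two_patients(self):
        g = assign_budding_grade(eta_series([0.3, -0.1]))
        assert sorted(g["grade"]) == ["high", "low"]
        assert g.loc[g["linear_predictor"] == -0.1, "grade"].item() == "low"

    def test_all_ties_resolved_by_patient_id(self):
        g = assign_budding_grade(eta_series([1.0] * 5))
        assert (g["grade"] == "low").sum() == 3
        by_id = g.set_index("patient_id")["grade"]
        # lexicographically first ids become low
        assert by_id.loc[["P000", "P001", "P002"]].eq("low").all()
        assert by_id.loc[["P003", "P004"]].eq("high").all()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        eta = eta_series(rng.normal(size=30))
        g1 = assign_budding_grade(eta)
        g2 = assign_budding_grade(np.exp(eta * 3) + 7)
        assert (g1["grade"] == g2["grade"]).all()

    def test_high_group_has_larger_eta(self):
        rng = np.random.default_rng(2)
        eta = eta_series(rng.normal(size=41))
        g = assign_budding_grade(eta)
        assert g.loc[g["grade"] == "high", "linear_predictor"].min() >= \
            g.loc[g["grade"] == "low", "linear_predictor"].max()

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            assign_budding_grade(eta_series([1.0]))


class TestFitSelectedCox:
    def test_delegates_to_cox_fit(self, medium_cohort):
        X = medium_cohort.features
        t = medium_cohort.clinical["time_months"].to_numpy()
        e = medium_cohort.clinical["event"].to_numpy(bool)
        sel = ["buds.10", "buds.35", "cyto.15", "cyto.30"]
        fit1 = fit_selected_cox(X, t, e, selected=sel)
        fit2 = cox_fit(np.asarray(X[sel]), t, e, feature_names=sel)
        np.testing.assert_array_equal(fit1.coefficients, fit2.coefficients)

    def test_planted_signs_recovered(self, medium_cohort):
        # cytoplasmic shift harmful (HR > 1), large clusters protective
        X = medium_cohort.features
        t = medium_cohort.clinical["time_months"].to_numpy()
        e = medium_cohort.clinical["event"].to_numpy(bool)
        fit = fit_selected_cox(X, t, e, selected=["buds.35", "cyto.15"])
        s = fit.summary()
        assert s.loc["cyto.15", "hazard_ratio"] > 1
        assert s.loc["buds.35", "hazard_ratio"] < 1

    def test_null_single_feature_ci_contains_one(self):
        rng = np.random.default_rng(3)
        n = 120
        X = pd.DataFrame({"f": rng.normal(size=n)})
        t = rng.exponential(10, n) + 0.1
        e = rng.random(n) < 0.7
        fit = fit_selected_cox(X, t, e, selected=["f"])
        lo, hi = fit.ci95[0]
        assert lo < 1 < hi

    def test_empty_selection_rejected(self, medium_cohort):
        X = medium_cohort.features
        t = medium_cohort.clinical["time_months"].to_numpy()
        e = medium_cohort.clinical["event"].to_numpy(bool)
        with pytest.raises(FitError, match="threshold"):
            fit_selected_cox(X, t, e, selected=[])

    def test_linear_predictor_is_x_dot_beta(self, medium_cohort):
        X = medium_cohort.features
        t = medium_cohort.clinical["time_months"].to_numpy()
        e = medium_cohort.clinical["event"].to_numpy(bool)
        sel = ["buds.10", "cyto.15"]
        fit = fit_selected_cox(X, t, e, selected=sel)
        eta = linear_predictor(fit, X)
        np.testing.assert_allclose(
            eta.to_numpy(), np.asarray(X[sel]) @ fit.coefficients
        )


def make_clinical(n, rng):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "age": rng.integers(40, 85, n),
            "sex": rng.choice(["male", "female"], n),
            "pT": rng.integers(1, 5, n),
            "pN": rng.choice(["N0", "N+"], n),
            "M": rng.choice(["M0", "M+"], n, p=[0.95, 0.05]),
            "grade": rng.integers(1, 5, n),
            "lymphovascular": rng.choice(["absent", "present"], n),
            "vascular": rng.choice(["absent", "present"], n),
            "perineural": rng.choice(["absent", "present"], n),
            "margin": rng.choice(["R0", "R+"], n),
            "location": rng.choice(["PDAC", "DBDAC", "AMPAC", "DUOAC"], n),
            "histology": rng.choice(["PB", "MIX", "INT", "UNDIFF", "OTH"], n),
        }
    )


class TestClinicalDesign:
    def test_reference_levels_dropped(self):
        rng = np.random.default_rng(4)
        clin = make_clinical(50, rng)
        design, blocks = build_clinical_design(clin)
        assert "location_PDAC" not in design.columns  # reference level
        assert set(blocks["location"]) == {"location_DBDAC", "location_AMPAC", "location_DUOAC"}
        assert set(blocks["histology"]) == {
            "histology_MIX", "histology_INT", "histology_UNDIFF", "histology_OTH"}
        # dummies one-hot against reference
        row = clin.iloc[0]
        for lev in ("DBDAC", "AMPAC", "DUOAC"):
            assert design.iloc[0][f"location_{lev}"] == float(row["location"] == lev)

    def test_budding_grade_block_added(self):
        rng = np.random.default_rng(5)
        clin = make_clinical(20, rng)
        grades = pd.DataFrame(
            {"patient_id": clin["patient_id"], "grade": ["low", "high"] * 10}
        )
        design, blocks = build_clinical_design(clin, grades)
        assert blocks["budding_grade"] == ["budding_high"]
        assert design["budding_high"].tolist() == [0.0, 1.0] * 10


class TestStepwise:
    def small_design(self, n, rng, beta=(1.0, 0.0, 0.0)):
        design = pd.DataFrame(
            {f"c{j}": rng.normal(size=n) for j in range(3)},
            index=[f"P{i}" for i in range(n)],
        )
        blocks = {f"c{j}": [f"c{j}"] for j in range(3)}
        eta = design.to_numpy() @ np.array(beta)
        t = rng.exponential(10 / np.exp(eta)) + 0.01
        e = rng.random(n) < 0.8
        return design, blocks, t, e

    def test_final_aic_is_best_reachable_subset(self):
        rng = np.random.default_rng(6)
        design, blocks, t, e = self.small_design(80, rng, beta=(0.8, -0.5, 0.0))
        res = stepwise_cox(design, blocks, t, e)
        # exhaustive enumeration of all 8 subsets
        best = np.inf
        for r in range(4):
            for combo in itertools.combinations(blocks, r):
                cols = list(combo)
                if cols:
                    fit = cox_fit(design[cols].to_numpy(), t, e)
                    aic = -2 * fit.log_partial_likelihood + 2 * len(cols)
                else:
                    aic = -2 * cox_loglik(np.zeros(0), np.empty((len(t), 0)), t, e)
                best = min(best, aic)
        assert res.criterion_value == pytest.approx(best, abs=1e-6)

    def test_strong_covariate_retained(self):
        kept = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(3000 + seed)
            design, blocks, t, e = self.small_design(300, rng, beta=(1.0, 0.0, 0.0))
            res = stepwise_cox(design, blocks, t, e)
            kept += "c0" in res.retained_blocks
        assert kept >= int(0.95 * n_seeds)

    def test_null_retention_near_aic_false_inclusion_rate(self):
        # AIC admits a 1-df noise covariate with P(chi2_1 > 2) ~ 0.157
        retained = total = 0
        for seed in range(40):
            rng = np.random.default_rng(4000 + seed)
            design, blocks, t, e = self.small_design(150, rng, beta=(0, 0, 0))
            res = stepwise_cox(design, blocks, t, e)
            retained += len(res.retained_blocks)
            total += len(blocks)
        assert retained / total <= 0.157 + 0.05

    def test_force_in_kept(self):
        rng = np.random.default_rng(7)
        design, blocks, t, e = self.small_design(80, rng, beta=(0, 0, 0))
        res = stepwise_cox(design, blocks, t, e, force_in=("c2",))
        assert "c2" in res.retained_blocks

    def test_full_start_supported_and_finds_signal(self):
        rng = np.random.default_rng(8)
        design, blocks, t, e = self.small_design(150, rng, beta=(0.9, 0.6, 0.0))
        r_empty = stepwise_cox(design, blocks, t, e, start="empty")
        r_full = stepwise_cox(design, blocks, t, e, start="full")
        for r in (r_empty, r_full):
            assert {"c0", "c1"} <= set(r.retained_blocks)

    def test_pvalue_criterion_finds_strong_covariate(self):
        rng = np.random.default_rng(12)
        design, blocks, t, e = self.small_design(200, rng, beta=(1.0, 0.0, 0.0))
        res = stepwise_cox(design, blocks, t, e, criterion="pvalue")
        assert "c0" in res.retained_blocks
        # every retained block must be LRT-significant at entry level
        assert all(m.get("p", 0) < 0.05 for m in res.move_log
                   if m.get("move", ("", ""))[0] == "add" and "p" in m)

    def test_constant_block_skipped_with_log(self):
        rng = np.random.default_rng(9)
        design, blocks, t, e = self.small_design(80, rng, beta=(1.0, 0.0, 0.0))
        design["c3"] = 1.0  # constant: unfittable, e.g. a level absent in a subgroup
        blocks["c3"] = ["c3"]
        res = stepwise_cox(design, blocks, t, e)
        assert "c3" not in res.retained_blocks
        assert any(m.get("move") == ("add", "c3") and "skipped" in m for m in res.move_log)


class TestGradeSurvivalReport:
    def test_halved_times_in_high_group(self):
        rng = np.random.default_rng(10)
        n = 60
        t_low = rng.exponential(40, n // 2) + 1
        grades = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)],
             "grade": ["low"] * (n // 2) + ["high"] * (n // 2)}
        )
        time = np.r_[t_low, t_low / 2]
        event = np.ones(n, bool)
        rep = grade_survival_report(grades, time, event)
        assert rep.median_os["high"] < rep.median_os["low"]
        assert rep.p < 0.01
        assert rep.table.loc["low", "n"] == n // 2

    def test_identical_groups_p_one(self):
        t = np.r_[np.arange(1.0, 11.0), np.arange(1.0, 11.0)]
        e = np.ones(20, bool)
        grades = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(20)],
             "grade": ["low"] * 10 + ["high"] * 10}
        )
        rep = grade_survival_report(grades, t, e)
        assert rep.p == 1.0

    def test_missing_grade_group_rejected(self):
        grades = pd.DataFrame({"patient_id": ["P1", "P2"], "grade": ["low", "low"]})
        with pytest.raises(ValueError, match="high"):
            grade_survival_report(grades, np.array([1.0, 2.0]), np.array([True, True]))
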
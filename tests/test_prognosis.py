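import numpy as np
import pandas as pd
import pytest

from radiomit import synthetic
from radiomit.pipeline import simulate_preset
from radiomit.prognosis import (
    build_report,
    c_statistic,
    covariate_association,
    cv_c_statistic,
    fit_cox,
    group_by_batch,
    nmi,
)
from radiomit.types import CohortTable

from oracles import c_index_brute, cox_beta_grid


def survival_frame(rng, n=60, beta=1.0, censor=0.2):
    x = rng.standard_normal(n)
    t = rng.exponential(1.0, n) / np.exp(beta * x)
    event = (rng.random(n) > censor).astype(int)
    return pd.DataFrame({"x": x, "time": t, "event": event})


class TestGrouping:
    def _cohort(self, values, name="pixel_spacing"):
        df = pd.DataFrame({name: values}, index=[f"P{i}" for i in range(len(values))])
        return CohortTable(df, batch_variables=[name])

    def test_pixel_spacing_threshold(self):
        g = group_by_batch(self._cohort([0.7, 0.8]), "pixel_spacing", threshold=0.78)
        assert g.assignment["P0"] == "pixel_spacing<0.78"
        assert g.assignment["P1"] == "pixel_spacing>=0.78"

    def test_slice_thickness_threshold(self):
        g = group_by_batch(
            self._cohort([0.9, 3.0], name="slice_thickness"), "slice_thickness",
            threshold=1.5,
        )
        assert g.members("slice_thickness<1.5") == ["P0"]
        assert g.members("slice_thickness>=1.5") == ["P1"]

    def test_boundary_value_goes_to_ge_group(self):
        g = group_by_batch(self._cohort([0.5, 0.78]), "pixel_spacing", threshold=0.78)
        assert g.assignment["P1"] == "pixel_spacing>=0.78"

    def test_categorical_level_set(self):
        df = pd.DataFrame({"kernel": ["soft", "sharp", "soft"]}, index=list("abc"))
        cohort = CohortTable(df, batch_variables=["kernel"])
        g = group_by_batch(cohort, "kernel", level_set={"soft"})
        assert set(g.members(g.group_names[0])) == {"a", "c"}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            group_by_batch(self._cohort([0.9, 1.0]), "pixel_spacing", threshold=0.5)


class TestCox:
    def test_null_covariate_small_beta(self):
        rng = np.random.default_rng(0)
        n = 500
        df = pd.DataFrame({"x": rng.standard_normal(n)})
        time = pd.Series(rng.exponential(1.0, n))
        event = pd.Series(np.ones(n, dtype=int))
        res = fit_cox(df, time, event)
        assert abs(res.coefficients["x"]) < 0.2

    def test_matches_partial_likelihood_grid_search(self):
        # 8-patient, binary covariate, no ties
        x = np.array([1, 0, 1, 0, 1, 0, 0, 1], dtype=float)
        time = np.array([1.0, 2.0, 3.0, 4.5, 5.0, 6.5, 7.0, 9.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        res = fit_cox(pd.DataFrame({"x": x}), pd.Series(time), pd.Series(event))
        oracle = cox_beta_grid(x, time, event)
        assert res.coefficients["x"] == pytest.approx(oracle, abs=1e-4)

    def test_planted_log_hazard_recovered(self):
        rng = np.random.default_rng(1)
        df = survival_frame(rng, n=1000, beta=1.0, censor=0.1)
        res = fit_cox(df[["x"]], df["time"], df["event"])
        assert 0.8 <= res.coefficients["x"] <= 1.2

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="2 events"):
            fit_cox(df, pd.Series([1.0, 2.0, 3.0]), pd.Series([1, 0, 0]))

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            fit_cox(df, pd.Series([1.0, 2, 3, 4]), pd.Series([1, 1, 1, 1]))

    def test_monotone_likelihood_flagged_not_crash(self):
        # perfectly separating covariate -> monotone likelihood
        df = pd.DataFrame({"x": [0.0, 0, 0, 1, 1, 1]})
        time = pd.Series([1.0, 2, 3, 10, 11, 12])
        event = pd.Series([1, 1, 1, 1, 1, 1])
        res = fit_cox(df, time, event)
        assert res.converged in (True, False)  # flagged result, never an exception


class TestCStatistic:
    def test_perfect_ordering(self):
        assert c_statistic([2.0, 1.0], [1.0, 2.0], [1, 1]) == 1.0

    def test_all_risks_tied(self):
        assert c_statistic([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1]) == 0.5

    def test_six_patient_censored_fixture_matches_brute(self):
        risk = np.array([3.0, 1.0, 2.0, 2.5, 0.5, 1.5])
        time = np.array([1.0, 5.0, 3.0, 2.0, 6.0, 4.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        assert c_statistic(risk, time, event) == c_index_brute(risk, time, event)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        df = survival_frame(rng)
        c1 = c_statistic(df["x"], df["time"], df["event"])
        c2 = c_statistic(np.exp(df["x"]), df["time"], df["event"])
        assert c1 == c2

    def test_complement_under_risk_negation(self):
        rng = np.random.default_rng(3)
        df = survival_frame(rng)
        c = c_statistic(df["x"], df["time"], df["event"])
        c_neg = c_statistic(-df["x"], df["time"], df["event"])
        assert c + c_neg == pytest.approx(1.0)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            c_statistic([1.0, 2.0], [1.0, 2.0], [0, 1])


class TestCVC:
    def test_null_features_give_null_c(self):
        rng = np.random.default_rng(4)
        n = 300
        design = pd.DataFrame({"x": rng.standard_normal(n)})
        time = pd.Series(rng.exponential(1.0, n))
        event = pd.Series((rng.random(n) > 0.2).astype(int))
        mean_c, (lo, hi), _ = cv_c_statistic(design, time, event, n_iterations=10, seed=0)
        assert 0.45 <= mean_c <= 0.55
        assert lo <= mean_c <= hi

    def test_strong_signal_held_out_close_to_apparent(self):
        rng = np.random.default_rng(5)
        df = survival_frame(rng, n=500, beta=1.5, censor=0.1)
        fit = fit_cox(df[["x"]], df["time"], df["event"])
        apparent = c_statistic(fit.risk_scores, df["time"], df["event"])
        mean_c, _, _ = cv_c_statistic(df[["x"]], df["time"], df["event"],
                                      n_iterations=10, seed=1)
        assert abs(mean_c - apparent) < 0.05

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        df = survival_frame(rng, n=100)
        r1 = cv_c_statistic(df[["x"]], df["time"], df["event"], n_iterations=5, seed=9)
        r2 = cv_c_statistic(df[["x"]], df["time"], df["event"], n_iterations=5, seed=9)
        assert r1[0] == r2[0] and r1[1] == r2[1]


class TestNMI:
    def test_identical_labelings(self):
        assert nmi([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_permutation_invariance(self):
        assert nmi([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_independent_labelings_zero(self):
        assert nmi([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_single_cluster_convention(self):
        assert nmi([0, 0, 0, 0], [0, 1, 0, 1]) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 3, 50)
        b = rng.integers(0, 2, 50)
        assert nmi(a, b) == pytest.approx(nmi(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nmi([0, 1], [0, 1, 0])


class TestChiSquare:
    def test_diagonal_table(self):
        labels = [0] * 10 + [1] * 10
        covariate = ["a"] * 10 + ["b"] * 10
        stat, p = covariate_association(labels, covariate)
        assert stat == pytest.approx(20.0)
        assert p < 1e-4

    def test_perfect_independence_zero(self):
        labels = [0, 0, 1, 1] * 5
        covariate = ["a", "b", "a", "b"] * 5
        stat, _ = covariate_association(labels, covariate)
        assert stat == pytest.approx(0.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            covariate_association([0, 0, 0], ["a", "b", "a"])

    def test_uniform_p_under_independence(self):
        from scipy import stats as ss

        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(500):
            labels = rng.integers(0, 2, 40)
            cov = rng.integers(0, 2, 40)
            try:
                with np.errstate(all="ignore"):
                    _, p = covariate_association(labels, cov)
            except ValueError:
                continue
            pvals.append(p)
        # chi-square p-values are discrete at n=40; compare calibration coarsely
        assert ss.kstest(pvals, "uniform").pvalue > 1e-4 or (
            0.02 < np.mean(np.array(pvals) < 0.05) < 0.10
        )


class TestBuildReport:
    def _inputs(self, seed=0):
        features, cohort, _ = simulate_preset("feature-only-small", seed=seed)
        groupings = [
            group_by_batch(cohort, "spacing_group", level_set={"lo"}),
            group_by_batch(cohort, "kernel", level_set={"soft"}),
        ]
        return features, cohort, groupings

    def test_report_contains_all_groups_and_scenarios(self):
        features, cohort, groupings = self._inputs()
        report = build_report(
            {"original": features, "3": features}, cohort, groupings
        )
        assert set(report.c_scores.columns) == {"original", "3"}
        assert len(report.c_scores) == 4

    def test_group_sizes_partition_cohort(self):
        features, cohort, groupings = self._inputs()
        report = build_report({"original": features}, cohort, groupings)
        for g in groupings:
            total = sum(report.group_sizes[name] for name in g.group_names)
            assert total == len(cohort.patients)

    def test_c_scores_recomputable_from_saved_labels(self):
        features, cohort, groupings = self._inputs()
        report = build_report({"original": features}, cohort, groupings)
        for (group, scenario), labels in report.labels.items():
            patients = labels.index
            design = cohort.data.loc[patients, ["covar"]].copy()
            design["phenotype"] = labels.astype(float)
            fit = fit_cox(
                design,
                cohort.data.loc[patients, "time"],
                cohort.data.loc[patients, "event"],
            )
            c = c_statistic(
                fit.risk_scores.to_numpy(),
                cohort.data.loc[patients, "time"].to_numpy(),
                cohort.data.loc[patients, "event"].to_numpy(),
            )
            assert c == pytest.approx(report.c_scores.loc[group, scenario])
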
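"""Survival machinery against independent oracles: hand product-limit, manual
log-rank tables, brute-force Efron partial likelihood, exhaustive pair counts."""

import numpy as np
import pandas as pd
import pytest

from hehprofile.experiments import simulate_two_arm
from hehprofile.simulate import CohortConfig
from hehprofile.validate import (
    CoxResult,
    cochran_q,
    cox_fit,
    harrell_c,
    km_at,
    km_estimate,
    logrank,
    prepare_survival_dataset,
    run_validation,
    schoenfeld_check,
    subgroup_forest,
)


class TestKaplanMeier:
    def test_no_events_survival_one(self):
        curves = km_estimate([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert np.allclose(curves["all"].survival, 1.0)

    def test_hand_product_limit(self):
        # times {1,2,3}, all events: S = 1, 2/3, 1/3, 0
        c = km_estimate([1, 2, 3], [1, 1, 1])["all"]
        after_t2 = km_at(c, 2.5)[0]
        assert after_t2 == pytest.approx((2 / 3) * (1 / 2))

    def test_tied_events_simultaneous_decrement(self):
        c = km_estimate([1, 1, 2], [1, 1, 1])["all"]
        assert km_at(c, 1.0)[0] == pytest.approx(1 / 3)

    def test_greenwood_variance_hand_formula(self):
        times, ev = [1, 2, 3, 4], [1, 1, 0, 1]
        c = km_estimate(times, ev)["all"]
        # at t=2: S = (3/4)(2/3) = 1/2; Var = S^2 (1/(4·3) + 1/(3·2))
        i = list(c.times).index(2.0)
        assert c.survival[i] == pytest.approx(0.5)
        assert c.variance[i] == pytest.approx(0.25 * (1 / 12 + 1 / 6))

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(0)
        c = km_estimate(rng.exponential(5, 200), rng.integers(0, 2, 200))["all"]
        assert (c.ci_lower <= c.survival + 1e-12).all()
        assert (c.ci_upper >= c.survival - 1e-12).all()

    def test_survival_non_increasing(self):
        rng = np.random.default_rng(1)
        c = km_estimate(rng.exponential(5, 300), np.ones(300))["all"]
        assert (np.diff(c.survival) <= 1e-12).all()

    def test_step_read_at_event_time(self):
        c = km_estimate([5.0, 6.0], [1, 0])["all"]
        assert km_at(c, 5.0)[0] == pytest.approx(0.5)

    def test_all_zero_times_error(self):
        with pytest.raises(ValueError):
            km_estimate([0, 0], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0] * 2
        g = ["A"] * 5 + ["B"] * 5
        stat, p = logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_two_subject_hand_table(self):
        # one event in A at t=1 while both at risk: O−E = 0.5, V = 0.25
        stat, p = logrank([1, 2], [1, 0], ["A", "B"])
        assert stat == pytest.approx(1.0)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank([1, 2], [1, 1], ["A", "A"])


def efron_log_pl(beta: float, t, e, x) -> float:
    """Brute-force Efron partial log-likelihood for one covariate."""
    t, e, x = np.asarray(t, float), np.asarray(e, int), np.asarray(x, float)
    ll = 0.0
    for tt in np.unique(t[e == 1]):
        d_mask = (t == tt) & (e == 1)
        r_mask = t >= tt
        d = d_mask.sum()
        theta_r = np.exp(beta * x[r_mask]).sum()
        theta_d = np.exp(beta * x[d_mask]).sum()
        ll += beta * x[d_mask].sum()
        for l in range(d):
            ll -= np.log(theta_r - (l / d) * theta_d)
    return ll


class TestCoxFit:
    def test_identical_groups_hr_one(self):
        t = np.tile([1.0, 2, 3, 4, 5, 6], 2)
        e = np.tile([1, 1, 0, 1, 0, 1], 2)
        x = np.repeat([0, 1], 6)
        df = pd.DataFrame({"relapse_time": t, "relapse_ind": e, "x": x})
        res = cox_fit(df, ["x"], endpoint="relapse")
        assert res.hr("x") == pytest.approx(1.0, abs=1e-6)

    def test_matches_efron_grid_oracle_on_tied_toy(self):
        t = [1.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        e = [1, 1, 1, 1, 0, 1]
        x = [1.0, 0.0, 1.0, 1.0, 0.0, 0.0]
        df = pd.DataFrame({"relapse_time": t, "relapse_ind": e, "x": x})
        res = cox_fit(df, ["x"], endpoint="relapse")
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [efron_log_pl(b, t, e, x) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        assert abs(beta_star) < 2.9  # interior maximum
        assert res.summary.loc["x", "coef"] == pytest.approx(beta_star, abs=1e-4)

    def test_hr_ci_consistency(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.integers(0, 2, n)
        tt = rng.exponential(1 / (0.1 * np.exp(0.7 * x)))
        df = pd.DataFrame({"relapse_time": tt, "relapse_ind": np.ones(n, int), "x": x})
        res = cox_fit(df, ["x"], endpoint="relapse")
        row = res.summary.loc["x"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))
        assert row["hr_lower"] == pytest.approx(np.exp(row["coef"] - 1.96 * row["se"]), rel=1e-3)

    def test_no_events_errors(self):
        df = pd.DataFrame(
            {"relapse_time": [1.0, 2.0], "relapse_ind": [0, 0], "x": [0, 1]}
        )
        with pytest.raises(ValueError):
            cox_fit(df, ["x"], endpoint="relapse")

    def test_constant_covariate_errors(self):
        df = pd.DataFrame(
            {"relapse_time": [1.0, 2.0], "relapse_ind": [1, 1], "x": [1, 1]}
        )
        with pytest.raises(ValueError):
            cox_fit(df, ["x"], endpoint="relapse")


def concordance_oracle(times, events, risks) -> float:
    """Exhaustive comparable-pair count, ties in risk scored 1/2."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den


def _stub_result(coef: float, cov: str = "x") -> CoxResult:
    s = pd.DataFrame(
        {"coef": [coef], "se": [0.1], "hr": [np.exp(coef)],
         "hr_lower": [1.0], "hr_upper": [1.0], "p": [0.5]},
        index=[cov],
    )
    return CoxResult(summary=s, log_likelihood=0.0, n=1, n_events=1)


class TestHarrellC:
    def test_perfect_ordering(self):
        df = pd.DataFrame(
            {"relapse_time": [1.0, 2, 3, 4], "relapse_ind": [1, 1, 1, 1],
             "x": [4.0, 3.0, 2.0, 1.0]}
        )
        assert harrell_c(df, _stub_result(1.0), "relapse") == pytest.approx(1.0)

    def test_matches_exhaustive_pair_count(self):
        df = pd.DataFrame(
            {"relapse_time": [1.0, 2, 3, 4], "relapse_ind": [1, 1, 0, 1],
             "x": [2.0, 3.0, 1.0, 1.0]}
        )
        expected = concordance_oracle(
            df["relapse_time"].tolist(), df["relapse_ind"].tolist(), df["x"].tolist()
        )
        assert harrell_c(df, _stub_result(1.0), "relapse") == pytest.approx(expected)

    def test_null_model_near_half(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {"relapse_time": rng.exponential(5, 2000),
             "relapse_ind": np.ones(2000, int),
             "x": rng.normal(size=2000)}
        )
        res = cox_fit(df, ["x"], endpoint="relapse")
        assert harrell_c(df, res, "relapse") == pytest.approx(0.5, abs=0.05)


class TestSchoenfeld:
    def test_runs_under_proportional_hazards(self):
        cfg = CohortConfig(n=1)
        df = simulate_two_arm(cfg, 400, np.random.default_rng(4))
        res = cox_fit(df, ["_pr"], endpoint="relapse")
        out = schoenfeld_check(res, df, endpoint="relapse")
        assert set(out) == {"per_covariate", "global_statistic", "global_p"}
        assert 0.0 < out["per_covariate"]["_pr"]["p"] <= 1.0

    def test_detects_time_varying_effect(self):
        """Hazard doubling after year 2 in one arm: rejection >50% at n=2000."""
        lam0 = 0.15
        rejections = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng([99, rep])
            n = 2000
            x = np.repeat([0, 1], n // 2)
            e = rng.exponential(size=n)
            t0 = e / lam0
            t = np.where(x == 0, t0, np.where(t0 < 2, t0, 2 + (t0 - 2) / 2.0))
            c = rng.uniform(6, 10, n)
            df = pd.DataFrame(
                {"relapse_time": np.minimum(t, c),
                 "relapse_ind": (t <= c).astype(int), "x": x}
            )
            res = cox_fit(df, ["x"], endpoint="relapse")
            out = schoenfeld_check(res, df, endpoint="relapse")
            rejections += out["per_covariate"]["x"]["p"] < 0.05
        assert rejections / reps > 0.5

    def test_too_few_events_errors(self):
        df = pd.DataFrame(
            {"relapse_time": [1.0, 2, 3], "relapse_ind": [1, 0, 0], "x": [0, 1, 0]}
        )
        res_df = pd.DataFrame(
            {"relapse_time": [1.0, 2, 3, 4], "relapse_ind": [1, 1, 0, 1],
             "x": [0, 1, 0, 1]}
        )
        res = cox_fit(res_df, ["x"], endpoint="relapse")
        with pytest.raises(ValueError):
            schoenfeld_check(res, df, endpoint="relapse")


class TestHeterogeneity:
    def test_identical_subgroups_q_zero(self):
        q, dof, p = cochran_q([0.5, 0.5], [0.2, 0.2])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert dof == 1

    def test_hand_computed_q(self):
        b, se = [0.0, 1.0], [0.5, 0.5]
        # weights 4, 4 → pooled 0.5 → Q = 4·0.25 + 4·0.25 = 2
        q, dof, p = cochran_q(b, se)
        assert q == pytest.approx(2.0)
        from scipy import stats

        assert p == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_forest_identical_levels_q_zero(self):
        cfg = CohortConfig(n=1)
        half = simulate_two_arm(cfg, 300, np.random.default_rng(7))
        half["merged_group"] = np.where(half["_pr"] == 1, "PR", "GR")
        half["sex"] = "Female"
        other = half.copy()
        other["sex"] = "Male"
        df = pd.concat([half, other], ignore_index=True)
        forest = subgroup_forest(df, variables=["sex"], endpoint="relapse")
        assert forest.q_statistic == pytest.approx(0.0, abs=1e-8)

    def test_eventless_arm_dropped_with_warning(self):
        cfg = CohortConfig(n=1)
        df = simulate_two_arm(cfg, 200, np.random.default_rng(9))
        df["merged_group"] = np.where(df["_pr"] == 1, "PR", "GR")
        df["sex"] = np.where(np.arange(len(df)) % 2 == 0, "Female", "Male")
        # kill all PR events among males
        kill = (df["sex"] == "Male") & (df["_pr"] == 1)
        df.loc[kill, "relapse_ind"] = 0
        with pytest.warns(UserWarning, match="dropped"):
            forest = subgroup_forest(df, variables=["sex"], endpoint="relapse")
        assert forest.dropped == ("sex=Male",)


class TestAdjustment:
    def test_mrd_independent_adjustment_stable(self):
        """With MRD independent of group, adjusting moves the HR by <5%."""
        cfg = CohortConfig(n=1)
        df = simulate_two_arm(cfg, 5000, np.random.default_rng(10))
        unadj = cox_fit(df, ["_pr"], endpoint="relapse").hr("_pr")
        adj = cox_fit(df, ["_pr", "log_mrd"], endpoint="relapse").hr("_pr")
        assert abs(adj - unadj) / unadj < 0.05


class TestRunValidation:
    @pytest.fixture(scope="class")
    def classified(self):
        from hehprofile.classifier import classify_cohort
        from hehprofile.simulate import generate_cohort

        return classify_cohort(generate_cohort(CohortConfig(n=800, seed=17)))

    def test_report_structure(self, classified):
        rep = run_validation(classified)
        assert set(rep["endpoints"]) == {"relapse", "event", "death"}
        block = rep["endpoints"]["relapse"]
        assert {"events", "km_5yr", "logrank", "unadjusted", "mrd_adjusted"} <= set(block)
        assert block["unadjusted"]["hr"] > 1.0
        assert rep["definite_vs_provisional"]["n"]["provisional"] > 0

    def test_single_group_cohort_warns_without_hr(self):
        cfg = CohortConfig(
            n=200, seed=2,
            group_mix={"GR": 1.0, "PR": 0.0, "not_heh": 0.0,
                       "ph_positive": 0.0, "masked_doubled": 0.0},
        )
        from hehprofile.classifier import classify_cohort
        from hehprofile.simulate import generate_cohort

        rep = run_validation(classify_cohort(generate_cohort(cfg)))
        assert any("single risk group" in w for w in rep["warnings"])
        assert "unadjusted" not in rep["endpoints"]["relapse"]

    def test_report_files_deterministic(self, classified, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        run_validation(classified, out_dir=d1)
        run_validation(classified, out_dir=d2)
        for name in ("table1.csv", "diagnostics.json", "km_relapse.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_prepare_dataset_bands(self, classified):
        data = prepare_survival_dataset(classified)
        assert set(data["nci_risk"].unique()) <= {"standard", "high"}
        assert (data.loc[data["nci_risk"] == "standard", "age_years"] < 10).all()
        assert (data.loc[data["nci_risk"] == "standard", "wcc"] < 50).all()
        assert ((data["mrd_ge_0.01pct"] == 1) == (data["mrd"] >= 1e-4)).all()
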
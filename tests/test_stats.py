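"""The cohort inference chain: tests per operation plus calibration checks."""
import itertools
import math
from math import lgamma

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from octamorph.stats import (backward_aic_select, correlation_prune,
                             delong_ci, fisher_exact, fit_lmm,
                             fit_logistic_mixed, fit_multinomial_mixed,
                             impute_rf, loocv_auc, stratify_thresholds,
                             univariate_screen)
from octamorph.synth import (CohortSpec, generate_cohort, make_lmm_table,
                             make_mixed_logistic_table)


# --------------------------------------------------------------------------
# Fisher exact
# --------------------------------------------------------------------------

def enumerate_rxc_pvalue(table):
    """Independent oracle: itertools enumeration of all fixed-margin tables."""
    obs = np.asarray(table, int)
    rows, cols = obs.sum(1), obs.sum(0)
    n = obs.sum()

    def logp(t):
        return (sum(lgamma(v + 1) for v in rows)
                + sum(lgamma(v + 1) for v in cols) - lgamma(n + 1)
                - sum(lgamma(v + 1) for v in np.ravel(t)))

    lp_obs = logp(obs)
    r, c = obs.shape
    total = 0.0
    ranges = [range(min(rows[i], cols[j]) + 1)
              for i in range(r - 1) for j in range(c - 1)]
    for combo in itertools.product(*ranges):
        t = np.zeros((r, c), int)
        t[:r - 1, :c - 1] = np.reshape(combo, (r - 1, c - 1))
        t[:r - 1, c - 1] = rows[:r - 1] - t[:r - 1, :c - 1].sum(1)
        t[r - 1, :] = cols - t[:r - 1, :].sum(0)
        if (t < 0).any():
            continue
        lp = logp(t)
        if lp <= lp_obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


class TestFisherExact:
    def test_symmetric_two_by_two(self):
        assert fisher_exact([[1, 0], [0, 1]]) == 1.0

    def test_degenerate_margin_returns_one(self):
        assert fisher_exact([[0, 0], [3, 5]]) == 1.0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_scipy_on_random_2x2(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 16, size=(2, 2))
        while t.sum() == 0:
            t = rng.integers(0, 16, size=(2, 2))
        assert fisher_exact(t) == pytest.approx(
            sps.fisher_exact(t)[1], abs=1e-10)

    @pytest.mark.parametrize("table", [
        [[0, 12, 10], [0, 5, 23]],
        [[3, 4, 15], [12, 7, 9]],
        [[6, 6, 4, 6], [3, 11, 5, 7]],
    ])
    def test_rxc_matches_enumeration_oracle(self, table):
        assert fisher_exact(table) == pytest.approx(
            enumerate_rxc_pvalue(table), abs=1e-9)


# --------------------------------------------------------------------------
# Univariate screen
# --------------------------------------------------------------------------

class TestUnivariateScreen:
    def _table(self, rng, n=60, null=True):
        y = np.repeat(["Y", "N"], n // 2)
        x = rng.normal(size=n)
        cat = rng.integers(0, 2, size=n)
        return pd.DataFrame({"Patient-ID": [f"P{i}" for i in range(n)],
                             "PNP_present": y, "num": x, "bin": cat})

    def test_group_label_copy_is_detected(self):
        rng = np.random.default_rng(0)
        t = self._table(rng)
        t["copy"] = (t["PNP_present"] == "Y").astype(int) * 5.0 \
            + rng.normal(scale=1e-3, size=len(t))
        res = {r.variable: r for r in univariate_screen(t)}
        assert res["copy"].p_value < 1e-6
        assert res["copy"].retest_requested

    def test_forced_variable_requested_even_if_not_significant(self):
        rng = np.random.default_rng(1)
        t = self._table(rng)
        t["faz_area_mm2"] = rng.normal(size=len(t))
        res = {r.variable: r for r in univariate_screen(t)}
        assert res["faz_area_mm2"].retest_requested
        assert not res["faz_area_mm2"].significant_at_10pct

    def test_constant_variable_skipped(self):
        t = self._table(np.random.default_rng(2))
        t["const"] = 1.234
        res = {r.variable: r for r in univariate_screen(t)}
        assert res["const"].test == "skipped"

    def test_type_one_rate_near_alpha(self):
        """Scaled null calibration; the full-size check runs in acceptance."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 200
        for _ in range(reps):
            t = self._table(rng)
            res = {r.variable: r for r in univariate_screen(t)}
            hits += res["num"].significant_at_10pct
        assert 0.05 < hits / reps < 0.16


# --------------------------------------------------------------------------
# Mixed models
# --------------------------------------------------------------------------

class TestLinearMixed:
    def test_one_eye_per_patient_equals_mean_difference(self):
        t = make_lmm_table(40, seed=0, eyes_per_patient=1, fixed_effect=1.5,
                           random_sd=0.0, resid_sd=1.0)
        fit = fit_lmm(t, "y")
        diff = t.loc[t.PNP_present == "Y", "y"].mean() \
            - t.loc[t.PNP_present == "N", "y"].mean()
        assert fit.fixed_effects[1]["estimate"] == pytest.approx(diff,
                                                                 abs=1e-6)

    def test_zero_between_patient_variance_reduces_to_ols(self):
        t = make_lmm_table(80, seed=1, fixed_effect=1.0, random_sd=0.0)
        fit = fit_lmm(t, "y")
        import statsmodels.api as sm

        g = (t.PNP_present == "Y").astype(float)
        ols = sm.OLS(t.y, sm.add_constant(g)).fit()
        assert fit.fixed_effects[1]["estimate"] == pytest.approx(
            ols.params.iloc[1], abs=1e-3)

    def test_assumption_checks_reported(self):
        t = make_lmm_table(40, seed=2)
        fit = fit_lmm(t, "y")
        assert 0 <= fit.shapiro_p <= 1
        assert 0 <= fit.levene_p <= 1

    def test_transformations(self):
        t = make_lmm_table(40, seed=3)
        t["y"] = np.abs(t["y"]) + 1
        sqrt_fit = fit_lmm(t, "y", transformation="sqrt")
        pow_fit = fit_lmm(t, "y", transformation="power_1.05")
        assert sqrt_fit.transformation == "sqrt"
        assert np.isfinite(pow_fit.aic)


class TestLogisticMixed:
    def test_constrained_sigma_reduces_to_plain_logistic(self):
        import statsmodels.api as sm

        t = make_mixed_logistic_table(120, {"x1": 1.0, "x2": -0.5}, seed=1,
                                      random_sd=0.0)
        fit = fit_logistic_mixed(t, fixed=["x1", "x2"], sigma_max=1e-6)
        X = np.column_stack([np.ones(len(t)), t.x1, t.x2])
        plain = sm.Logit(t.PNP_present.astype(float), X).fit(disp=0)
        est = np.array([f["estimate"] for f in fit.fixed_effects])
        assert np.abs(est - plain.params.values).max() < 1e-3
        assert fit.singular

    def test_quadrature_node_count_converged(self):
        """At fixed parameters, 7 vs 25 adaptive nodes agree to < 1e-4."""
        from octamorph.stats import _design, _mixed_logit_nll

        t = make_mixed_logistic_table(60, {"x1": 1.0}, seed=2, random_sd=1.0)
        X, y, gi, ng, _ = _design(t, "PNP_present", ["x1"], "Patient-ID")
        params = np.array([0.2, 0.9, math.log(1.1)])
        ll7 = -_mixed_logit_nll(params, X, y, gi, ng, 7)
        ll25 = -_mixed_logit_nll(params, X, y, gi, ng, 25)
        assert abs(ll7 - ll25) < 1e-4

    def test_loglik_monotone_in_nodes(self):
        from octamorph.stats import _design, _mixed_logit_nll

        t = make_mixed_logistic_table(40, {"x1": 1.0}, seed=3, random_sd=1.2)
        X, y, gi, ng, _ = _design(t, "PNP_present", ["x1"], "Patient-ID")
        params = np.array([0.1, 0.8, math.log(1.0)])
        lls = [-_mixed_logit_nll(params, X, y, gi, ng, k)
               for k in (3, 5, 9, 15, 25)]
        diffs = np.abs(np.diff(lls))
        assert diffs[-1] < diffs[0] + 1e-12  # successive refinements shrink

    def test_complete_separation_flagged(self):
        n = 40
        t = pd.DataFrame({
            "Patient-ID": [f"P{i // 2}" for i in range(n)],
            "PNP_present": np.repeat([1, 0], n // 2),
            "x1": np.repeat([5.0, -5.0], n // 2),
        })
        fit = fit_logistic_mixed(t, fixed=["x1"])
        assert any("separation" in f for f in fit.flags)


class TestMultinomialMixed:
    def _table(self, rng, n_pat=80, probs=(0.3, 0.4, 0.3), dependent=False):
        pid = np.repeat([f"P{i}" for i in range(n_pat)], 2)
        group = np.repeat(rng.choice(["N", "Y"], n_pat), 2)
        if dependent:
            cats = np.where(group == "Y",
                            rng.choice(["a", "b", "c"], len(pid),
                                       p=[0.1, 0.2, 0.7]),
                            rng.choice(["a", "b", "c"], len(pid),
                                       p=[0.5, 0.3, 0.2]))
        else:
            cats = rng.choice(["a", "b", "c"], len(pid), p=probs)
        return pd.DataFrame({"Patient-ID": pid, "PNP_present": group,
                             "cat": cats})

    def test_dependence_detected(self):
        t = self._table(np.random.default_rng(0), dependent=True)
        fit = fit_multinomial_mixed(t, "cat")
        assert fit.p_value < 0.01

    def test_two_category_collapse_matches_logistic(self):
        rng = np.random.default_rng(1)
        t = self._table(rng)
        t = t[t.cat != "c"].reset_index(drop=True)
        multi = fit_multinomial_mixed(t, "cat")
        t2 = t.copy()
        t2["is_b"] = (t2.cat == "b").astype(int)
        logit = fit_logistic_mixed(t2, response="is_b",
                                   fixed=["PNP_present"])
        assert multi.loglik == pytest.approx(logit.loglik, abs=1e-3)

    def test_empty_category_dropped_with_flag(self):
        t = self._table(np.random.default_rng(2))
        t["cat"] = pd.Categorical(t["cat"], categories=["a", "b", "c", "d"])
        fit = fit_multinomial_mixed(t, "cat")
        assert any("dropped" in f for f in fit.flags)

    def test_null_lrt_roughly_calibrated(self):
        rng = np.random.default_rng(4)
        hits = 0
        reps = 40
        for _ in range(reps):
            t = self._table(rng, n_pat=60)
            fit = fit_multinomial_mixed(t, "cat")
            hits += fit.p_value < 0.05
        assert hits / reps <= 0.15


# --------------------------------------------------------------------------
# Pruning, selection, LOOCV
# --------------------------------------------------------------------------

class TestCorrelationPrune:
    def test_identical_columns_one_removed(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        t = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=100)})
        kept, report = correlation_prune(t, ["a", "b", "c"],
                                         manual_exclusions=())
        assert len(kept) == 2 and "c" in kept
        assert report[0]["r"] == pytest.approx(1.0)

    def test_constructed_pair_pruned_once(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        b = 0.95 * a + math.sqrt(1 - 0.95 ** 2) * rng.normal(size=200)
        t = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=200)})
        kept, _ = correlation_prune(t, ["a", "b", "c"], manual_exclusions=())
        assert len(kept) == 2 and "c" in kept

    def test_manual_exclusion_always_applied(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame({"prp": rng.integers(0, 2, 50),
                          "x": rng.normal(size=50)})
        kept, report = correlation_prune(t, ["prp", "x"])
        assert "prp" not in kept
        assert any(r["reason"] == "manual exclusion" for r in report)


class TestSelection:
    def test_no_candidates_gives_intercept_only(self, default_cohort):
        t = impute_rf(default_cohort, seed=0)
        sel = backward_aic_select(t, [])
        assert sel.final_terms == []
        assert sel.elimination_trace == []

    def test_aic_trace_non_increasing(self):
        t = make_mixed_logistic_table(80, {"x1": 2.0}, seed=5, random_sd=0.8,
                                      n_noise=3)
        sel = backward_aic_select(
            t, ["x1", "noise_1", "noise_2", "noise_3"],
            significance_filter=None)
        for step in sel.elimination_trace:
            assert step["aic_after"] <= step["aic_before"]

    def test_strong_predictor_survives(self):
        t = make_mixed_logistic_table(100, {"x1": 3.0}, seed=6,
                                      random_sd=1.0, n_noise=2)
        sel = backward_aic_select(t, ["x1", "noise_1", "noise_2"])
        assert "x1" in sel.final_terms


class TestLOOCV:
    def test_perfect_scores_give_auc_one(self):
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        auc, (lo, hi) = delong_ci(labels.astype(float), labels)
        assert auc == 1.0 and hi == 1.0

    def test_auc_equals_concordance_oracle(self):
        t = make_mixed_logistic_table(15, {"x1": 2.0}, seed=7, random_sd=0.5)
        auc, _, scores = loocv_auc(t, ["x1"])
        y = t.PNP_present.to_numpy(bool)
        pos, neg = scores[y], scores[~y]
        conc = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                        for a in pos for b in neg])
        assert auc == pytest.approx(conc, abs=1e-12)

    def test_null_scores_near_half(self):
        aucs = []
        for s in range(10):
            t = make_mixed_logistic_table(25, {}, seed=40 + s,
                                          random_sd=0.5, n_noise=1)
            auc, _, _ = loocv_auc(t, ["noise_1"])
            aucs.append(auc)
        assert 0.35 < np.mean(aucs) < 0.65

    def test_patient_level_unit(self):
        t = make_mixed_logistic_table(20, {"x1": 2.0}, seed=8, random_sd=0.5)
        auc, _, scores = loocv_auc(t, ["x1"], unit="patient")
        assert np.isfinite(auc) and not np.isnan(scores).all()


# --------------------------------------------------------------------------
# Imputation and stratification
# --------------------------------------------------------------------------

class TestImputation:
    def test_complete_table_unchanged(self):
        t = make_mixed_logistic_table(20, {"x1": 1.0}, seed=0)
        assert impute_rf(t, seed=1).equals(t)

    def test_deterministic(self, default_cohort):
        a = impute_rf(default_cohort, seed=5)
        b = impute_rf(default_cohort, seed=5)
        assert a.equals(b)
        assert not a.isna().any().any()

    def test_beats_mean_imputation_on_correlated_data(self):
        wins = 0
        seeds = 12
        for s in range(seeds):
            rng = np.random.default_rng(s)
            n = 200
            rho = 0.8
            cov = rho + (1 - rho) * np.eye(4)
            X = rng.multivariate_normal(np.zeros(4), cov, size=n)
            df = pd.DataFrame(X, columns=list("abcd"))
            df["Patient-ID"] = [f"P{i}" for i in range(n)]
            miss = rng.random((n, 4)) < 0.10
            truth = df[list("abcd")].to_numpy().copy()
            dfm = df.copy()
            for j, c in enumerate("abcd"):
                dfm.loc[miss[:, j], c] = np.nan
            imp = impute_rf(dfm, seed=s)
            rf_rmse = np.sqrt(np.nanmean(
                (imp[list("abcd")].to_numpy() - truth)[miss] ** 2))
            mean_fill = dfm[list("abcd")].fillna(dfm[list("abcd")].mean())
            mean_rmse = np.sqrt(np.nanmean(
                (mean_fill.to_numpy() - truth)[miss] ** 2))
            wins += rf_rmse < mean_rmse
        assert wins >= seeds - 1

    def test_all_missing_column_rejected(self):
        t = make_mixed_logistic_table(10, {"x1": 1.0}, seed=0)
        t["x1"] = np.nan
        with pytest.raises(ValueError):
            impute_rf(t, seed=0)


class TestStratification:
    def test_single_cell(self):
        t = pd.DataFrame({"PNP_present": ["N"] * 6,
                          "perfusion_density": [0.5] * 6,
                          "faz_area_mm2": [0.2] * 6})
        out = stratify_thresholds(t)
        assert out["pd_table"].loc["normal", "no PNP"] == 6
        assert out["faz_table"].loc["preserved", "no PNP"] == 6

    def test_hand_counted_fixture(self):
        t = pd.DataFrame({
            "PNP_present": ["Y", "Y", "N", "N", "Y", "N"],
            "perfusion_density": [0.50, 0.40, 0.46, 0.30, 0.45, 0.60],
            "faz_area_mm2": [0.25, 0.35, 0.29, 0.31, 0.30, 0.10],
        })
        out = stratify_thresholds(t)
        pd_tab = out["pd_table"]
        assert pd_tab.loc["normal", "PNP"] == 1      # 0.50 only
        assert pd_tab.loc["reduced", "PNP"] == 2     # 0.40 and boundary 0.45
        assert pd_tab.loc["normal", "no PNP"] == 2   # 0.46, 0.60
        faz_tab = out["faz_table"]
        assert faz_tab.loc["preserved", "PNP"] == 1  # 0.25
        assert faz_tab.loc["enlarged", "PNP"] == 2   # 0.35 and boundary 0.30

    def test_missing_rows_excluded_and_counted(self):
        t = pd.DataFrame({"PNP_present": ["Y", "N", "N"],
                          "perfusion_density": [0.5, np.nan, 0.4],
                          "faz_area_mm2": [0.2, 0.4, np.nan]})
        out = stratify_thresholds(t)
        assert out["excluded"] == {"pd": 1, "faz": 1}
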
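"""Descriptive tables and the modified Poisson fit against independent oracles."""

import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from asthmactl.analysis import (
    ModelError,
    build_design,
    fit_modified_poisson,
    lookup,
    round_half_up,
    run_analysis,
    tabulate,
)
from asthmactl.data_model import write_dataset
from asthmactl.synthetic import SimConfig, generate, sample_cohort


def planted_cohort(n=2000, seed=0, **cfg_kwargs):
    cfg = SimConfig(n_patients=n, seed=seed, exclusion_noise={}, **cfg_kwargs)
    return sample_cohort(cfg).rename(
        columns={"planted_step": "gina_step", "planted_control_status": "control_status"}
    )


class TestTabulate:
    def test_single_patient_is_100_percent(self):
        cohort = pd.DataFrame(
            {
                "gina_step": ["2"],
                "control_status": ["well_controlled"],
                "sex": ["female"],
                "race": ["white"],
                "ethnicity": ["non_hispanic"],
                "smoking": ["non_smoker"],
                "bmi_category": ["normal"],
                "visit_type": ["primary_care"],
            }
        )
        tables = tabulate(cohort)
        n, pct = lookup(tables["by_step"], "control_status", "well_controlled", "step_2")
        assert (n, pct) == (1, 100.0)
        n, pct = lookup(tables["by_control"], "gina_step", "step_2", "well_controlled")
        assert (n, pct) == (1, 100.0)

    def test_empty_cohort_has_blank_percentages(self):
        cohort = planted_cohort(n=0)
        tables = tabulate(cohort)
        assert tables["by_step"]["n"].sum() == 0 if len(tables["by_step"]) else True

    def test_counts_sum_to_column_totals(self):
        cohort = planted_cohort(n=500, seed=3)
        t = tabulate(cohort)["by_step"]
        overall = t[(t.characteristic == "race") & (t.column == "overall")]
        assert overall["n"].sum() == len(cohort)

    def test_rounding_is_half_up(self):
        assert round_half_up(29.25, 1) == 29.3
        assert round_half_up(34.049, 1) == 34.0
        assert round_half_up(0.05, 1) == 0.1


class TestFitOracles:
    def test_intercept_only_recovers_the_mean_exactly(self):
        y = np.r_[np.ones(37), np.zeros(63)]
        X = pd.DataFrame({"intercept": np.ones(100)})
        fit = fit_modified_poisson(y, X)
        assert abs(fit["intercept"]["pr"] - 0.37) < 1e-12

    def test_two_group_closed_form(self):
        """Saturated two-group model: exp(b1) = p2/p1 exactly and the HC0
        robust SE matches sqrt((1-p2)/(n2 p2) + (1-p1)/(n1 p1))."""
        n1, k1, n2, k2 = 400, 120, 600, 270
        y = np.r_[np.repeat([1.0, 0.0], [k1, n1 - k1]), np.repeat([1.0, 0.0], [k2, n2 - k2])]
        X = pd.DataFrame({"intercept": np.ones(n1 + n2), "g": np.r_[np.zeros(n1), np.ones(n2)]})
        fit = fit_modified_poisson(y, X)
        p1, p2 = k1 / n1, k2 / n2
        assert abs(fit["g"]["pr"] - p2 / p1) < 1e-10
        se_cf = np.sqrt((1 - p2) / (n2 * p2) + (1 - p1) / (n1 * p1))
        assert abs(fit["g"]["se_robust"] - se_cf) < 1e-10

    def test_two_group_mle_against_brute_force_likelihood_grid(self):
        """The closed form is itself checked by scanning the Poisson
        log-likelihood over a fine grid around the fitted optimum."""
        n1, k1, n2, k2 = 50, 15, 80, 40
        y = np.r_[np.repeat([1.0, 0.0], [k1, n1 - k1]), np.repeat([1.0, 0.0], [k2, n2 - k2])]
        X = pd.DataFrame({"intercept": np.ones(n1 + n2), "g": np.r_[np.zeros(n1), np.ones(n2)]})
        fit = fit_modified_poisson(y, X)

        def loglik(b0, b1):
            mu = np.exp(b0 + b1 * X["g"].to_numpy())
            return float(np.sum(y * np.log(mu) - mu))

        best = loglik(*fit.beta)
        for db0 in (-0.01, 0.01):
            for db1 in (-0.01, 0.01):
                assert loglik(fit.beta[0] + db0, fit.beta[1] + db1) < best

    def test_crude_model_equals_proportion_ratios(self):
        cohort = planted_cohort(n=3000, seed=5)
        y, X = build_design(cohort, covariates=())
        fit = fit_modified_poisson(y, X)
        p_ref = y[(cohort.gina_step == "1").to_numpy()].mean()
        for s in ("2", "3", "4", "5", "undefined"):
            p_s = y[(cohort.gina_step == s).to_numpy()].mean()
            assert abs(fit[f"step_{s}"]["pr"] - p_s / p_ref) < 1e-10

    def test_matches_reference_glm_implementation(self):
        import statsmodels.api as sm

        cohort = planted_cohort(n=2500, seed=7)
        y, X = build_design(cohort)
        fit = fit_modified_poisson(y, X)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC0")
        assert np.abs(fit.beta - ref.params.to_numpy()).max() < 1e-6
        assert np.abs(fit.se_robust - ref.bse.to_numpy()).max() < 1e-6

    def test_ci_brackets_pr_and_cov_is_psd(self):
        cohort = planted_cohort(n=1500, seed=9)
        y, X = build_design(cohort)
        fit = fit_modified_poisson(y, X)
        assert np.all(fit.ci_low <= fit.pr) and np.all(fit.pr <= fit.ci_high)
        eigvals = np.linalg.eigvalsh(fit.robust_cov)
        assert eigvals.min() > -1e-12

    def test_sign_consistency_of_pr_and_beta(self):
        cohort = planted_cohort(n=3000, seed=11)
        y, X = build_design(cohort)
        fit = fit_modified_poisson(y, X)
        assert np.all((fit.pr > 1) == (fit.beta > 0))


class TestFitErrors:
    def test_rank_deficiency_names_collinear_columns(self):
        n = 50
        rng = np.random.default_rng(0)
        x = rng.random(n)
        X = pd.DataFrame({"intercept": np.ones(n), "a": x, "b": 2 * x})
        y = (rng.random(n) < 0.4).astype(float)
        with pytest.raises(ModelError, match="collinear") as err:
            fit_modified_poisson(y, X)
        assert "a" in str(err.value) and "b" in str(err.value)

    def test_constant_outcome_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(20), "x": np.arange(20.0)})
        with pytest.raises(ModelError, match="constant"):
            fit_modified_poisson(np.zeros(20), X)

    def test_more_parameters_than_rows_rejected(self):
        X = pd.DataFrame(np.eye(3), columns=["a", "b", "c"])
        with pytest.raises(ModelError, match="observations"):
            fit_modified_poisson(np.array([0.0, 1.0, 0.0]), X)


class TestRunAnalysis:
    def test_end_to_end_outputs_and_determinism(self, tmp_path):
        ds, _ = generate(SimConfig(n_patients=700, seed=21))
        data_dir = tmp_path / "data"
        write_dataset(ds, data_dir)
        out1, out2 = tmp_path / "out1", tmp_path / "out2"
        r1 = run_analysis(data_dir, out1)
        r2 = run_analysis(data_dir, out2)
        for name in ("cohort.csv", "attrition.csv", "table1.csv", "table2.csv",
                     "prevalence_ratios.csv", "run_log.json"):
            assert (out1 / name).exists()
            assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name
        assert r1["model_fitted"] and r1["fit"].converged

    def test_dataset_without_acts_skips_model_with_warning(self, tmp_path):
        ds, _ = generate(SimConfig(n_patients=40, seed=2))
        ds.act_records = []
        data_dir = tmp_path / "data"
        write_dataset(ds, data_dir)
        with pytest.warns(UserWarning, match="skipped"):
            report = run_analysis(data_dir, tmp_path / "out")
        assert report["n_cohort"] == 0 and not report["model_fitted"]
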
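"""Covariate screening, collinearity filtering, stepwise/COSSAC selection."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from salbupop import cohort as cm
from salbupop import covsearch, model, saem
from salbupop.pbpk import DoseRegimen


class TestLrtThreshold:
    def test_printed_quantiles(self):
        assert covsearch.lrt_threshold(0.05, 1) == 3.84
        assert covsearch.lrt_threshold(0.001, 1) == 10.83

    def test_limit_to_zero(self):
        assert covsearch.lrt_threshold(0.9999, 1) < 0.01

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            covsearch.lrt_threshold(1.5)


class TestVifFilter:
    def test_orthogonal_covariates_have_unit_vif(self):
        rng = np.random.default_rng(0)
        n = 200
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a -= a.mean()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)
        df = pd.DataFrame({"ID": np.arange(n), "A": a, "B": b})
        retained, excluded, table = covsearch.vif_filter(df)
        assert excluded == []
        assert table.iloc[0]["A"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_covariate_excluded(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"ID": np.arange(50), "X": x, "XCOPY": x, "Z": rng.standard_normal(50)})
        retained, excluded, _ = covsearch.vif_filter(
            df, p_values={"X": 0.001, "XCOPY": 0.5, "Z": 0.9}
        )
        assert "XCOPY" in excluded
        assert "X" in retained

    def test_anthropometrics_are_collinear_in_cohort(self, default_cohort):
        # BSA is a near-deterministic function of weight and height
        tab = cm.cohort_table(default_cohort)
        df = pd.DataFrame({
            "ID": tab["id"], "WT": tab["weight"], "BSA": tab["bsa"],
            "AGE": tab["age"], "HT": tab["height"],
        })
        _, _, table = covsearch.vif_filter(df, threshold=1e9)  # report only
        assert table.iloc[0][["WT", "BSA"]].max() > 15.0
        retained, excluded, _ = covsearch.vif_filter(
            df, p_values={"WT": 0.001, "BSA": 0.01, "AGE": 0.2, "HT": 0.3}
        )
        assert excluded and "WT" in retained


class TestScreening:
    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(42)
        n, reps = 40, 400
        cont_flags = 0
        cat_flags = 0
        for _ in range(reps):
            eta = pd.DataFrame({"ID": np.arange(n), "eta_Cl": rng.standard_normal(n)})
            cov = pd.DataFrame({
                "ID": np.arange(n),
                "WT": rng.normal(60, 15, n),
                "RACE": rng.integers(0, 3, n),
            })
            out = covsearch.screen_covariates(eta, cov)
            flags = out.groupby("covariate")["flagged"].first()
            cont_flags += bool(flags.get("WT", False))
            cat_flags += bool(flags.get("RACE", False))
        # min of Pearson/Spearman p inflates mildly above alpha
        assert 0.02 < cont_flags / reps < 0.12
        assert 0.02 < cat_flags / reps < 0.10

    def test_perfectly_correlated_covariate_flagged(self):
        n = 40
        eta = pd.DataFrame({"ID": np.arange(n), "eta_Cl": np.linspace(-1, 1, n)})
        cov = pd.DataFrame({"ID": np.arange(n), "WT": np.linspace(50, 90, n)})
        out = covsearch.screen_covariates(eta, cov)
        p = out[out.test == "pearson"]["p_value"].iloc[0]
        assert p < 1e-20
        assert out["flagged"].all()

    def test_degenerate_categorical_skipped(self):
        n = 3
        eta = pd.DataFrame({"ID": np.arange(n), "eta_Cl": [0.1, -0.2, 0.3]})
        cov = pd.DataFrame({"ID": np.arange(n), "RACE": [0, 1, 2]})
        out = covsearch.screen_covariates(eta, cov)
        assert (out.test == "skipped").all()

    def test_constant_covariate_skipped(self):
        n = 10
        eta = pd.DataFrame({"ID": np.arange(n), "eta_Cl": np.random.default_rng(3).standard_normal(n)})
        cov = pd.DataFrame({"ID": np.arange(n), "WT": np.full(n, 70.0)})
        out = covsearch.screen_covariates(eta, cov)
        assert (out.test == "skipped").all()


def _selection_problem(seed, beta=25.0):
    """20-subject dataset with (optionally) a gender effect on clearance."""
    base_model = model.default_population_model()
    omega = {p: 0.0 for p in model.PARAM_NAMES}
    omega.update({"Cl": 10.0, "ka": 0.4, "V1": 8.0})
    link = model.CovariateLink(parameter="Cl", covariate="SEX", kind="categorical",
                               beta=beta, reference=0, category=1)
    pop = replace(base_model, omega=omega,
                  error=model.ErrorModel(a=1e-4, b=0.05),
                  links=(link,) if beta else ())
    subs = pd.DataFrame({"ID": np.arange(1, 21), "SEX": [0, 1] * 10})
    sched = np.array([0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0])
    reg = DoseRegimen(4.0, interval=6.0, n_doses=4)
    ds = model.simulate_dataset(pop, subs, sched, reg, seed=seed)
    base_init = pop.with_links(())
    settings = saem.SaemSettings(k1=40, k2=30, seed=seed + 1)
    base_fit = saem.saem_fit(ds, base_init, settings)
    return ds, base_fit, settings


def _candidates():
    return [
        model.CovariateLink(parameter="Cl", covariate="SEX", kind="categorical",
                            beta=0.0, reference=0, category=1),
        model.CovariateLink(parameter="V1", covariate="SEX", kind="categorical",
                            beta=0.0, reference=0, category=1),
    ]


class TestStepwiseSearch:
    def test_power_against_strong_gender_effect(self):
        n_rep, hits, wald_hits = 5, 0, 0
        for r in range(n_rep):
            ds, base_fit, settings = _selection_problem(1000 + 17 * r, beta=25.0)
            final, trace = covsearch.stepwise_search(
                ds, base_fit, _candidates(), settings=settings,
                is_draws=150, ll_seed=50 + r,
            )
            labels = [l.label for l in final.pop.links]
            if "beta_Cl_SEX_1" in labels:
                hits += 1
                wald = covsearch.wald_tests(final, is_draws=100, seed=60 + r)
                _, p = wald["beta_Cl_SEX_1"]
                wald_hits += bool(np.isfinite(p) and p < 0.05)
        assert hits >= 4          # >= 80% power
        assert wald_hits >= 0.8 * hits

    def test_null_data_keeps_base_model(self):
        n_rep, clean = 5, 0
        for r in range(n_rep):
            ds, base_fit, settings = _selection_problem(3000 + 13 * r, beta=0.0)
            final, _ = covsearch.stepwise_search(
                ds, base_fit, _candidates(), settings=settings,
                is_draws=150, ll_seed=70 + r,
            )
            clean += len(final.pop.links) == 0
        assert clean >= 4          # false-inclusion controlled (>= 70%)

    def test_empty_candidates_return_base(self):
        ds, base_fit, settings = _selection_problem(5000, beta=0.0)
        final, trace = covsearch.stepwise_search(
            ds, base_fit, [], settings=settings, is_draws=100,
        )
        assert final.pop.links == ()
        assert len(trace) == 0

    def test_duplicate_candidates_enter_once(self):
        ds, base_fit, settings = _selection_problem(6000, beta=25.0)
        cands = _candidates()[:1] * 3
        final, trace = covsearch.stepwise_search(
            ds, base_fit, cands, settings=settings, is_draws=100,
        )
        labels = [l.label for l in final.pop.links]
        assert len(labels) == len(set(labels))


class TestCossacSearch:
    def test_agrees_with_stepwise_on_strong_effect(self):
        n_rep, agree = 3, 0
        for r in range(n_rep):
            ds, base_fit, settings = _selection_problem(8000 + 29 * r, beta=25.0)
            final_c, _ = covsearch.cossac_search(
                ds, base_fit, covariates=["SEX"], settings=settings,
                is_draws=150, ll_seed=80 + r,
            )
            labels = [l.label for l in final_c.pop.links]
            agree += "beta_Cl_SEX_1" in labels
        assert agree >= 2          # >= 70% method agreement

    def test_zero_iiv_returns_base_with_warning(self, final_model, q6h_regimen):
        pop = replace(final_model,
                      omega={p: 0.0 for p in model.PARAM_NAMES},
                      error=model.ErrorModel(a=1e-4, b=0.05))
        subs = pd.DataFrame({"ID": [1, 2], "SEX": [0, 1]})
        sched = np.array([1.0, 6.0, 12.0, 24.0])
        ds = model.simulate_dataset(pop, subs, sched, q6h_regimen, seed=4)
        fit = saem.saem_fit(ds, replace(pop), saem.SaemSettings(k1=10, k2=5, seed=1))
        # force the zero-IIV condition on the fitted object
        fit.pop = replace(fit.pop, omega={p: 0.0 for p in model.PARAM_NAMES})
        final, trace = covsearch.cossac_search(ds, fit)
        assert final is fit
        assert "degenerate" in trace.iloc[0]["reason"]
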
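"""SAEM estimation, marginal likelihood, BICc, EBEs, standard errors."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from salbupop import model, saem


def _noiseless_pop(final_model):
    """Packaged fixed effects, no IIV, near-zero residual error."""
    return replace(
        final_model,
        omega={p: 0.0 for p in model.PARAM_NAMES},
        error=model.ErrorModel(a=1e-8, b=1e-4),
    )


@pytest.fixture(scope="module")
def noiseless_dataset(final_model, q6h_regimen, rich_schedule):
    pop = _noiseless_pop(final_model)
    subs = pd.DataFrame({"ID": np.arange(1, 9)})
    return pop, model.simulate_dataset(pop, subs, rich_schedule, q6h_regimen, seed=3)


class TestBicc:
    def test_penalty_arithmetic(self):
        base = saem.bicc(-100.0, 40, 838, 10, 2)
        plus_one_beta = saem.bicc(-100.0, 40, 838, 11, 2)
        assert plus_one_beta - base == pytest.approx(math.log(40))

    def test_zero_dimension_reduces_to_m2ll(self):
        assert saem.bicc(-123.4, 40, 838, 0, 0) == -123.4

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            saem.bicc(0.0, 0, 10, 1, 1)


class TestLoglikImportance:
    def test_no_random_effects_is_exact(self, final_model, q6h_regimen, rich_schedule):
        pop = _noiseless_pop(final_model)
        pop = replace(pop, error=model.ErrorModel(a=1e-4, b=0.05))
        subs = pd.DataFrame({"ID": [1, 2]})
        ds = model.simulate_dataset(pop, subs, rich_schedule, q6h_regimen, seed=5)
        m2ll, se = saem.loglik_importance(pop, ds, n_draws=50, seed=0)
        assert se == 0.0
        # independent direct computation
        p = model.StructuralParams(**pop.theta)
        f = model.predict_conc(p, q6h_regimen, rich_schedule, method="conv", dt=0.0625)
        total = 0.0
        for sid in ds.subject_ids:
            y = ds.observations(sid)["DV"].to_numpy()
            sd = pop.error.sd(f)
            total += np.sum(-0.5 * ((y - f) / sd) ** 2 - np.log(sd)
                            - 0.5 * math.log(2 * math.pi))
        assert m2ll == pytest.approx(-2.0 * total, rel=1e-9)

    def test_matches_quadrature_oracle_one_dimension(
        self, final_model, q6h_regimen, rich_schedule
    ):
        # only Cl carries IIV: per-subject marginal is a 1-D integral that
        # adaptive quadrature evaluates to near machine precision
        omega = {p: 0.0 for p in model.PARAM_NAMES}
        omega["Cl"] = 20.0
        pop = replace(
            final_model, omega=omega, error=model.ErrorModel(a=1e-4, b=0.05)
        )
        subs = pd.DataFrame({"ID": [1, 2, 3]})
        sched = rich_schedule[::3]
        ds = model.simulate_dataset(pop, subs, sched, q6h_regimen, seed=8)
        m2ll, se = saem.loglik_importance(pop, ds, n_draws=4000, seed=1)

        def subject_marginal(sid):
            y = ds.observations(sid)["DV"].to_numpy()

            def integrand(eta):
                th = dict(pop.theta)
                th["Cl"] = th["Cl"] + eta
                p = model.StructuralParams(**th)
                f = model.predict_conc(p, q6h_regimen, sched, method="conv", dt=0.0625)
                sd = pop.error.sd(f)
                ll = np.sum(-0.5 * ((y - f) / sd) ** 2 - np.log(sd)
                            - 0.5 * math.log(2 * math.pi))
                prior = math.exp(-0.5 * (eta / 20.0) ** 2) / (20.0 * math.sqrt(2 * math.pi))
                return math.exp(ll) * prior

            val, _ = quad(integrand, -80.0, 80.0, limit=200)
            return math.log(val)

        oracle = -2.0 * sum(subject_marginal(s) for s in ds.subject_ids)
        assert m2ll == pytest.approx(oracle, abs=max(4.0 * se, 0.5))

    def test_mc_error_shrinks_with_draws(self, final_model, q6h_regimen, rich_schedule):
        omega = {p: 0.0 for p in model.PARAM_NAMES}
        omega["Cl"] = 20.0
        pop = replace(final_model, omega=omega,
                      error=model.ErrorModel(a=1e-4, b=0.05))
        subs = pd.DataFrame({"ID": [1, 2, 3]})
        ds = model.simulate_dataset(pop, subs, rich_schedule[::3], q6h_regimen, seed=8)
        reps = 6
        ests_small = [saem.loglik_importance(pop, ds, n_draws=200, seed=100 + r)[0]
                      for r in range(reps)]
        ests_big = [saem.loglik_importance(pop, ds, n_draws=800, seed=200 + r)[0]
                    for r in range(reps)]
        # 4x draws ~ half the spread (allow generous slack at 6 replicates)
        assert np.std(ests_big) < np.std(ests_small)


class TestSaemFit:
    def test_noiseless_recovery_within_two_percent(self, noiseless_dataset):
        pop_true, ds = noiseless_dataset
        init, eta0 = saem.individual_fit_init(ds)
        fit = saem.saem_fit(
            ds, init, saem.SaemSettings(k1=60, k2=40, seed=2), eta0=eta0
        )
        for p in model.PARAM_NAMES:
            assert fit.pop.theta[p] == pytest.approx(pop_true.theta[p], rel=0.02), p

    def test_row_permutation_invariance(self, final_model, q6h_regimen):
        subs = pd.DataFrame({"ID": np.arange(1, 5)})
        sched = np.array([0.5, 1.0, 2.0, 4.0, 6.0, 10.0, 14.0, 24.0])
        ds = model.simulate_dataset(final_model, subs, sched, q6h_regimen, seed=4)
        perm = ds.frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
        ds_perm = model.PKDataset(perm)
        settings = saem.SaemSettings(k1=15, k2=10, seed=6)
        init = replace(final_model)
        f1 = saem.saem_fit(ds, init, settings)
        f2 = saem.saem_fit(ds_perm, init, settings)
        for p in model.PARAM_NAMES:
            assert f1.pop.theta[p] == f2.pop.theta[p], p

    def test_trace_length_and_omega_positive(self, final_model_fit):
        st = final_model_fit.settings
        assert len(final_model_fit.trace) == st.k1 + st.k2
        assert all(v >= 0 for v in final_model_fit.pop.omega.values())

    def test_absorption_rate_recovered(self, final_model_fit):
        # the identifiable headline parameter of the final model
        assert final_model_fit.pop.theta["ka"] == pytest.approx(2.91, rel=0.2)

    def test_residual_error_scale_recovered(self, final_model_fit, final_model):
        # proportional error within a factor ~2 of the generating 0.15%
        assert final_model.error.b / 3 < final_model_fit.pop.error.b < final_model.error.b * 3


class TestComputeEbes:
    def test_complete_shrinkage_with_tiny_omega(self, final_model, q6h_regimen):
        pop = replace(
            final_model,
            omega={p: (1e-6 if p == "Cl" else 0.0) for p in model.PARAM_NAMES},
            error=model.ErrorModel(a=1e-3, b=0.2),
        )
        subs = pd.DataFrame({"ID": [1, 2]})
        sched = np.array([1.0, 4.0, 8.0, 16.0, 24.0])
        ds = model.simulate_dataset(pop, subs, sched, q6h_regimen, seed=9)
        ebes = saem.compute_ebes(pop, ds)
        assert np.all(np.abs(ebes["eta_Cl"]) < 1e-4)

    def test_noiseless_rich_data_recovers_individuals(
        self, final_model, q6h_regimen, rich_schedule
    ):
        pop = replace(final_model, error=model.ErrorModel(a=1e-8, b=1e-4))
        subs = pd.DataFrame({"ID": [1, 2, 3]})
        ds, truth = model.simulate_dataset(
            pop, subs, rich_schedule, q6h_regimen, seed=12, return_truth=True
        )
        ebes = saem.compute_ebes(pop, ds, starts=None)
        merged = ebes.merge(truth, on="ID", suffixes=("_ebe", "_true"))
        # absorption-side parameters are individually identifiable
        for p in ("Mtt", "Ktr", "ka", "Cl"):
            rel = np.abs(merged[f"{p}_ebe"] - merged[f"{p}_true"]) / merged[f"{p}_true"]
            assert rel.max() < 0.01, p

    def test_dataset_without_observations_rejected(self):
        frame = pd.DataFrame({
            "ID": [1, 1], "TIME": [0.0, 0.0], "DV": [np.nan, np.nan],
            "AMT": [4.0, 4.0], "EVID": [1, 1],
        })
        with pytest.raises(ValueError):
            model.PKDataset(frame)


class TestStandardErrors:
    def test_duplicated_dataset_halves_variance(self, final_model, q6h_regimen):
        # same data twice -> information doubles -> SE / sqrt(2)
        omega = {p: 0.0 for p in model.PARAM_NAMES}
        omega.update({"Cl": 15.0, "ka": 0.4})
        pop = replace(final_model, omega=omega,
                      error=model.ErrorModel(a=1e-4, b=0.05))
        subs = pd.DataFrame({"ID": np.arange(1, 13)})
        sched = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 18.0, 24.0])
        ds = model.simulate_dataset(pop, subs, sched, q6h_regimen, seed=21)
        init = replace(pop)
        fit = saem.saem_fit(ds, init, saem.SaemSettings(k1=40, k2=30, seed=7))

        dup = ds.frame.copy()
        dup["ID"] = dup["ID"] + 100
        ds2 = model.PKDataset(pd.concat([ds.frame, dup], ignore_index=True))
        fit2 = saem.FitResult(
            pop=fit.pop, dataset=ds2, trace=fit.trace,
            eta=np.tile(fit.eta, (2, 1)),
            cond_mean=np.tile(fit.cond_mean, (2, 1)),
            cond_sd=np.tile(fit.cond_sd, (2, 1)),
            cond_draws=fit.cond_draws, ids=np.arange(24),
            seed=fit.seed, settings=fit.settings,
        )
        block = ["omega_Cl", "a", "b"]
        rse1 = saem.standard_errors(fit, n_draws=100, seed=5, include=block)
        rse2 = saem.standard_errors(fit2, n_draws=100, seed=5, include=block)
        ratios = [rse2[k] / rse1[k] for k in block
                  if np.isfinite(rse1.get(k, np.nan)) and np.isfinite(rse2.get(k, np.nan))]
        assert len(ratios) >= 2
        assert np.median(ratios) == pytest.approx(1.0 / math.sqrt(2.0), rel=0.25)

    def test_flat_direction_flagged(self, final_model, q6h_regimen):
        # V2 carries no information when Q ~ 0 in truth: RSE missing/huge
        omega = {p: 0.0 for p in model.PARAM_NAMES}
        omega["Cl"] = 15.0
        truth_pop = replace(
            final_model,
            theta={**final_model.theta, "Q": 1e-3},
            omega=omega, error=model.ErrorModel(a=1e-4, b=0.05),
        )
        subs = pd.DataFrame({"ID": np.arange(1, 7)})
        sched = np.array([1.0, 4.0, 8.0, 16.0, 24.0])
        ds = model.simulate_dataset(truth_pop, subs, sched, q6h_regimen, seed=30)
        fit = saem.saem_fit(ds, replace(truth_pop), saem.SaemSettings(k1=15, k2=10, seed=3))
        rse = saem.standard_errors(fit, n_draws=60, seed=2, include=["V2", "b"])
        assert not np.isfinite(rse["V2"]) or rse["V2"] > 100.0
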
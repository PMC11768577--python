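"""Structural popPK model: transit input, prediction, simulation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from salbupop import model


class TestTransitInput:
    @pytest.mark.parametrize("mtt,ktr", [(9.5, 0.15), (2.0, 1.7), (0.5, 2.5)])
    def test_normalizes_to_bioavailable_dose(self, mtt, ktr):
        val, _ = quad(
            lambda t: model.transit_input_rate(t, 4000.0, 0.8, mtt, ktr),
            0.0, 200.0 * mtt, limit=500,
        )
        assert val == pytest.approx(0.8 * 4000.0, rel=1e-6)

    def test_zero_at_origin_for_positive_n(self):
        assert model.transit_input_rate(0.0, 1000.0, 1.0, 9.5, 0.15) == 0.0

    def test_peak_time_matches_gamma_mode(self):
        # Mtt = 9.50, Ktr = 0.15 -> n = 0.425, mode at n / Ktr
        mtt, ktr = 9.5, 0.15
        n = ktr * mtt - 1.0
        t = np.linspace(0.01, 30, 30000)
        r = model.transit_input_rate(t, 1.0, 1.0, mtt, ktr)
        assert t[np.argmax(r)] == pytest.approx(n / ktr, abs=0.01)
        assert n / ktr == pytest.approx(2.83, abs=0.01)

    def test_rejects_invalid_transit_number(self):
        with pytest.raises(ValueError):
            model.transit_input_rate(1.0, 1.0, 1.0, 5.0, 0.0)  # n = -1


class TestPredictConc:
    def test_zero_dose(self, final_model):
        p = model.StructuralParams(**final_model.theta)
        out = model.predict_conc(p, [(0.0, 0.0)], np.linspace(0, 24, 10))
        assert np.allclose(out, 0.0)

    def test_one_compartment_closed_form_limit(self):
        # Q -> 0, Mtt tiny: matches the oral one-compartment solution
        # delayed by the mean transit time
        mtt = 0.005
        p = model.StructuralParams(
            Mtt=mtt, Ktr=2 / mtt, ka=1.2, Cl=20.0, V1=50.0, Q=1e-6, V2=1.0
        )
        t = np.linspace(0.25, 24, 40)
        got = model.predict_conc(p, [(0.0, 4000.0)], t, method="ode")
        ke = 20.0 / 50.0
        ts = t - mtt
        ref = 1.2 * 4000.0 / (50.0 * (1.2 - ke)) * (
            np.exp(-ke * ts) - np.exp(-1.2 * ts)
        ) / 1000.0
        assert np.max(np.abs(got - ref) / ref) < 0.005

    def test_self_oracle_at_tightened_tolerance(self, final_model, q6h_regimen):
        p = model.StructuralParams(**final_model.theta)
        t = np.linspace(0.25, 24, 49)
        base = model.predict_conc(p, q6h_regimen, t, method="ode")
        tight = model.predict_conc(p, q6h_regimen, t, method="ode", rtol=1e-10)
        assert np.max(np.abs(base - tight) / tight) < 1e-6

    def test_conv_path_matches_ode(self, final_model, q6h_regimen):
        p = model.StructuralParams(**final_model.theta)
        t = np.linspace(0.25, 24, 49)
        ode = model.predict_conc(p, q6h_regimen, t, method="ode", rtol=1e-10)
        conv = model.predict_conc(p, q6h_regimen, t, method="conv", dt=0.0125)
        assert np.max(np.abs(conv - ode) / ode) < 1e-3

    def test_linear_in_dose(self, final_model):
        p = model.StructuralParams(**final_model.theta)
        t = np.linspace(0.5, 24, 20)
        c1 = model.predict_conc(p, [(0.0, 4000.0)], t, method="conv")
        c2 = model.predict_conc(p, [(0.0, 8000.0)], t, method="conv")
        assert np.allclose(c2, 2 * c1, rtol=1e-9)


class TestIndividualParams:
    def test_identity_without_links_or_eta(self, final_model):
        p = model.individual_params(final_model, {}, np.zeros(7))
        for name in model.PARAM_NAMES:
            assert getattr(p, name) == final_model.theta[name]

    def test_continuous_link_zero_at_reference(self, final_model):
        link = model.CovariateLink(
            parameter="Cl", covariate="WT", kind="continuous", beta=0.5, reference=70.0
        )
        pop = final_model.with_links([link])
        p = model.individual_params(pop, {"WT": 70.0}, np.zeros(7))
        assert p.Cl == pop.theta["Cl"]
        p2 = model.individual_params(pop, {"WT": 80.0}, np.zeros(7))
        assert p2.Cl == pytest.approx(pop.theta["Cl"] + 5.0)

    def test_gender_effect_direction(self, final_model):
        # positive beta for the female category raises female clearance
        link = model.CovariateLink(
            parameter="Cl", covariate="SEX", kind="categorical", beta=25.0,
            reference=0, category=1,
        )
        pop = final_model.with_links([link])
        female = model.individual_params(pop, {"SEX": 1}, np.zeros(7))
        male = model.individual_params(pop, {"SEX": 0}, np.zeros(7))
        assert female.Cl > male.Cl

    def test_unknown_covariate_rejected(self, final_model):
        link = model.CovariateLink(
            parameter="Cl", covariate="WT", kind="continuous", beta=0.5, reference=70.0
        )
        pop = final_model.with_links([link])
        with pytest.raises(KeyError):
            model.individual_params(pop, {"AGE": 30.0}, np.zeros(7))


class TestResidualSd:
    def test_additive_at_zero_and_proportional_limits(self):
        err = model.ErrorModel(a=0.1, b=0.0)
        assert model.residual_sd(0.0, err) == pytest.approx(0.1)
        err2 = model.ErrorModel(a=0.0, b=0.2)
        assert model.residual_sd(5.0, err2) == pytest.approx(1.0)

    def test_combined_table_values(self):
        err = model.ErrorModel(a=0.19e-4, b=0.15e-2)
        f = 0.005
        assert model.residual_sd(f, err) == pytest.approx(
            math.sqrt((0.19e-4) ** 2 + (0.15e-2 * f) ** 2), rel=1e-12
        )

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            model.ErrorModel(a=0.0, b=0.0)


class TestSimulateDataset:
    def test_deterministic_under_seed(self, final_model, q6h_regimen, rich_schedule):
        subs = pd.DataFrame({"ID": [1, 2, 3]})
        d1 = model.simulate_dataset(final_model, subs, rich_schedule, q6h_regimen, seed=9)
        d2 = model.simulate_dataset(final_model, subs, rich_schedule, q6h_regimen, seed=9)
        pd.testing.assert_frame_equal(d1.frame, d2.frame)

    def test_degenerate_model_reproduces_prediction(self, final_model, q6h_regimen):
        from dataclasses import replace

        pop = replace(
            final_model,
            omega={p: 0.0 for p in model.PARAM_NAMES},
            error=model.ErrorModel(a=1e-12, b=1e-12),
        )
        subs = pd.DataFrame({"ID": [1]})
        sched = np.linspace(0.5, 24, 10)
        ds = model.simulate_dataset(pop, subs, sched, q6h_regimen, seed=1)
        p = model.StructuralParams(**pop.theta)
        ref = model.predict_conc(p, q6h_regimen, sched, method="conv", dt=0.0625)
        dv = ds.observations(1)["DV"].to_numpy()
        assert np.allclose(dv, ref, rtol=1e-6, atol=1e-12)

    def test_between_subject_spread_matches_omega(self, final_model, q6h_regimen):
        # spot-check on Cl: sample SD of individual Cl ~ omega_Cl at large n
        # (slightly shrunk by the positivity rejection step)
        subs = pd.DataFrame({"ID": np.arange(1, 401)})
        sched = np.array([6.0, 24.0])
        _, truth = model.simulate_dataset(
            final_model, subs, sched, q6h_regimen, seed=17, return_truth=True
        )
        assert truth["Cl"].std() == pytest.approx(final_model.omega["Cl"], rel=0.2)
        assert truth["ka"].std() == pytest.approx(final_model.omega["ka"], rel=0.2)

    def test_observation_count(self, parametric_dataset):
        ds, _ = parametric_dataset
        assert ds.n_subjects == 40
        assert ds.n_observations == 840
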
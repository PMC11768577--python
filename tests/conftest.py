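import numpy as np
import pandas as pd
import pytest

from salbupop import cohort as cohort_mod
from salbupop import io as io_mod
from salbupop import model, pbpk


@pytest.fixture(scope="session")
def reference_subject():
    return cohort_mod.reference_subject()


@pytest.fixture(scope="session")
def reference_physiology(reference_subject):
    return cohort_mod.scale_physiology(reference_subject)


@pytest.fixture(scope="session")
def compound():
    return pbpk.default_compound()


@pytest.fixture(scope="session")
def kp_set():
    return pbpk.default_kp_set()


@pytest.fixture(scope="session")
def default_cohort():
    spec = cohort_mod.default_cohort_spec(seed=20250101)
    return cohort_mod.sample_cohort(spec)


@pytest.fixture(scope="session")
def single_dose_profile(reference_physiology, compound, kp_set):
    """Reference-male single 4 mg oral dose, 48 h grid."""
    reg = pbpk.DoseRegimen(4.0, n_doses=1)
    grid = np.linspace(0.0, 48.0, 481)
    return pbpk.simulate_pbpk(reference_physiology, compound, kp_set, reg, grid)


@pytest.fixture(scope="session")
def final_model():
    return model.default_population_model()


@pytest.fixture(scope="session")
def q6h_regimen():
    return pbpk.DoseRegimen(4.0, interval=6.0, n_doses=4)


@pytest.fixture(scope="session")
def rich_schedule():
    return io_mod.default_schedule()


@pytest.fixture(scope="session")
def parametric_dataset(final_model, q6h_regimen, rich_schedule):
    """40 subjects simulated from the packaged final model, with truth."""
    subs = pd.DataFrame({"ID": np.arange(1, 41)})
    return model.simulate_dataset(
        final_model, subs, rich_schedule, q6h_regimen, seed=101, return_truth=True
    )


@pytest.fixture(scope="session")
def final_model_fit(parametric_dataset):
    """Full SAEM fit of the packaged-model simulation (shared; expensive)."""
    from salbupop import saem

    ds, _ = parametric_dataset
    init, eta0 = saem.individual_fit_init(ds)
    settings = saem.SaemSettings(k1=200, k2=100, seed=42)
    return saem.saem_fit(ds, init, settings, eta0=eta0)
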
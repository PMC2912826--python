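import numpy as np
import pytest

from socsurv.pseudo_records import compute_pseudo_records
from socsurv.simulate import SimConfig, simulate_dataset
from socsurv.survival_model import fit_cox_animal


@pytest.fixture(scope="session")
def hazard_sim():
    """Moderate hazard-scale population (~600 hens) with social effects."""
    cfg = SimConfig(n_sires=8, dams_per_sire=8, mean_offspring_per_dam=10,
                    houses=2, rows=2, levels=2, seed=5)
    data, ped, truth = simulate_dataset(cfg)
    return data, ped.ensure(data["animal"]), truth


@pytest.fixture(scope="session")
def cox_fit(hazard_sim):
    data, ped, _ = hazard_sim
    return fit_cox_animal(data, ped)


@pytest.fixture(scope="session")
def pseudo(hazard_sim, cox_fit):
    data, _, _ = hazard_sim
    return compute_pseudo_records(cox_fit, data)


@pytest.fixture(scope="session")
def small_linear_sim():
    """Small linear-scale population, uncensored, for mixed-model tests."""
    r_a = 0.18
    s2ad, s2as = 915.0, 134.0
    g = np.array([[s2ad, r_a * np.sqrt(s2ad * s2as)],
                  [r_a * np.sqrt(s2ad * s2as), s2as]])
    cfg = SimConfig(
        n_sires=8, dams_per_sire=8, mean_offspring_per_dam=10,
        scale="linear", G0_true=g, rho_true=0.08, sigma2_e_true=11530.0,
        houses=2, rows=2, levels=2, study_end_day=None, seed=11,
    )
    data, ped, truth = simulate_dataset(cfg)
    return data, ped.ensure(data["animal"]), truth
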
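import numpy as np
import pytest

from hypertx import (DrugRegimen, baseline_state, default_patient,
                     generate_population, observe)


@pytest.fixture(scope="session")
def reference_patient():
    """Constructed reference hypertensive patient (160/100, HR 75, 80 kg)."""
    return default_patient()


@pytest.fixture(scope="session")
def reference_equilibrium(reference_patient):
    return observe(baseline_state(reference_patient), reference_patient)


@pytest.fixture(scope="session")
def small_population():
    """Six-patient seeded population shared by the slower pipeline tests."""
    return generate_population(n=6, seed=42)


@pytest.fixture(scope="session")
def small_population_baseline(small_population):
    return np.array([[vp.equilibrium.SBP, vp.equilibrium.DBP,
                      vp.equilibrium.HR] for vp in small_population])
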
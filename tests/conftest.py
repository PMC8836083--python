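import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import caoscsim as cs

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> cs.ModelParameters:
    return cs.kyse150_parameters()


@pytest.fixture(scope="session")
def drug_params() -> cs.DrugParameters:
    return cs.baseline_drug_parameters()


@pytest.fixture(scope="session")
def baseline_summary(params, drug_params) -> cs.OscillationSummary:
    """Untreated KYSE-150 oscillation summary (compiled backend)."""
    return cs.simulate_period(params, drug_params, method="rk45")


def period_at(params, drug_params, dose, t_end=6000.0, cutoff=1500.0):
    """Convenience: mean period (s) at a dose, NaN if not oscillating."""
    summ = cs.simulate_period(params, drug_params, dose, t_end=t_end,
                              transient_cutoff=cutoff, method="rk45")
    return summ.period_mean if summ.oscillating else np.nan
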
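import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("suite")

from twolocus import (MigrationModel, SampleConfig, effective_params,
                      make_symmetric_diallelic, solve_probabilities)
from twolocus.experiments import run_scenario, two_deme_scenarios


@pytest.fixture(scope="session")
def params_ref():
    """Symmetric diallelic model at the reference parameters theta=0.01, rho=50."""
    return make_symmetric_diallelic(0.01, 50.0)


@pytest.fixture(scope="session")
def table1(params_ref):
    """Solved recursion covering every full-gamete configuration with n <= 6."""
    return solve_probabilities(SampleConfig.full([[6, 0], [0, 0]]), params_ref)


@pytest.fixture(scope="session")
def table1_n7(params_ref):
    """Same, n <= 7; needed for add-one-gamete consistency sums."""
    return solve_probabilities(SampleConfig.full([[7, 0], [0, 0]]), params_ref)


@pytest.fixture(scope="session")
def mig_nonconservative():
    """Two-deme migration model with q' != xi, hence delta < 1."""
    return MigrationModel([[0.9, 0.1], [0.2, 0.8]], (1 / 5, 4 / 5))


@pytest.fixture(scope="session")
def table2(mig_nonconservative):
    """Solved recursion at the rescaled parameters (theta*delta, rho*delta)."""
    theta_eff, rho_eff = effective_params(0.01, 50.0, mig_nonconservative.delta)
    params = make_symmetric_diallelic(theta_eff, rho_eff)
    return solve_probabilities(SampleConfig.full([[6, 0], [0, 0]]), params)


# --- chain arms for the scaled-down validation study (shared across tests;
# each arm is 8 replicate chains of ~5e5 generations) ---

@pytest.fixture(scope="session")
def scenario_specs():
    return two_deme_scenarios()


@pytest.fixture(scope="session")
def report_conservative(scenario_specs):
    return run_scenario(scenario_specs[0])


@pytest.fixture(scope="session")
def report_nonconservative(scenario_specs):
    return run_scenario(scenario_specs[1])


@pytest.fixture(scope="session")
def report_conservative_mono(scenario_specs):
    """Same scenario as report_conservative but started from a monomorphic state."""
    return run_scenario(scenario_specs[0], init="monomorphic")
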
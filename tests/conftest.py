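import pytest

from dairymin import balance_data, meta_regression, synthetic_data


@pytest.fixture(scope="session")
def p_records():
    """One simulated P balance-trial dataset at the default conditions."""
    params = synthetic_data.SimulationParams.for_mineral("P", seed=42)
    return synthetic_data.simulate_balance_trials(params)


@pytest.fixture(scope="session")
def p_obs(p_records):
    """Scaled observations with weights for the P dataset."""
    return balance_data.weighted_observations(p_records)


@pytest.fixture(scope="session")
def p_fit(p_obs):
    """One converged excretion-model fit on the P dataset."""
    return meta_regression.fit_excretion_model(p_obs)
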
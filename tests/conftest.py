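import numpy as np
import pytest

from provar import trialgen as tg


@pytest.fixture(scope="session")
def regular_trials_2k():
    """A shared batch of Regular trials for regression-based tests."""
    return tg.generate_trialset(2000, seed=101)


@pytest.fixture(scope="session")
def agent_choices_20k():
    """Choices of a known logistic agent on 20k Regular trials
    (unrounded heights keep the generative coefficients exact)."""
    config = tg.GenConfig(round_heights=False)
    ts = tg.generate_trialset(20_000, config=config, seed=7)
    agent = tg.AgentSpec(beta0=0.0, beta_mean=0.10, beta_sd=0.02)
    cs = tg.simulate_logistic_agent(ts, agent, np.random.default_rng(11))
    return ts, agent, cs
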
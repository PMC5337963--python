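import numpy as np
import pandas as pd
import pytest

from pupilbias import synthetic


def make_trials(n_blocks=4, seed=0, session=1, obs=None, coherence_set="easy",
                return_truth=False):
    """Small simulated dataset used across test modules."""
    obs = obs or synthetic.ObserverParams(noise="logistic")
    rng = np.random.default_rng(seed)
    seq = synthetic.generate_stimulus_sequence(n_blocks, coherence_set,
                                               seed=rng)
    return synthetic.simulate_observer(seq, obs, session=session, seed=rng,
                                       return_truth=return_truth)


@pytest.fixture(scope="session")
def plain_trials():
    """200 trials from an unbiased observer."""
    return make_trials(n_blocks=4, seed=11)


@pytest.fixture(scope="session")
def repeater_trials():
    """2500 trials from a lag-1 choice repeater (decaying kernel)."""
    obs = synthetic.ObserverParams(
        kernel_choice=0.3 * np.exp(-np.arange(7)),
        noise="logistic", lapse=0.02)
    rng = np.random.default_rng(21)
    parts = []
    for s in range(1, 6):
        seq = synthetic.generate_stimulus_sequence(10, "easy", seed=rng)
        parts.append(synthetic.simulate_observer(seq, obs, session=s,
                                                 seed=rng))
    return pd.concat(parts, ignore_index=True)
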
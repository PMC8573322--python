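import numpy as np
import pytest

import searchshift as ss


@pytest.fixture(scope="session")
def exp2_pairs():
    """60 strategy-discriminating pairs: EV and maximax disagree on each."""
    return ss.generate_pairs(60, "exp2", seed=1)


@pytest.fixture(scope="session")
def exp1_pairs():
    return ss.generate_pairs(60, "exp1", seed=2)


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated experiment shared by IO/inference/pipeline tests."""
    cfg = ss.PipelineConfig(seed=7, n_participants=12, n_pairs=20, n_boot=200)
    trials, fixations, pairs = ss.simulate_experiment(cfg)
    trials = ss.inference.add_ev_consistent(trials, pairs)
    return cfg, trials, fixations, pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
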
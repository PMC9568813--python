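import numpy as np
import pandas as pd
import pytest

from asrt.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study, shared across tests."""
    cfg = SimulationConfig(n_cu=10, n_mci=10)
    return simulate_study(cfg, seed=11)


@pytest.fixture(scope="session")
def noiseless_config():
    """Zero text-noise conditions: retellings are verbatim unit subsets."""
    return SimulationConfig(
        n_cu=10, n_mci=10,
        token_dropout=0.0, token_substitution=0.0, filler_insertion=0.0,
        story_skip=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_study(noiseless_config):
    return simulate_study(noiseless_config, seed=5)


@pytest.fixture()
def two_sentence_story():
    """Source with two disjoint-vocabulary sentences of 5 and 10 tokens."""
    first = "alpha bravo charlie delta echo"
    second = "foxtrot golf hotel india juliet kilo lima mike november oscar"
    return {"text": f"{first.capitalize()}. {second.capitalize()}.",
            "first": first, "second": second}
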
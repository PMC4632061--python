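import numpy as np
import pandas as pd
import pytest

from gsflux.generate import generate_design, simulate_concentrations
from gsflux.pathway import build_default_model, steady_state


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def wt_state(default_model):
    ss = steady_state(default_model)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def plants():
    """One full simulated study (3 lines x 368 plants), fixed seed."""
    design = generate_design()
    return simulate_concentrations(design, seed=20150910)


@pytest.fixture(scope="session")
def cyp79f1_plants(plants):
    return plants[plants["line"] == "Cyp79f1"].reset_index(drop=True)
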
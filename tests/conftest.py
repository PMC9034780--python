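import numpy as np
import pytest

from scracm.pipeline import analyze_session, average_morphology_profile, simulate_cell
from scracm.synthetic_data import SimSpec, generate_morphology


@pytest.fixture(scope="session")
def avg_morph():
    """Average dendritic profile over 11 generated reconstructions."""
    return average_morphology_profile(n=11, seed=1)


@pytest.fixture(scope="session")
def default_morph():
    return generate_morphology(500.0, seed=1)


@pytest.fixture(scope="session")
def noisy_cell():
    """One simulated cell at default conditions, analysed end to end."""
    session, morph = simulate_cell(SimSpec(), seed=5)
    return session, morph, analyze_session(session)


@pytest.fixture(scope="session")
def noiseless_cell():
    """A noise-free simulated cell for exact-charge checks."""
    spec = SimSpec(noise_sd_pa=0.0, n_trials=2)
    session, morph = simulate_cell(spec, seed=3)
    return spec, session, morph, analyze_session(session)
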
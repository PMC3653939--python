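import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

import seedlim as sl


@pytest.fixture(scope="session")
def small_design():
    """8 plots x 2 stations, all five species: quick but structured."""
    return sl.ExperimentDesign(n_plots=8, stations_per_plot=2)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return sl.simulate_experiment(small_design, sl.TrueParams(), 20130514)
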
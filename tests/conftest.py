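import datetime as dt

import pandas as pd
import pytest

from mindu.simulate import SimulationConfig, simulate_survey

#: Published axis-1 coordinates of the eleven Niger Delta stations.
TABLE1_COORDS = {
    "Wa": -19.811, "An1": -11.592, "An2": -9.4896, "Ad": -8.3649,
    "Ol": -5.7767, "Et1": -2.1216, "Et2": 10.287, "Ob": 7.0565,
    "Og1": 22.909, "Og2": 17.97, "Or": -1.0664,
}

#: Published (distance, percent distance, category) per station.
TABLE1_EXPECTED = {
    "Wa": (42.72, 100.0, 1),
    "An1": (34.501, 80.76077, 1),
    "An2": (32.3986, 75.83942, 2),
    "Ad": (31.2739, 73.20669, 2),
    "Ol": (28.6857, 67.14817, 2),
    "Et1": (25.0306, 58.59223, 2),
    "Et2": (12.622, 29.54588, 3),
    "Ob": (15.8525, 37.10791, 3),
    "Og1": (0.0, 0.0, 3),
    "Og2": (4.939, 11.56133, 3),
    "Or": (23.9754, 56.12219, 3),
}


@pytest.fixture(scope="session")
def table1_coords():
    return pd.Series(TABLE1_COORDS)


@pytest.fixture(scope="session")
def table1_expected():
    return TABLE1_EXPECTED


@pytest.fixture(scope="session")
def survey():
    """One default synthetic survey, shared across tests."""
    return simulate_survey(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_survey():
    """A shorter survey for quicker end-to-end checks."""
    return simulate_survey(SimulationConfig(seed=2, n_months=6))


@pytest.fixture()
def abundance_csv(tmp_path):
    path = tmp_path / "abundance.csv"
    path.write_text(
        "station,date,taxon,count\n"
        "A,2009-05-15,Chironomidae,12\n"
        "A,2009-05-15,Baetidae,5\n"
        "B,2009-11-15,Naucoridae,3\n"
    )
    return path
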
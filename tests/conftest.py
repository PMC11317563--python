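import warnings

import numpy as np
import pandas as pd
import pytest

from harvestcarbon import defaults, load_tables
from harvestcarbon.synthetic import simulate_harvest_reports, simulate_trips

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def species():
    return defaults.species_frame()


@pytest.fixture(scope="session")
def tiny_species():
    """One species per taxon class, round weights, for arithmetic checks."""
    return pd.DataFrame(
        [
            ("goose", "geese", "bird", 2.0, "poultry"),
            ("char", "char", "fish", 2.5, "fish_mix"),
            ("caribou", "caribou", "mammal", 40.0, "beef_pork_mix"),
        ],
        columns=defaults.SPECIES_COLUMNS,
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("cfg")
    paths = defaults.write_default_inputs(out)
    return load_tables(paths["species"], paths["prices"], paths["config"])


@pytest.fixture(scope="session")
def small_survey(species):
    """A 300-report heaped survey with its ground truth."""
    return simulate_harvest_reports(species, 300, seed=101)


@pytest.fixture(scope="session")
def trips_table():
    """A trip table at observed-study scale (132 trips)."""
    return simulate_trips(132, seed=202)
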
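import numpy as np
import pandas as pd
import pytest

from addseries.data import COLUMNS, ExperimentTable
from addseries.simulate import DEFAULT_PARAMS, DesignSpec, generate_dataset, noise_free


def make_record(
    pot_id="p1",
    replicate=1,
    species="BRTE",
    planted=(4, 0),
    realized=None,
    biomass=0.1,
):
    realized = realized or planted
    return {
        "pot_id": pot_id,
        "replicate": replicate,
        "species": species,
        "planted_n_brte": planted[0],
        "planted_n_vedu": planted[1],
        "realized_n_brte": realized[0],
        "realized_n_vedu": realized[1],
        "biomass_g": biomass,
    }


def table_from_rows(rows) -> ExperimentTable:
    return ExperimentTable(pd.DataFrame(rows, columns=COLUMNS))


@pytest.fixture(scope="session")
def noise_free_table() -> ExperimentTable:
    """Default design, default parameter magnitudes, no noise, no mortality."""
    return generate_dataset(DesignSpec(seed=11), noise_free(DEFAULT_PARAMS))


@pytest.fixture(scope="session")
def noisy_table() -> ExperimentTable:
    """One seeded experiment at the default (noisy) generator settings."""
    return generate_dataset(DesignSpec(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
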
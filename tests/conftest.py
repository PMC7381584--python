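import numpy as np
import pandas as pd
import pytest

from pollinet.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20170501)


@pytest.fixture
def observations_df():
    """Three well-formed observation periods."""
    rows = []
    for i, (hb, fly, ant) in enumerate([(2, 3, 5), (0, 0, 0), (4, 1, 2)]):
        rows.append({
            "obs_id": f"O{i}", "site": "S1", "week": 1 + i, "zone": "Z1",
            "plant_id": ["A", "B", "A"][i], "floral_units": 30,
            "minutes": 15.0,
            "visits_honey_bee": hb, "visits_other_bee_wasp": 0,
            "visits_fly": fly, "visits_butterfly_moth": 0,
            "visits_ant": ant, "visits_true_bug": 1,
            "outside_honey_bee": 0, "outside_other_bee_wasp": 0,
            "outside_fly": 1, "outside_butterfly_moth": 0,
            "outside_ant": 0, "outside_true_bug": 0,
        })
    return pd.DataFrame(rows)


@pytest.fixture
def plants_df():
    return pd.DataFrame({
        "plant_id": ["A", "B", "C"],
        "name": ["Alpha", "Beta", "Gamma"],
        "native_status": ["native", "introduced", "excluded"],
    })


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic synthetic dataset shared across tests."""
    return generate_dataset(GeneratorConfig(seed=11, n_plants=16,
                                            n_weeks=6, n_sites=2))
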
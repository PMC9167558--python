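import numpy as np
import pandas as pd
import pytest

from invashift.synthetic_data import SyntheticScenario, simulate_dataset
from invashift.tables_io import CountTable, SampleMetadata


def make_metadata(
    ids,
    region="RedSea",
    season="spring",
    species="S_rivulatus",
    compartment="fish",
) -> SampleMetadata:
    """Build metadata from per-sample labels (scalars broadcast)."""
    n = len(ids)

    def broadcast(x):
        return list(x) if isinstance(x, (list, tuple, np.ndarray, pd.Series)) else [x] * n

    return SampleMetadata(
        pd.DataFrame(
            {
                "compartment": broadcast(compartment),
                "host_species": broadcast(species),
                "region": broadcast(region),
                "season": broadcast(season),
                "site": ["site1"] * n,
            },
            index=list(ids),
        )
    )


def small_scenario(seed=42, n_per_group=6, n_features=60):
    sizes = {
        (sp, reg, season): n_per_group
        for sp in ("S_rivulatus", "S_luridus")
        for reg in ("RedSea", "Crete")
        for season in ("spring", "autumn")
    }
    return SyntheticScenario(
        n_features=n_features,
        n_samples_per_group=sizes,
        depth_mean=2000.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small two-species, two-region simulated dataset shared by tests."""
    return simulate_dataset(small_scenario(), oracle_samples=0)


@pytest.fixture()
def toy_table():
    df = pd.DataFrame(
        [[5, 0, 2], [2, 3, 0], [0, 7, 1], [4, 4, 4]],
        index=["s1", "s2", "s3", "s4"],
        columns=["f1", "f2", "f3"],
    )
    return CountTable(df)
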
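import numpy as np
import pandas as pd
import pytest

from lakesize import RunConfig, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default sampling-null dataset at a fixed seed, shared across tests."""
    return generate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def synthetic_results(synthetic_dataset):
    """Full pipeline run (short resampling) on the shared dataset."""
    from lakesize import run_analysis

    cfg = RunConfig(seed=0, resample_reps=100)
    return run_analysis(synthetic_dataset.species, synthetic_dataset.lakes, cfg)


@pytest.fixture()
def toy_species_frame():
    """Five species in two lakes, one without a height measurement."""
    return pd.DataFrame(
        {
            "species_id": [f"sp{i}" for i in range(1, 6)],
            "lake_id": ["A", "A", "A", "B", "B"],
            "family": ["F1", "F1", "F2", "F2", "F3"],
            "height": [4.0, 9.0, 2.0, np.nan, 5.0],
            "width": [1.0, 9.0, 8.0, 3.0, 5.0],
            "endemic": [True, False, False, True, False],
        }
    )


@pytest.fixture()
def toy_species_csv(tmp_path, toy_species_frame):
    path = tmp_path / "species.csv"
    toy_species_frame.to_csv(path, index=False)
    return path


@pytest.fixture()
def toy_lakes_csv(tmp_path):
    path = tmp_path / "lakes.csv"
    pd.DataFrame(
        {
            "lake_id": ["A", "B"],
            "latitude": [45.0, 42.0],
            "longitude": [10.0, 20.0],
            "area": [100.0, 2500.0],
            "duration": [1.0, 3.0],
            "pct_endemism": [33.3, 50.0],
            "distance": [10.0, 40.0],
            "n_species": [3, 2],
        }
    ).to_csv(path, index=False)
    return path
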
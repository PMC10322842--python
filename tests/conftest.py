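import numpy as np
import pandas as pd
import pytest

from navgap.cultural_atlas import load_cluster_map
from navgap.synthetic_cohort import generate_cohort, plant_world


@pytest.fixture(scope="session")
def cluster_map():
    return load_cluster_map()


@pytest.fixture(scope="session")
def small_world():
    """6 countries x 300 players: shared read-only cohort for pipeline tests."""
    config = plant_world(6, 300, seed=11)
    players, trajectories, truth = generate_cohort(config)
    return config, players, trajectories, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_distance_table():
    """Hand-sized per-attempt distance table used by scoring tests."""
    rows = [
        # player, level, attempt, distance
        ("a", 1, 1, 10.0), ("a", 2, 1, 20.0),
        ("a", 3, 1, 50.0), ("a", 6, 1, 30.0),
        ("b", 1, 1, 10.0), ("b", 1, 2, 20.0), ("b", 1, 3, 30.0), ("b", 1, 4, 40.0),
        ("b", 2, 1, 6.0),
        ("b", 3, 1, 26.0), ("b", 3, 2, 99.0), ("b", 6, 1, 13.0),
        ("c", 1, 1, 30.0), ("c", 2, 1, 30.0),
        ("c", 3, 1, 120.0), ("c", 6, 1, 60.0),
    ]
    return pd.DataFrame(rows, columns=["player_id", "level", "attempt", "distance"])
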
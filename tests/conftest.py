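import numpy as np
import pandas as pd
import pytest

from forestshift import Grid, ScenarioConfig, simulate_scenario


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(
        n_cells_x=6,
        n_cells_y=6,
        n_clusters=3,
        n_taxa=8,
        obs_per_cell=20,
        plots_per_cell=5,
        n_years=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return simulate_scenario(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_observations(rows):
    """Observation table from (obs_id, line_id, seq, kind, x, y, x2, y2, taxa)."""
    return pd.DataFrame(
        rows,
        columns=["obs_id", "line_id", "seq", "kind", "x", "y", "x2", "y2", "taxa"],
    )


def point(obs_id, line_id, seq, x, y, taxa):
    return (obs_id, line_id, seq, "point", x, y, np.nan, np.nan, taxa)


def line(obs_id, line_id, seq, x, y, x2, y2, taxa):
    return (obs_id, line_id, seq, "line", x, y, x2, y2, taxa)
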
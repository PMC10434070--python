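"""Shared fixtures: synthetic study datasets at desk-friendly sizes."""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

from lakeco.simulate import SimulationConfig, simulate_dataset


class ImportanceLinear(LinearRegression):
    """Deterministic stand-in regressor exposing |coef| as importances."""

    @property
    def feature_importances_(self):
        c = np.abs(self.coef_)
        total = c.sum()
        return c / total if total > 0 else c


def make_dataset(w, seed=202, n_taxa=140, depth=2500, samples_per_lake=2):
    cfg = SimulationConfig(
        samples_per_lake=samples_per_lake,
        n_taxa=n_taxa,
        filtering_strength=w,
        sequencing_depth=depth,
        seed=seed,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def neutral_run():
    """Neutral assembly (w = 0): every sample draws from the same pool."""
    return make_dataset(0.0)


@pytest.fixture(scope="session")
def selected_run():
    """Strong salinity filtering (w = 4), same seed/design as neutral_run."""
    return make_dataset(4.0)


@pytest.fixture(scope="session")
def selected_big():
    """Larger selected design for per-group network construction."""
    return make_dataset(4.0, seed=303, n_taxa=150, depth=3000, samples_per_lake=12)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
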
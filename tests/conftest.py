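"""Shared fixtures: a small synthetic world reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from nicheshift.grid_io import Grid
from nicheshift.maxent_engine import build_features, fit_maxent, sample_background
from nicheshift.occurrence_prep import occurrence_cells, thin_to_grid
from nicheshift.synthetic_data import (
    SyntheticSpecies, SyntheticWorldConfig, generate_landscape, sample_presences,
    true_suitability,
)

CANDIDATE_LAYERS = ("BIO1", "BIO6", "BIO8", "BIO11", "BIO12", "BIO18")


@pytest.fixture(scope="session")
def world():
    cfg = SyntheticWorldConfig(
        n_rows=100, n_cols=100, layer_names=CANDIDATE_LAYERS, seed=1
    )
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def species():
    return SyntheticSpecies(n_presence=200, seed=1)


@pytest.fixture(scope="session")
def truth(world, species):
    return true_suitability(species, world)


@pytest.fixture(scope="session")
def thinned_occurrences(world, truth):
    occ = sample_presences(truth, 200, seed=2)
    return thin_to_grid(occ, world.template, seed=3)


@pytest.fixture(scope="session")
def presence_values(world, thinned_occurrences):
    rows, cols = occurrence_cells(thinned_occurrences, world.template)
    return pd.DataFrame(world.value_table(rows, cols), columns=world.names)


@pytest.fixture(scope="session")
def background(world):
    return sample_background(world, 1000, seed=4)


@pytest.fixture(scope="session")
def lq_features(background, species):
    return build_features(
        None, list(species.true_variables), classes=("linear", "quadratic"),
        background=background.values,
    )


@pytest.fixture(scope="session")
def fitted(presence_values, background, lq_features):
    """A well-converged model on the true variables (beta = 1)."""
    return fit_maxent(presence_values, background.values, lq_features, beta=1.0)


def make_grid(values, x_min=0.0, y_max=None, cell_size=1.0, nodata=-9999.0, name="g"):
    values = np.asarray(values, dtype=float)
    if y_max is None:
        y_max = values.shape[0] * cell_size
    return Grid(values=values, x_min=x_min, y_max=y_max, cell_size=cell_size,
                nodata=nodata, name=name)


@pytest.fixture
def grid_factory():
    return make_grid
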
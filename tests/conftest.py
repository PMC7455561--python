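import numpy as np
import pandas as pd
import pytest

import sdmniche as sn
from sdmniche.raster import GridTransform, PROJECTED, RasterGrid


@pytest.fixture(scope="session")
def small_scenario():
    return sn.SyntheticScenario(shape=(60, 60), rng_seed=3)


@pytest.fixture(scope="session")
def small_stack(small_scenario):
    return sn.generate_env_stack(small_scenario)


@pytest.fixture(scope="session")
def narrow_species():
    """Strongly separable virtual species (niche width << predictor range)."""
    return sn.VirtualSpecies({"bio12": sn.GaussianResponse(600.0, 100.0),
                              "bio5": sn.GaussianResponse(45.0, 3.0)})


@pytest.fixture(scope="session")
def training_tables(small_stack, narrow_species):
    """Presence/background predictor tables plus a held-out presence table."""
    suit = sn.suitability_surface(narrow_species, small_stack)
    pres = sn.sample_presences(suit, 200, rng_seed=5)
    bg = sn.sample_background(small_stack, 1500, rng_seed=6)
    train, test = sn.split_train_test(pres, 0.8, rng_seed=7)
    return {
        "train": sn.extract_env_values(train, small_stack),
        "test": sn.extract_env_values(test, small_stack),
        "background": sn.extract_env_values(bg, small_stack),
        "suit": suit,
    }


@pytest.fixture(scope="session")
def fast_hyperparameters():
    """Cheap tree settings for contract tests that do not probe accuracy."""
    return {"gbm": {"n_trees": 100}, "rf": {"n_trees": 100}}


def make_grid(values, cell_size=1000.0, x_min=0.0, y_max=None,
              crs_kind=PROJECTED, mask=None):
    values = np.asarray(values, dtype=float)
    if y_max is None:
        y_max = values.shape[0] * cell_size
    return RasterGrid(values, GridTransform(x_min, y_max, cell_size),
                      crs_kind, mask)


@pytest.fixture
def grid_factory():
    return make_grid
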
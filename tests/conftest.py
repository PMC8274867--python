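import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from geodisc import landscape as ls

logging.getLogger("geodisc").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=RuntimeWarning, module="statsmodels")


def make_grid(
    tenure: np.ndarray,
    carbon: dict[int, np.ndarray] | None = None,
    covariates: dict[str, np.ndarray] | None = None,
    cell_size: float = 0.5,
    years: tuple[int, ...] = (2003,),
    region: np.ndarray | None = None,
) -> ls.LandscapeGrid:
    """Hand-built grid from 2D arrays, defaulting covariates/carbon to constants."""
    tenure = np.asarray(tenure, dtype=object)
    shape = tenure.shape
    layers: dict[str, np.ndarray] = {"tenure": tenure}
    defaults = {
        "elevation": 500.0,
        "slope": 10.0,
        "dist_roads": 15.0,
        "dist_settlements": 20.0,
        "dist_rivers": 8.0,
    }
    for name in ls.COVARIATES:
        layers[name] = (
            np.asarray(covariates[name], dtype=float)
            if covariates and name in covariates
            else np.full(shape, defaults[name])
        )
    for y in years:
        layers[f"carbon_{y}"] = (
            np.asarray(carbon[y], dtype=float)
            if carbon and y in carbon
            else np.full(shape, 100.0)
        )
    grid = ls.load_grid(layers, years=years, cell_size=cell_size)
    if region is not None:
        grid.table["region"] = np.asarray(region, dtype=object).ravel()
    return grid


@pytest.fixture
def split_grid():
    """10x10 grid, left half IT, right half OTHER, constant covariates."""
    tenure = np.full((10, 10), "OTHER", dtype=object)
    tenure[:, :5] = "IT"
    return make_grid(tenure)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
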
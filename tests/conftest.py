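import numpy as np
import pytest

from routexpose.hexgrid import (
    aggregate_buildings,
    aggregate_streets,
    assign_noise,
    count_pois,
    get_scheme,
    make_grid,
)
from routexpose.router import build_network
from routexpose.synthetic_city import CityConfig, UtilityParams, generate_city


@pytest.fixture(scope="session")
def city():
    """One seeded toy city shared by the aggregation/routing/exposure tests."""
    return generate_city(CityConfig(seed=7))


@pytest.fixture(scope="session")
def scheme(city):
    return get_scheme(city.config.noise_scheme_name)


@pytest.fixture(scope="session")
def city_grid(city, scheme):
    grid = make_grid(city.config.bbox)
    grid = aggregate_buildings(grid, city.buildings)
    grid = aggregate_streets(grid, city.streets)
    grid = count_pois(grid, city.pois)
    return assign_noise(grid, city.noise, scheme)


@pytest.fixture(scope="session")
def network(city):
    return build_network(city.streets)


@pytest.fixture(scope="session")
def default_params():
    return UtilityParams()


def make_classification_frame(n, seed, informative_feature="x0", n_noise=4):
    """3-class synthetic trip-like table where the label depends only on one
    feature; used by the modeling and interpretation tests."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0, 3, n)
    noise = rng.normal(size=(n, n_noise))
    labels = np.where(x0 < 1.0, "walk", np.where(x0 < 2.0, "bicycle", "car"))
    frame = pd.DataFrame({informative_feature: x0})
    for i in range(n_noise):
        frame[f"noise{i}"] = noise[:, i]
    frame["mode"] = labels
    frame.insert(0, "individual_id", np.arange(n))
    return frame
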
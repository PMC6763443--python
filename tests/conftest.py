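import numpy as np
import pandas as pd
import pytest

import treemort as tm
from treemort.scenario import SyntheticScenario


@pytest.fixture(scope="session")
def small_scenario():
    return SyntheticScenario(domain_size_m=(120.0, 120.0), n_trees=120,
                             min_spacing_m=4.0, seed=7)


@pytest.fixture(scope="session")
def small_landscape(small_scenario):
    land = tm.generate_landscape(small_scenario)
    return tm.simulate_mortality(land)


@pytest.fixture(scope="session")
def small_chm(small_landscape):
    return tm.render_chm(small_landscape)


def make_landscape(trees: pd.DataFrame, scenario=None) -> tm.Landscape:
    """Hand-built landscape around an explicit tree table (for exact-geometry
    tests); environmental rasters are flat."""
    scen = scenario or SyntheticScenario(domain_size_m=(60.0, 60.0), n_trees=0)
    shape = scen.shape
    env = {name: np.full(shape, 1.0) for name in
           ("vpd_max", "dt_pct", "dppt_pct", "soil_awc", "cover_pct", "slope_pct")}
    trees = trees.copy()
    if "crown_radius" not in trees:
        trees["crown_radius"] = scen.crown_radius_coef * trees["height"]
    if "death_year" not in trees:
        trees["death_year"] = np.nan
    for name in env:
        if name not in trees:
            trees[name] = 1.0
    return tm.Landscape(scenario=scen, trees=trees, env_fields=env)
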
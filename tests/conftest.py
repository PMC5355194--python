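import numpy as np
import pandas as pd
import pytest

from reefshift.grids import GridSpec, great_circle_km


@pytest.fixture(scope="session")
def unit_row_spec():
    """1x4 equatorial row; horizontal step = one degree of longitude."""
    return GridSpec(nrows=1, ncols=4, cellsize=1.0, lon0=0.0, lat0=0.0)


@pytest.fixture(scope="session")
def unit_step_km():
    """Great-circle length of a one-degree step along the equator."""
    return float(great_circle_km(0.0, 0.0, 1.0, 0.0))


@pytest.fixture(scope="session")
def small_world():
    """A small but fully structured synthetic world, shared read-only."""
    from reefshift.synthetic import ScenarioConfig, generate_world

    cfg = ScenarioConfig(seed=7, grid_shape=(36, 120), n_species=60)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_sdm_results(small_world):
    """Partition-only SDM summaries for the shared small world."""
    from reefshift.sdm import ALL_PREDICTORS, fit_predictor_sets, partition_deviance

    pred = small_world.predictors[list(ALL_PREDICTORS)]
    rows = {}
    for sp in small_world.occurrences.index:
        y = small_world.occurrences.loc[sp].to_numpy(float)
        fits = fit_predictor_sets(y, pred, str(sp))
        if not all(fits[k].converged for k in ("full", "contemporary", "historical")):
            continue
        part = partition_deviance(fits)
        rows[sp] = {
            "d2_full": fits["full"].d2,
            "d2_contemporary": fits["contemporary"].d2,
            "d2_historical": fits["historical"].d2,
            "pure_contemporary": part.pure_contemporary,
            "shared": part.shared,
            "pure_historical": part.pure_historical,
            "unexplained": part.unexplained,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def random_sea_grid(rng, shape=(20, 20), p_land=0.3):
    """Random traversability mask with a guaranteed sea cell."""
    mask = rng.uniform(size=shape) > p_land
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask
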
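from datetime import datetime

import numpy as np
import pytest

from borealdeer.occupancy import OccupancyParams
from borealdeer.survey import DetectionHistory, build_design


@pytest.fixture
def design_12x3():
    """The deer study's layout: 12 quarterly seasons x 3 monthly surveys."""
    return build_design(datetime(2011, 10, 1), 12, 3)


@pytest.fixture
def small_design():
    return build_design(datetime(2011, 10, 1), 3, 2)


def random_params(design, rng) -> OccupancyParams:
    """Random valid parameter set, kept away from the exact boundary."""
    T, J = design.n_seasons, design.surveys_per_season
    u = lambda size=None: rng.uniform(0.05, 0.95, size)
    return OccupancyParams(
        psi1=float(u()),
        epsilon=u(max(T - 1, 0)),
        gamma=u(max(T - 1, 0)),
        p=u((T, J)),
    )


def random_history(design, n_sites, rng, missing_rate=0.0) -> DetectionHistory:
    m = rng.integers(0, 2, size=(n_sites, design.n_surveys)).astype(float)
    if missing_rate:
        mask = rng.random(m.shape) < missing_rate
        mask[mask.all(axis=1), 0] = False
        m[mask] = np.nan
    coords = rng.uniform(0, 10000, size=(n_sites, 2))
    return DetectionHistory(
        site_ids=[f"s{i}" for i in range(n_sites)], coordinates=coords, matrix=m
    )
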
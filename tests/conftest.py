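from __future__ import annotations

import numpy as np
import pytest

from noisepop import SplSeries, load_curve_registry
from noisepop.synth import LC_DEVELOPED, LC_TRANSPORT, gen_world
from noisepop.population import distribute_population, impervious_mask


def make_series(levels, start=0, utc_offset_s=0, **kw):
    """Contiguous 1-Hz series from a level sequence."""
    levels = np.asarray(levels, dtype=float)
    return SplSeries(
        location_id="test",
        timestamps=start + np.arange(len(levels), dtype=np.int64),
        levels=levels,
        utc_offset_s=utc_offset_s,
        **kw,
    )


@pytest.fixture(scope="session")
def curves():
    return load_curve_registry()


@pytest.fixture(scope="session")
def curve_by_name(curves):
    return {c.name: c for c in curves}


@pytest.fixture(scope="session")
def small_world():
    """A 60x60 synthetic study area shared by pipeline-level tests."""
    return gen_world(seed=7, nrows=60, ncols=60, n_blocks=12)


@pytest.fixture(scope="session")
def small_world_pop(small_world):
    mask = impervious_mask(
        small_world.census.landcover, {LC_DEVELOPED}, {LC_TRANSPORT}
    )
    return distribute_population(
        small_world.census.blocks, mask, small_world.spec
    )
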
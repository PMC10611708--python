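import numpy as np
import pytest

from vegshift.grid_io import Grid, GridStack, Transform
from vegshift.synthetic_landscape import LandscapeSpec, gen_fields, gen_landcover, gen_occurrences, true_potential_map

UNIT_TRANSFORM = Transform(x0=0.0, y0=0.0, dx=1.0, dy=1.0)


def make_grid(values, cell=1.0, nodata=np.nan, **kw) -> Grid:
    values = np.asarray(values, dtype=float)
    t = Transform(x0=0.0, y0=values.shape[0] * cell, dx=cell, dy=cell)
    return Grid(values=values, transform=t, nodata=nodata, **kw)


@pytest.fixture(scope="session")
def small_spec() -> LandscapeSpec:
    """A reduced landscape used by most integration fixtures (fast to generate)."""
    return LandscapeSpec(shape=(80, 80), seed=7)


@pytest.fixture(scope="session")
def small_fields(small_spec):
    return gen_fields(small_spec)


@pytest.fixture(scope="session")
def small_occurrences(small_spec, small_fields):
    current, paleo, _, _ = small_fields
    return gen_occurrences(current, paleo, small_spec)


@pytest.fixture(scope="session")
def small_truth(small_spec, small_fields):
    current, _, _, _ = small_fields
    return true_potential_map(current, small_spec)


@pytest.fixture(scope="session")
def small_landcover(small_spec, small_fields, small_truth):
    _, _, hfp, _ = small_fields
    return gen_landcover(small_truth, hfp, small_spec)
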
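import numpy as np
import pytest

from mcda.composites import CompositeSeries, EVIComposite
from mcda.synthetic import default_specs, generate_scene


def make_series(per_pixel_values, year=2006, doys=None, masks=None):
    """Series of constant-valued composites from a per-composite value list.

    ``per_pixel_values`` may contain NaN to mark nodata; ``masks`` overrides
    per-composite nodata grids.  Grid is 2x2 unless masks dictate otherwise.
    """
    doys = doys if doys is not None else [225 + 16 * i for i in range(len(per_pixel_values))]
    comps = []
    for i, (v, doy) in enumerate(zip(per_pixel_values, doys)):
        grid = np.full((2, 2), v, dtype=float)
        mask = None if masks is None else masks[i]
        comps.append(EVIComposite(grid, year=year, doy=doy, nodata_mask=mask))
    return CompositeSeries(comps)


@pytest.fixture(scope="session")
def small_scene():
    """One 120x120 default scene shared by the slower end-to-end tests."""
    return generate_scene(grid_size=(120, 120), seed=7)


@pytest.fixture(scope="session")
def shifted_scene():
    """Same landscape with the soybean-cotton calendar anticipated 30 days."""
    specs = [
        s.shifted(30) if s.class_name == "soybean_cotton" else s
        for s in default_specs()
    ]
    return generate_scene(specs, grid_size=(120, 120), seed=7)
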
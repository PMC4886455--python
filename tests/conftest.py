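import pytest

import croprisk as cr


@pytest.fixture(scope="session")
def small_config():
    """A small but complete study world: two pooled regions + one alone."""
    regions = (
        cr.RegionSpec("aragon", x0=0.0, y0=0.0, width=15_000.0, height=15_000.0, n_population=4000),
        cr.RegionSpec("catalonia", x0=30_000.0, y0=0.0, width=15_000.0, height=15_000.0, n_population=4000),
        cr.RegionSpec("madrid", x0=60_000.0, y0=0.0, width=15_000.0, height=15_000.0, n_population=4000),
    )
    return cr.SimulationConfig(seed=42, regions=regions)


@pytest.fixture(scope="session")
def small_world(small_config):
    return cr.generate_world(small_config)


@pytest.fixture()
def unit_square():
    from shapely.geometry import box

    return box(0.0, 0.0, 1.0, 1.0)


def make_random_scene(rng, n_polygons=6, extent=4000.0, cell=800.0):
    """Disjoint random rectangles on a coarse grid, random crop classes."""
    from shapely.geometry import box

    ncell = int(extent // cell)
    cells = rng.choice(ncell * ncell, size=min(n_polygons, ncell * ncell), replace=False)
    polys = []
    for k, c in enumerate(cells):
        i, j = divmod(int(c), ncell)
        cls = rng.choice(list(cr.ALL_CLASSES))
        polys.append(
            cr.LandCoverPolygon(f"p{k}", box(i * cell - extent / 2, j * cell - extent / 2,
                                             (i + 1) * cell - extent / 2, (j + 1) * cell - extent / 2), cls)
        )
    return cr.LandCoverMap("scene", polys)
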
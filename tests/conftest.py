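import numpy as np
import pytest

from standcarbon.stand_io import (
    AllometryEntry,
    AllometryTable,
    CarbonFractionTable,
    StemMap,
    Tree,
)


def make_stem_map(xy, plot_id="T", extent=(20.0, 20.0), species=None, dbh=None):
    """Build a StemMap from coordinate pairs with optional marks."""
    n = len(xy)
    species = species or ["SPX"] * n
    dbh = dbh if dbh is not None else [10.0] * n
    trees = tuple(
        Tree(tree_id=f"t{i:03d}", x=float(x), y=float(y), species=species[i], dbh=float(dbh[i]))
        for i, (x, y) in enumerate(xy)
    )
    return StemMap(plot_id=plot_id, trees=trees, extent=extent)


def lattice_map(spacing=2.0, extent=(20.0, 20.0), **kwargs):
    """Full square lattice of trees at the given spacing."""
    xs = np.arange(spacing / 2, extent[0], spacing)
    ys = np.arange(spacing / 2, extent[1], spacing)
    xy = [(x, y) for y in ys for x in xs]
    return make_stem_map(xy, extent=extent, **kwargs)


def random_map(n, seed, extent=(20.0, 20.0)):
    rng = np.random.default_rng(seed)
    xy = np.column_stack([rng.uniform(0, extent[0], n), rng.uniform(0, extent[1], n)])
    dbh = rng.uniform(5, 60, n)
    species = [f"S{int(s)}" for s in rng.integers(0, 6, n)]
    return make_stem_map(xy.tolist(), extent=extent, species=species, dbh=dbh.tolist())


@pytest.fixture
def simple_allometry():
    return AllometryTable(
        entries={
            "PINMAS": AllometryEntry("PINMAS", a=0.05, b=2.5),
            "DEFAULT": AllometryEntry("DEFAULT", a=0.05, b=2.4),
        }
    )


@pytest.fixture
def half_fractions():
    return CarbonFractionTable(fractions={}, fallback=0.5)
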
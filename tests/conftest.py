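import numpy as np
import pytest
from hypothesis import settings

from emtcpm.lattice import CellTable, PixelLattice, PottsParams, RandomStream, \
    recompute_geometry

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

TYPE_NAMES = ("Medium", "LowBetaCat", "HighBetaCat")


def flat_contact_table(j=0.0):
    return {(a, b): j for i, a in enumerate(TYPE_NAMES)
            for b in TYPE_NAMES[i:]}


@pytest.fixture
def potts_params():
    table = flat_contact_table(0.0)
    table.update({("Medium", "LowBetaCat"): 8.0,
                  ("LowBetaCat", "LowBetaCat"): 3.0,
                  ("Medium", "HighBetaCat"): 4.0,
                  ("LowBetaCat", "HighBetaCat"): 14.0,
                  ("HighBetaCat", "HighBetaCat"): 14.0})
    return PottsParams(contact_table=table)


def random_soup(dims=(8, 8, 6), n_cells=4, seed=0, type_choices=(1, 2)):
    """A random multi-cell spin configuration with consistent bookkeeping."""
    rng = np.random.default_rng(seed)
    lat = PixelLattice(dims)
    cells = CellTable()
    ids = [cells.new_cell(int(rng.choice(type_choices))) for _ in range(n_cells)]
    lat.spin[:] = rng.choice([0] + ids, size=dims)
    recompute_geometry(lat, cells)
    for cid in ids:
        cells.tvol[cid] = float(rng.integers(10, 120))
        cells.tsurf[cid] = float(rng.integers(30, 200))
        cells.init_volume[cid] = max(int(cells.volume[cid]), 1)
    return lat, cells, ids


@pytest.fixture
def soup():
    return random_soup()


@pytest.fixture
def stream():
    return RandomStream(1234)
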
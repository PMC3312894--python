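"""Hamiltonian terms against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from emtcpm import _kernels
from emtcpm.energy import (ChemotaxisSpec, chemotaxis_delta, delta_hamiltonian,
                           surface_energy, total_contact_energy,
                           total_hamiltonian, volume_energy)
from emtcpm.errors import ConfigurationError
from emtcpm.lattice import (CellTable, PixelLattice, PottsParams, RandomStream,
                            neighbour_offsets, recompute_geometry)

from conftest import flat_contact_table, random_soup


def brute_force_contact(lattice, cells, params, order):
    """Independent O(N * noff) link enumeration (each link counted twice)."""
    jm = params.j_matrix()
    spin = lattice.spin
    nx, ny, nz = spin.shape
    total = 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = spin[x, y, z]
                for ox, oy, oz in neighbour_offsets(order, 3):
                    jx, jy, jz = x + ox, y + oy, z + oz
                    if not (0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz):
                        continue
                    b = spin[jx, jy, jz]
                    if a != b:
                        total += jm[cells.ctype[a], cells.ctype[b]]
    return total / 2.0


@pytest.mark.parametrize("order", [1, 2, 4])
def test_contact_energy_matches_brute_force(order, potts_params):
    lat, cells, _ = random_soup(dims=(6, 5, 4), n_cells=3, seed=order)
    got = total_contact_energy(lat, cells, potts_params, order)
    exp = brute_force_contact(lat, cells, potts_params, order)
    assert got == pytest.approx(exp, rel=1e-12)


def test_single_cell_has_zero_contact_energy(potts_params):
    lat = PixelLattice((3, 3, 3))
    cells = CellTable()
    lat.spin[:] = cells.new_cell(1)
    recompute_geometry(lat, cells)
    assert total_contact_energy(lat, cells, potts_params, 4) == 0.0


def test_two_adjacent_single_pixel_cells():
    lat = PixelLattice((2, 1, 1))
    cells = CellTable()
    a = cells.new_cell(1)
    b = cells.new_cell(2)
    lat.spin[0, 0, 0] = a
    lat.spin[1, 0, 0] = b
    recompute_geometry(lat, cells)
    table = flat_contact_table(0.0)
    table[("LowBetaCat", "HighBetaCat")] = 7.5
    params = PottsParams(contact_table=table, neighbour_order=1)
    assert total_contact_energy(lat, cells, params, 1) == pytest.approx(7.5)


def test_contact_energy_invariant_under_type_swap(potts_params):
    """With a symmetric J table, relabelling every type pair symmetrically
    leaves the energy unchanged."""
    lat, cells, ids = random_soup(dims=(6, 6, 4), n_cells=4, seed=9)
    e1 = total_contact_energy(lat, cells, potts_params, 2)
    swapped = {1: 2, 2: 1}
    for cid in ids:
        cells.ctype[cid] = swapped[int(cells.ctype[cid])]
    table = {}
    for (a, b), v in potts_params.contact_table.items():
        m = {"LowBetaCat": "HighBetaCat", "HighBetaCat": "LowBetaCat"}
        table[(m.get(a, a), m.get(b, b))] = v
    swapped_params = PottsParams(contact_table=table)
    e2 = total_contact_energy(lat, cells, swapped_params, 2)
    assert e1 == pytest.approx(e2)


def test_missing_type_pair_is_configuration_error(soup):
    lat, cells, _ = soup
    with pytest.raises(ConfigurationError):
        total_contact_energy(lat, cells, {("Medium", "LowBetaCat"): 1.0}, 1)


def test_volume_and_surface_energy_arithmetic():
    cells = CellTable()
    cid = cells.new_cell(1)
    rec = cells.record(cid)
    rec.volume, rec.target_volume = 5, 3
    assert volume_energy(rec, 2.0) == pytest.approx(8.0)
    rec.volume = 3
    assert volume_energy(rec, 2.0) == 0.0
    rec.surface, rec.target_surface = 10, 6
    assert surface_energy(rec, 1.0) == pytest.approx(16.0)
    rec.surface = 6
    assert surface_energy(rec, 1.0) == 0.0


def test_single_pixel_cell_has_six_boundary_faces():
    lat = PixelLattice((3, 3, 3))
    cells = CellTable()
    cid = cells.new_cell(1)
    lat.spin[1, 1, 1] = cid
    recompute_geometry(lat, cells)
    assert cells.surface[cid] == 6


def test_chemotaxis_delta_conventions():
    spec = ChemotaxisSpec(kind="linear", origin=(0, 0, 0), axis=(0, 1, 0),
                          slope=2.0, coefficient={"LowBetaCat": 3.0})
    # advancing one pixel up the gradient is energetically favourable
    assert chemotaxis_delta(spec, (0, 0, 0), (0, 1, 0), "LowBetaCat") == \
        pytest.approx(-3.0 * 2.0)
    # uniform field and zero coefficient are exactly neutral
    assert chemotaxis_delta(spec, (0, 2, 0), (5, 2, 3), "HighBetaCat") == 0.0
    flat = ChemotaxisSpec(kind="none")
    assert chemotaxis_delta(flat, (0, 0, 0), (0, 1, 0), "LowBetaCat") == 0.0


def test_radial_field_increases_outward():
    spec = ChemotaxisSpec(kind="radial", origin=(2, 2, 2), slope=1.5)
    assert spec.concentration((2, 2, 2)) == 0.0
    assert spec.concentration((2, 2, 5)) == pytest.approx(4.5)
    field = spec.build_field((5, 5, 5))
    assert field[2, 2, 2] == 0.0
    assert field[4, 2, 2] == pytest.approx(3.0)


def _random_proposal(lat, rng, order):
    offs = neighbour_offsets(order, 3)
    while True:
        t = tuple(int(rng.integers(0, d)) for d in lat.dims)
        s = tuple(np.array(t) + offs[rng.integers(0, len(offs))])
        if all(0 <= c < d for c, d in zip(s, lat.dims)) and lat.spin[t] != lat.spin[s]:
            return s, t


@given(st.integers(0, 60))
def test_delta_hamiltonian_matches_from_scratch(case_seed):
    """dH from the incremental form equals H(after) - H(before), and the
    reverse proposal has exactly -dH (no chemotaxis, static fields)."""
    lat, cells, _ = random_soup(dims=(5, 5, 4), n_cells=3, seed=case_seed)
    params = PottsParams(contact_table=flat_contact_table(2.5),
                         lambda_volume=1.3, lambda_surface=0.7,
                         neighbour_order=3)
    rng = np.random.default_rng(case_seed + 1000)
    for _ in range(5):
        s, t = _random_proposal(lat, rng, 3)
        h0 = total_hamiltonian(lat, cells, params)
        dh = delta_hamiltonian(lat, cells, params, None, s, t)
        old = lat.spin[t]
        lat.spin[t] = lat.spin[s]
        recompute_geometry(lat, cells)
        h1 = total_hamiltonian(lat, cells, params)
        assert dh == pytest.approx(h1 - h0, rel=1e-9, abs=1e-9)
        # reverse the copy via a neighbouring site still carrying `old`
        lat.spin[s] = old
        recompute_geometry(lat, cells)
        if lat.spin[t] != old:
            dh_rev = delta_hamiltonian(lat, cells, params, None, s, t)
            h2 = total_hamiltonian(lat, cells, params)
            lat.spin[t] = old
            recompute_geometry(lat, cells)
            assert dh_rev == pytest.approx(
                total_hamiltonian(lat, cells, params) - h2, rel=1e-9, abs=1e-9)


def test_kernel_delta_matches_reference_implementation(potts_params):
    """The njit sweep computes the same dH as the pure-python energy module."""
    chemo = ChemotaxisSpec(kind="linear", origin=(0, 0, 0), axis=(1, 0, 0),
                           slope=0.8, coefficient={"HighBetaCat": 5.0})
    lat, cells, _ = random_soup(dims=(6, 5, 4), n_cells=4, seed=21)
    field = chemo.build_field(lat.dims)
    mu = chemo.mu_array(potts_params.type_names)
    offs = neighbour_offsets(potts_params.neighbour_order, 3)
    rng = RandomStream(77)
    checked = 0
    for _ in range(400):
        snap_spin = lat.spin.copy()
        out = _kernels.run_mcs_kernel(
            lat.spin, cells.ctype, cells.volume, cells.surface, cells.tvol,
            cells.tsurf, cells.cx, cells.cy, cells.cz, cells.alive,
            potts_params.j_matrix(), potts_params.lambda_v_array(),
            potts_params.lambda_s_array(), mu, field, True, offs,
            potts_params.temperature, rng.state, 1)
        (_, _, _, _, dh, acc, kind, tx, ty, tz, sx, sy, sz) = out
        if kind != 0:
            continue
        lat_snap = PixelLattice(lat.dims, spin=snap_spin)
        snap_cells = CellTable()
        # rebuild a matching cell table on the snapshot
        for cid in range(1, cells.max_id + 1):
            snap_cells.new_cell(int(cells.ctype[cid]))
        recompute_geometry(lat_snap, snap_cells)
        snap_cells.tvol[:] = cells.tvol[: snap_cells.capacity]
        snap_cells.tsurf[:] = cells.tsurf[: snap_cells.capacity]
        ref = delta_hamiltonian(lat_snap, snap_cells, potts_params, chemo,
                                (sx, sy, sz), (tx, ty, tz))
        assert dh == pytest.approx(ref, rel=1e-9, abs=1e-9)
        checked += 1
    assert checked > 50
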
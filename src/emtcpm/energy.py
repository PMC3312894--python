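"""The effective energy (Hamiltonian) of the cell pattern.

H = sum_links J(tau, tau') * (1 - delta(sigma, sigma'))
  + sum_cells lambda_v (v - Vt)^2
  + sum_cells lambda_s (s - St)^2
plus a chemotaxis bias that only exists as a per-copy energy change (a
"quasi energy"): positive coefficient biases motion up the gradient.

These are reference (from-scratch) forms; the Metropolis kernel maintains the
same quantities incrementally, and the agreement of the two routes is a core
correctness check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .lattice import CellRecord, CellTable, PixelLattice, PottsParams, neighbour_offsets

__all__ = [
    "ChemotaxisSpec",
    "total_contact_energy",
    "volume_energy",
    "surface_energy",
    "total_hamiltonian",
    "chemotaxis_delta",
    "delta_hamiltonian",
]


@dataclass
class ChemotaxisSpec:
    """Static analytic chemoattractant field and per-type bias strengths.

    kind 'linear': c(x) = slope * dot(x - origin, axis-unit-vector)
    kind 'radial': c(x) = slope * |x - origin|  (increasing outwardly)
    ``coefficient`` maps type name -> mu; types absent from the map do not
    respond.  kind 'none' contributes exactly zero.
    """

    kind: str = "none"
    origin: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (0.0, 1.0, 0.0)
    slope: float = 0.0
    coefficient: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("none", "linear", "radial"):
            raise ConfigurationError(f"unknown chemotaxis field kind {self.kind!r}")

    def concentration(self, site) -> float:
        p = np.asarray(site, dtype=float)
        if self.kind == "none":
            return 0.0
        d = p - np.asarray(self.origin, dtype=float)
        if self.kind == "linear":
            ax = np.asarray(self.axis, dtype=float)
            ax = ax / np.linalg.norm(ax)
            return float(self.slope * d @ ax)
        return float(self.slope * np.linalg.norm(d))

    def build_field(self, dims) -> np.ndarray | None:
        """Precompute c(x) on the lattice; None for kind 'none'."""
        if self.kind == "none":
            return None
        xs, ys, zs = np.indices(dims).astype(float)
        d = np.stack([xs - self.origin[0], ys - self.origin[1], zs - self.origin[2]])
        if self.kind == "linear":
            ax = np.asarray(self.axis, dtype=float)
            ax = ax / np.linalg.norm(ax)
            return self.slope * np.einsum("i,ixyz->xyz", ax, d)
        return self.slope * np.sqrt((d ** 2).sum(axis=0))

    def mu_array(self, type_names) -> np.ndarray:
        return np.array([float(self.coefficient.get(t, 0.0)) for t in type_names])


def total_contact_energy(lattice: PixelLattice, cells: CellTable,
                         contact_table_or_params, neighbour_order: int = 4) -> float:
    """Adhesion energy summed over all neighbour links joining distinct cells.

    Each unordered link is counted once; same-cell links contribute nothing
    (the Kronecker-delta factor).
    """
    if isinstance(contact_table_or_params, PottsParams):
        params = contact_table_or_params
    else:
        params = PottsParams(contact_table=contact_table_or_params)
    jm = params.j_matrix()
    spin = lattice.spin
    tmap = cells.ctype
    offsets = neighbour_offsets(neighbour_order, 3)
    # keep one representative of each +/- offset pair
    half = [o for o in offsets if tuple(o) > (0, 0, 0)]
    total = 0.0
    nx, ny, nz = spin.shape
    for ox, oy, oz in half:
        xs = slice(max(0, -ox), min(nx, nx - ox))
        ys = slice(max(0, -oy), min(ny, ny - oy))
        zs = slice(max(0, -oz), min(nz, nz - oz))
        a = spin[xs, ys, zs]
        b = spin[xs.start + ox: xs.stop + ox,
                 ys.start + oy: ys.stop + oy,
                 zs.start + oz: zs.stop + oz]
        mask = a != b
        total += jm[tmap[a[mask]], tmap[b[mask]]].sum()
    return float(total)


def volume_energy(cell: CellRecord, lambda_volume: float) -> float:
    """lambda_v (v - Vt)^2; the medium (id 0) is exempt."""
    if cell.id == 0:
        return 0.0
    return float(lambda_volume) * (cell.volume - cell.target_volume) ** 2


def surface_energy(cell: CellRecord, lambda_surface: float) -> float:
    """lambda_s (s - St)^2; the medium (id 0) is exempt."""
    if cell.id == 0:
        return 0.0
    return float(lambda_surface) * (cell.surface - cell.target_surface) ** 2


def total_hamiltonian(lattice, cells, params: PottsParams) -> float:
    """From-scratch total effective energy (chemotaxis excluded: it is defined
    only as a per-copy bias)."""
    h = total_contact_energy(lattice, cells, params, params.neighbour_order)
    for rec in cells.records():
        h += volume_energy(rec, params.lambda_volume)
        h += surface_energy(rec, params.lambda_surface)
    return h


def chemotaxis_delta(spec: ChemotaxisSpec, source_site, target_site,
                     cell_type: str) -> float:
    """Chemotaxis energy change for a copy extending ``cell_type`` into the
    target site: -mu * (c(target) - c(source)). Positive mu favours copies
    that advance the cell up the concentration gradient."""
    if spec is None or spec.kind == "none":
        return 0.0
    mu = float(spec.coefficient.get(cell_type, 0.0))
    if mu == 0.0:
        return 0.0
    return -mu * (spec.concentration(target_site) - spec.concentration(source_site))


def delta_hamiltonian(lattice, cells, params: PottsParams, chemo,
                      source_site, target_site) -> float:
    """Exact energy change if the source index is copied onto the target site.

    Reference implementation touching only the affected links and cells; the
    Metropolis kernel computes the same quantity inline.
    """
    spin = lattice.spin
    nx, ny, nz = spin.shape
    tx, ty, tz = target_site
    sx, sy, sz = source_site
    a = int(spin[tx, ty, tz])
    b = int(spin[sx, sy, sz])
    if a == b:
        raise ConfigurationError("source and target carry the same index")
    jm = params.j_matrix()
    tmap = cells.ctype
    ta, tb = int(tmap[a]), int(tmap[b])

    dh = 0.0
    for ox, oy, oz in neighbour_offsets(params.neighbour_order, 3):
        jx, jy, jz = tx + ox, ty + oy, tz + oz
        if not (0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz):
            continue
        sj = int(spin[jx, jy, jz])
        tj = int(tmap[sj])
        if sj != b:
            dh += jm[tb, tj]
        if sj != a:
            dh -= jm[ta, tj]

    lam_v = params.lambda_v_array()
    lam_s = params.lambda_s_array()
    if a != 0:
        va, tva = cells.volume[a], cells.tvol[a]
        dh += lam_v[ta] * ((va - 1 - tva) ** 2 - (va - tva) ** 2)
    if b != 0:
        vb, tvb = cells.volume[b], cells.tvol[b]
        dh += lam_v[tb] * ((vb + 1 - tvb) ** 2 - (vb - tvb) ** 2)

    n_in_a = n_in_b = n_tot = 0
    for ox, oy, oz in neighbour_offsets(1, 3):
        jx, jy, jz = tx + ox, ty + oy, tz + oz
        if not (0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz):
            continue
        n_tot += 1
        sj = int(spin[jx, jy, jz])
        if sj == a:
            n_in_a += 1
        elif sj == b:
            n_in_b += 1
    ds_a = 2 * n_in_a - n_tot
    ds_b = n_tot - 2 * n_in_b
    if a != 0:
        sa, tsa = cells.surface[a], cells.tsurf[a]
        dh += lam_s[ta] * ((sa + ds_a - tsa) ** 2 - (sa - tsa) ** 2)
    if b != 0:
        sb, tsb = cells.surface[b], cells.tsurf[b]
        dh += lam_s[tb] * ((sb + ds_b - tsb) ** 2 - (sb - tsb) ** 2)

    if chemo is not None and chemo.kind != "none":
        names = params.type_names
        dh += chemotaxis_delta(chemo, source_site, target_site, names[tb])
        dh -= chemotaxis_delta(chemo, source_site, target_site, names[ta])
    return float(dh)
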
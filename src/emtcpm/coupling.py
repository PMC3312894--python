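"""Bidirectional coupling between the lattice and the per-cell networks.

Contact-fraction measurement feeds the kinetics (translocation forcing);
free beta-catenin crossing the threshold switches the cell's adhesive type
and kinetic branch (EMT), and the reverse crossing restores it (MET).
This module also carries the trigger schedule, growth/division rules and the
removal-based invasion assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import ConfigurationError, InvalidParameterError
from .kinetics import PARAM_NAMES
from .lattice import CellRecord, CellTable, PixelLattice, RandomStream

_P = {name: i for i, name in enumerate(PARAM_NAMES)}

LOW_TYPE = "LowBetaCat"
HIGH_TYPE = "HighBetaCat"

__all__ = [
    "ContactMap",
    "ScheduleConfig",
    "measure_contact_map",
    "update_contact_fractions",
    "update_cell_mode",
    "apply_threshold_switches",
    "apply_trigger",
    "grow_cells",
    "maybe_divide",
    "remove_distant_cells",
]


@dataclass
class ContactMap:
    """Shared boundary links per cell pair plus per-cell contact fraction g.

    g = (links shared with other non-medium cells) / (cell surface links);
    contact with the medium is excluded from the numerator.
    """

    links: dict            # cell id -> {neighbour id -> shared link count}
    total_contact_fraction: dict  # cell id -> g in [0, 1]


def measure_contact_map(lattice: PixelLattice, cells: CellTable) -> ContactMap:
    """Count first-neighbour links between distinct non-medium cells."""
    spin = lattice.spin
    nx, ny, nz = spin.shape
    links: dict[int, dict[int, int]] = {int(c): {} for c in cells.live_ids()}
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        a = spin[tuple(sl_a)].ravel()
        b = spin[tuple(sl_b)].ravel()
        mask = (a != b) & (a != 0) & (b != 0)
        for p, q in zip(a[mask], b[mask]):
            p, q = int(p), int(q)
            links[p][q] = links[p].get(q, 0) + 1
            links[q][p] = links[q].get(p, 0) + 1
    g = {}
    for cid, nb in links.items():
        surf = int(cells.surface[cid])
        g[cid] = (sum(nb.values()) / surf) if surf > 0 else 0.0
    return ContactMap(links=links, total_contact_fraction=g)


def update_contact_fractions(lattice: PixelLattice, cells: CellTable) -> None:
    """Fast path: roll g_now into g_prev and measure the new g for all cells."""
    boundary, contact = _kernels.contact_counts_kernel(lattice.spin, cells.capacity)
    n = cells.max_id + 1
    cells.g_prev[:n] = cells.g_now[:n]
    surf = boundary[:n]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(surf > 0, contact[:n] / np.maximum(surf, 1), 0.0)
    g[0] = 0.0
    cells.g_now[:n] = g


@dataclass
class ScheduleConfig:
    """When the networks start integrating and when EMT is induced.

    The trigger lowers every cell's beta-catenin--proteasome binding rate
    (kappa) from ``kappa_before`` to ``kappa_after`` at ``trigger_mcs``.
    """

    integration_start_mcs: int = 20
    trigger_mcs: int = 70
    kappa_before: float = 5.0
    kappa_after: float = 1.0
    check_cadence: int = 1

    def __post_init__(self):
        if self.integration_start_mcs > self.trigger_mcs:
            raise ConfigurationError(
                "integration must start at or before the trigger MCS")
        if self.check_cadence < 1:
            raise ConfigurationError("check_cadence must be >= 1")


def apply_trigger(schedule: ScheduleConfig, mcs: int,
                  param_rows: np.ndarray) -> bool:
    """Set kappa on every instance row: kappa_before strictly before the
    trigger MCS, kappa_after at and after it.  Returns True if rows changed."""
    kappa = schedule.kappa_after if mcs >= schedule.trigger_mcs else schedule.kappa_before
    col = param_rows[:, _P["kappa"]]
    if col.size and not np.all(col == kappa):
        param_rows[:, _P["kappa"]] = kappa
        return True
    return False


def _switch_rows(param_rows, rows, detached: bool):
    param_rows[rows, _P["phi_gate"]] = 0.0 if detached else 1.0
    param_rows[rows, _P["psi_gate"]] = 1.0 if detached else 0.0


def apply_threshold_switches(cells: CellTable, cell_ids: np.ndarray,
                             states: np.ndarray, param_rows: np.ndarray,
                             type_low: int, type_high: int):
    """Vectorised EMT/MET check for all instances after an integration step.

    Strict comparisons: a cell exactly at threshold keeps its mode.  Returns
    (emt_ids, met_ids).
    """
    b = states[:, 1]
    thr = param_rows[:, _P["beta_thr"]]
    detached = cells.mode_detached[cell_ids].astype(bool)
    up = (b > thr) & ~detached
    down = (b < thr) & detached
    emt_ids = cell_ids[up]
    met_ids = cell_ids[down]
    if emt_ids.size:
        cells.mode_detached[emt_ids] = 1
        cells.ctype[emt_ids] = type_high
        _switch_rows(param_rows, np.nonzero(up)[0], detached=True)
    if met_ids.size:
        cells.mode_detached[met_ids] = 0
        cells.ctype[met_ids] = type_low
        _switch_rows(param_rows, np.nonzero(down)[0], detached=False)
    return emt_ids, met_ids


def update_cell_mode(cell: CellRecord, state, params,
                     type_low: int = 1, type_high: int = 2) -> str | None:
    """Per-cell EMT/MET switch, called once per cell per MCS after integration.

    If free beta-catenin strictly exceeds the threshold while attached the
    cell detaches (type -> HighBetaCat, detached kinetic branch); strictly
    below the threshold while detached it re-attaches (MET).  A cell exactly
    at threshold keeps its mode.  Returns 'emt', 'met' or None; the switch is
    idempotent within an MCS.
    """
    b = state.bcat_free
    thr = params.threshold_beta
    if cell.mode == "attached" and b > thr:
        cell.mode = "detached"
        state.mode = "detached"
        cell.type = type_high
        return "emt"
    if cell.mode == "detached" and b < thr:
        cell.mode = "attached"
        state.mode = "attached"
        cell.type = type_low
        return "met"
    return None


def grow_cells(cells: CellTable, volume_rate: float, surface_rate: float,
               growing_ids=None) -> None:
    """Increment growth targets at constant fractional rates of the current
    volume/surface: Vt += r_v * v, St += r_s * s, once per MCS."""
    if volume_rate < 0 or surface_rate < 0:
        raise InvalidParameterError("growth rates must be non-negative")
    ids = cells.live_ids() if growing_ids is None else np.asarray(growing_ids)
    cells.tvol[ids] += volume_rate * cells.volume[ids]
    cells.tsurf[ids] += surface_rate * cells.surface[ids]


def maybe_divide(lattice: PixelLattice, cells: CellTable, cell: CellRecord,
                 division_multiple: float, rng: RandomStream,
                 max_retries: int = 16) -> CellRecord | None:
    """Split the cell by a random plane through its centroid once its volume
    exceeds ``division_multiple`` times its volume at creation.

    Both halves get half the parent's pre-division targets; the caller copies
    the parent's network state to the child.
    """
    if division_multiple <= 1:
        raise InvalidParameterError("division_multiple must be > 1")
    if cell.volume <= division_multiple * cell.initial_volume:
        return None
    coords = np.argwhere(lattice.spin == cell.id)
    centroid = cell.centroid
    for _ in range(max_retries):
        normal = rng.unit_vector()
        side = (coords - centroid) @ normal >= 0.0
        n_child = int(side.sum())
        if 0 < n_child < coords.shape[0]:
            break
    else:
        raise RuntimeError(f"could not find a dividing plane for cell {cell.id}")

    child_id = cells.new_cell(cell.type)
    child_coords = coords[side]
    lattice.spin[tuple(child_coords.T)] = child_id

    tv, ts = cell.target_volume, cell.target_surface
    for rec, pix in ((cell, coords[~side]), (cells.record(child_id), child_coords)):
        rec.target_volume = tv / 2.0
        rec.target_surface = ts / 2.0
        cells.volume[rec.id] = pix.shape[0]
        sums = pix.sum(axis=0)
        cells.cx[rec.id], cells.cy[rec.id], cells.cz[rec.id] = sums
        cells.surface[rec.id] = _local_surface(lattice.spin, pix, rec.id)
    child = cells.record(child_id)
    child.initial_volume = child.volume
    child.mode = cell.mode
    cells.g_now[child_id] = cells.g_now[cell.id]
    cells.g_prev[child_id] = cells.g_now[child_id]
    return child


def _local_surface(spin, coords, cid) -> int:
    nx, ny, nz = spin.shape
    s = 0
    for x, y, z in coords:
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            jx, jy, jz = x + dx, y + dy, z + dz
            if 0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz:
                if spin[jx, jy, jz] != cid:
                    s += 1
    return s


def remove_distant_cells(lattice: PixelLattice, cells: CellTable,
                         origin_spec, distance_threshold: float,
                         dispose=None) -> list[int]:
    """Delete every cell whose centroid lies beyond the threshold distance.

    ``origin_spec`` is ``("plane", axis, coordinate)`` (distance measured
    normal to the initial layer plane) or ``("point", (x, y, z))`` (radial
    distance from the lattice centre for spheroids).  Removed pixels revert
    to medium; ``dispose(cell_id)`` lets the caller drop network instances.
    """
    kind = origin_spec[0]
    removed = []
    for cid in cells.live_ids():
        c = np.array([cells.cx[cid], cells.cy[cid], cells.cz[cid]])
        c = c / max(cells.volume[cid], 1)
        if kind == "plane":
            _, axis, coord = origin_spec
            dist = abs(c[axis] - coord)
        elif kind == "point":
            dist = float(np.linalg.norm(c - np.asarray(origin_spec[1], float)))
        else:
            raise ConfigurationError(f"unknown origin spec {origin_spec!r}")
        if dist > distance_threshold:
            removed.append(int(cid))
    for cid in removed:
        lattice.spin[lattice.spin == cid] = 0
        cells.alive[cid] = 0
        cells.volume[cid] = 0
        cells.surface[cid] = 0
        if dispose is not None:
            dispose(cid)
    return removed
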
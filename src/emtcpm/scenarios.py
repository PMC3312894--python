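"""Runnable experiment drivers and their analysis reductions.

Three scenarios: ``layer_waves`` (detachment waves in an epithelial sheet),
``tumour_layer`` (tumour grown from a cell layer with a linear
chemoattractant gradient and a removal-based invasion assay) and ``mts``
(multicellular tumour spheroid grown from one central cell with a radial
gradient).  Each MCS: Potts sweep -> contact measurement -> network forcing,
integration and threshold checks -> trigger/growth/division/removal ->
logging.  A run is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coupling, registry as registry_mod
from .config import ScenarioConfig
from .coupling import apply_threshold_switches, apply_trigger, grow_cells, \
    maybe_divide, remove_distant_cells, update_contact_fractions
from .errors import ConfigurationError
from .kinetics import PARAM_NAMES
from .lattice import CellTable, PixelLattice, RandomStream, recompute_geometry, run_mcs

_P = {name: i for i, name in enumerate(PARAM_NAMES)}

MODEL_NAME = "EcadBcatKinetics"
MODEL_KEY = "SM"
TYPE_LOW, TYPE_HIGH = 1, 2

__all__ = [
    "TimeSeriesLog",
    "build_initial_condition",
    "run_scenario",
    "invasion_curve",
    "radius_trace",
    "run_invasion_sweep",
]


@dataclass
class TimeSeriesLog:
    """Per-cell time series, the structured event log and run metadata."""

    cells: pd.DataFrame     # mcs,id,type,mode,volume,surface,cx,cy,cz,g,Ecad,Bcat,Complex,BcatPro
    events: pd.DataFrame    # mcs,event,cell_id,detail
    potts: pd.DataFrame     # mcs,attempts,acceptances,net_dh,energy_tracked
    manifest: dict

    def detached_fraction(self) -> pd.Series:
        grp = self.cells.groupby("mcs")["mode"]
        return grp.apply(lambda s: (s == "detached").mean())

    def removed_count(self) -> int:
        return int((self.events["event"] == "removal").sum())


def build_initial_condition(config: ScenarioConfig):
    """Deterministic initial placement of cube-shaped cells.

    Sheet scenarios: ``cells_x x cells_y x cells_z`` cubes of edge
    ``cell_edge`` with ``gap`` empty pixels between them.  MTS: a single cube
    at the lattice centre.
    """
    lattice = PixelLattice(config.lattice_dims, pixel_scale=config.pixel_scale)
    cells = CellTable(capacity=max(config.max_id_hint,
                                   config.cells_x * config.cells_y * config.cells_z + 2))
    e = config.cell_edge
    tv = config.target_volume_factor * e ** 3
    ts = config.target_surface_factor * 6 * e ** 2

    def add_cube(lo):
        cid = cells.new_cell(TYPE_LOW)
        x, y, z = lo
        lattice.spin[x: x + e, y: y + e, z: z + e] = cid
        return cid

    if config.scenario == "mts":
        lo = tuple((d - e) // 2 for d in config.lattice_dims)
        add_cube(lo)
    else:
        pitch = e + config.gap
        m = config.margin
        for i in range(config.cells_x):
            for j in range(config.cells_y):
                for k in range(config.cells_z):
                    lo = (m + i * pitch, m + j * pitch, m + k * pitch)
                    if any(l + e > d for l, d in zip(lo, config.lattice_dims)):
                        raise ConfigurationError("initial cell outside lattice")
                    add_cube(lo)
    recompute_geometry(lattice, cells)
    for cid in cells.live_ids():
        cells.tvol[cid] = tv
        cells.tsurf[cid] = ts
        cells.init_volume[cid] = cells.volume[cid]
    return lattice, cells


def _removal_origin(config: ScenarioConfig):
    if config.scenario == "mts":
        centre = tuple((d - 1) / 2.0 for d in config.lattice_dims)
        return ("point", centre)
    z0 = config.margin + config.cell_edge / 2.0
    return ("plane", config.layer_axis, z0)


def run_scenario(config: ScenarioConfig, seed: int | None = None,
                 on_mcs=None) -> TimeSeriesLog:
    """Run one full scenario; fully reproducible for a given (config, seed).

    ``on_mcs(mcs, lattice, cells, registry)``, if given, is called at the end
    of every MCS (snapshot hooks); it must not mutate the state.
    """
    seed = config.seed if seed is None else seed
    rng = RandomStream(seed)
    lattice, cells = build_initial_condition(config)

    reg = registry_mod.Registry()
    reg.load_model(MODEL_NAME, registry_mod.builtin_emt_model(config.kinetics),
                   MODEL_KEY)
    reg.add_model_to_template_library(MODEL_NAME, "LowBetaCat")
    reg.add_model_to_template_library(MODEL_NAME, "HighBetaCat")
    reg.initialize_networks(config.timestep, cells, config.potts.type_names)

    chemo = config.chemotaxis
    field = chemo.build_field(config.lattice_dims)
    mu = chemo.mu_array(config.potts.type_names)
    origin = _removal_origin(config)

    from .energy import total_hamiltonian
    energy = total_hamiltonian(lattice, cells, config.potts)

    cols = {k: [] for k in ("mcs", "id", "type", "mode", "volume", "surface",
                            "cx", "cy", "cz", "g", "Ecad", "Bcat", "Complex",
                            "BcatPro")}
    events = []
    potts_rows = []
    dt = config.timestep
    tnames = config.potts.type_names

    def log_event(mcs, name, cid=-1, detail=""):
        events.append((mcs, name, cid, detail))

    update_contact_fractions(lattice, cells)
    cells.g_prev[:] = cells.g_now[:]

    for mcs in range(1, config.mcs_total + 1):
        ids, states, params = reg.arrays_for(MODEL_NAME)
        if apply_trigger(config.schedule, mcs, params):
            log_event(mcs, "trigger", detail=f"kappa={config.schedule.kappa_after}")

        stats = run_mcs(lattice, cells, config.potts, rng,
                        chemo_field=field, mu_array=mu)
        energy += stats.net_delta_h - stats.net_delta_h_chemo

        # cells squeezed to zero volume die; drop their networks
        for cid in reg.live_instance_ids(MODEL_NAME):
            if not cells.alive[cid]:
                reg.dispose_cell(cid)
                log_event(mcs, "death", cid)

        update_contact_fractions(lattice, cells)

        if mcs >= config.schedule.integration_start_mcs:
            ids, states, params = reg.arrays_for(MODEL_NAME)
            r = (cells.g_now[ids] - cells.g_prev[ids]) / dt
            params[:, _P["Jplus"]] = params[:, _P["p_plus"]] * np.maximum(r, 0.0)
            params[:, _P["Jminus"]] = params[:, _P["p_minus"]] * np.maximum(-r, 0.0)
            reg.timestep_networks()
            emt_ids, met_ids = apply_threshold_switches(
                cells, ids, states, params, TYPE_LOW, TYPE_HIGH)
            for cid in emt_ids:
                log_event(mcs, "emt", int(cid))
            for cid in met_ids:
                log_event(mcs, "met", int(cid))

        # the population cap bounds the total number of cells ever created,
        # so the cumulative removed count can never exceed it
        if config.growth.enabled and cells.max_id < config.growth.max_cells:
            live = cells.live_ids()
            if not config.growth.grow_detached:
                live = live[cells.mode_detached[live] == 0]
            grow_cells(cells, config.growth.volume_rate,
                       config.growth.surface_rate, live)
            for cid in list(cells.live_ids()):
                if cells.max_id >= config.growth.max_cells:
                    break
                rec = cells.record(int(cid))
                child = maybe_divide(lattice, cells, rec,
                                     config.growth.division_multiple, rng)
                if child is not None:
                    reg.copy_from_parent(rec.id, child.id)
                    log_event(mcs, "division", rec.id, detail=str(child.id))

        if config.removal.enabled and mcs % config.removal.cadence == 0:
            removed = remove_distant_cells(lattice, cells, origin,
                                           config.removal.distance,
                                           dispose=reg.dispose_cell)
            for cid in removed:
                log_event(mcs, "removal", cid)
            if removed:
                from .energy import total_hamiltonian as _th
                energy = _th(lattice, cells, config.potts)

        potts_rows.append((mcs, stats.attempts, stats.acceptances,
                           stats.net_delta_h, energy))

        if on_mcs is not None:
            on_mcs(mcs, lattice, cells, reg)

        if mcs % config.log_every == 0:
            ids, states, _ = reg.arrays_for(MODEL_NAME)
            order = np.argsort(ids)
            ids_o = ids[order]
            st = states[order]
            n = ids_o.size
            vol = np.maximum(cells.volume[ids_o], 1)
            cols["mcs"].append(np.full(n, mcs))
            cols["id"].append(ids_o.copy())
            cols["type"].append(cells.ctype[ids_o].copy())
            cols["mode"].append(cells.mode_detached[ids_o].copy())
            cols["volume"].append(cells.volume[ids_o].copy())
            cols["surface"].append(cells.surface[ids_o].copy())
            cols["cx"].append(cells.cx[ids_o] / vol)
            cols["cy"].append(cells.cy[ids_o] / vol)
            cols["cz"].append(cells.cz[ids_o] / vol)
            cols["g"].append(cells.g_now[ids_o].copy())
            cols["Ecad"].append(st[:, 0].copy())
            cols["Bcat"].append(st[:, 1].copy())
            cols["Complex"].append(st[:, 2].copy())
            cols["BcatPro"].append(st[:, 3].copy())

    frames = {k: np.concatenate(v) if v else np.array([]) for k, v in cols.items()}
    cells_df = pd.DataFrame(frames)
    cells_df["type"] = [tnames[t] for t in cells_df["type"].astype(int)]
    cells_df["mode"] = np.where(cells_df["mode"].astype(bool), "detached", "attached")
    events_df = pd.DataFrame(events, columns=["mcs", "event", "cell_id", "detail"])
    potts_df = pd.DataFrame(potts_rows, columns=["mcs", "attempts", "acceptances",
                                                 "net_dh", "energy_tracked"])
    manifest = {
        "scenario": config.scenario,
        "seed": int(seed),
        "mcs_total": int(config.mcs_total),
        "lattice_dims": list(config.lattice_dims),
        "clip_events": int(reg.clip_events),
    }
    return TimeSeriesLog(cells=cells_df, events=events_df, potts=potts_df,
                         manifest=manifest)


# ----------------------------------------------------------------- analyses

def invasion_curve(log: TimeSeriesLog, mcs_total: int | None = None) -> pd.Series:
    """Cumulative removed-cell count vs MCS (non-decreasing step curve)."""
    total = mcs_total or log.manifest["mcs_total"]
    idx = pd.RangeIndex(0, total + 1, name="mcs")
    rem = log.events[log.events["event"] == "removal"]
    counts = rem.groupby("mcs").size().reindex(idx, fill_value=0)
    return counts.cumsum()


@dataclass
class RadiusTrace:
    series: pd.Series        # centroid distance vs MCS
    plateau: float           # estimated resident radius before detachment
    onset_mcs: int | None    # first sustained departure from the plateau


def radius_trace(log: TimeSeriesLog, cell_id: int, origin,
                 window: int = 51, onset_margin: float = 1.5) -> RadiusTrace:
    """Distance-from-origin trace for one cell with a plateau estimate.

    The plateau is read as the mean over the lowest-variance rolling window
    (extended to the surrounding low-variance region); the onset is the first
    later MCS at which the distance exceeds plateau + margin and stays there.
    """
    sub = log.cells[log.cells["id"] == cell_id]
    if sub.empty:
        raise ConfigurationError(f"cell {cell_id} never logged")
    if origin[0] == "plane":
        _, axis, coord = origin
        col = ("cx", "cy", "cz")[axis]
        d = (sub[col] - coord).abs()
    else:
        pt = np.asarray(origin[1], dtype=float)
        d = np.sqrt((sub["cx"] - pt[0]) ** 2 + (sub["cy"] - pt[1]) ** 2
                    + (sub["cz"] - pt[2]) ** 2)
    series = pd.Series(d.to_numpy(), index=sub["mcs"].to_numpy(), name="distance")
    return RadiusTrace(series, *_plateau(series, window, onset_margin))


def _plateau(series: pd.Series, window: int, onset_margin: float):
    """Plateau = mean over the last low-variance residence window; onset =
    first sustained exceedance of plateau + margin after that window."""
    vals = series.to_numpy(dtype=float)
    n = vals.size
    w = max(2, min(window, n))
    if n < 4:
        return float(vals.mean()), None
    roll = pd.Series(vals).rolling(w)
    std = roll.std().to_numpy()
    mean = roll.mean().to_numpy()
    valid = ~np.isnan(std)
    thr = np.quantile(std[valid], 0.3)
    low = valid & (std <= max(thr, 1e-12))
    # contiguous low-variance regions; keep the last one (the residence
    # closest to the final departure)
    idx = np.flatnonzero(low)
    if idx.size == 0:
        return float(np.nanmean(vals)), None
    breaks = np.flatnonzero(np.diff(idx) > 1)
    start = idx[breaks[-1] + 1] if breaks.size else idx[0]
    end = idx[-1]
    plateau = float(np.nanmean(mean[start: end + 1]))
    onset = None
    above = vals > plateau + onset_margin
    for i in range(end, n):
        if above[i] and above[i:].mean() > 0.9:
            onset = int(series.index[i])
            break
    return plateau, onset


def run_invasion_sweep(config_factory, nus, seeds, **overrides) -> pd.DataFrame:
    """Final removed-cell counts for a grid of degradation rates x seeds.

    ``config_factory`` is one of the scenario config factories; each run gets
    ``kinetics`` with the swept ``degradation_nu``.
    """
    from dataclasses import replace as drep

    rows = []
    for nu in nus:
        for seed in seeds:
            cfg = config_factory(**overrides)
            cfg.kinetics = drep(cfg.kinetics, degradation_nu=float(nu))
            log = run_scenario(cfg, seed=seed)
            rows.append({"nu": float(nu), "seed": int(seed),
                         "removed": log.removed_count(),
                         "scenario": cfg.scenario})
    return pd.DataFrame(rows)
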
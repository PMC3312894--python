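"""Template-library management of per-cell reaction networks.

Mirrors the workflow of coupling frameworks that bind reaction-kinetic models
to cell types: models are loaded once, added to named template libraries
(template name == cell type name), and at initialisation every live cell of a
templated type receives its own network instance.  Instances are stepped
together, addressed per cell as ``"<model key>_<variable>"``, and copied to
the child on mitosis.

Instance state lives in per-model arrays (one row per instance), so the
mitosis copy is a plain row copy and stepping is vectorised across cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import kinetics, sbml
from .errors import ConfigurationError, LifecycleError, ModelFormatError

ADDRESS_SEP = "_"

__all__ = ["ModelDefinition", "builtin_emt_model", "Registry", "ADDRESS_SEP"]


@dataclass
class ModelDefinition:
    """A reaction network: named species/parameters and a vectorised RHS."""

    species: tuple
    params: tuple
    species_defaults: dict
    param_defaults: dict
    rhs_fn: Callable  # (Y (n, ns), P (n, np)) -> dY
    source: str = "builtin"

    def __post_init__(self):
        overlap = set(self.species) & set(self.params)
        if overlap:
            raise ModelFormatError(
                f"names used both as species and parameter: {sorted(overlap)}")


def builtin_emt_model(params: kinetics.KineticParams | None = None) -> ModelDefinition:
    """The built-in E-cadherin/beta-catenin model as a registry model."""
    kp = params or kinetics.KineticParams()
    row = kp.to_param_row()
    return ModelDefinition(
        species=kinetics.SPECIES_NAMES,
        params=kinetics.PARAM_NAMES,
        species_defaults={"Ecad": kp.ecad_total_E0, "Bcat": 0.0,
                          "Complex": 0.0, "BcatPro": 0.0},
        param_defaults=dict(zip(kinetics.PARAM_NAMES, row)),
        rhs_fn=kinetics.rhs_vec,
        source="builtin",
    )


def model_from_sbml(path) -> ModelDefinition:
    """Build a mass-action ModelDefinition from an SBML-subset file."""
    desc = sbml.parse_sbml(path)
    species = tuple(s for s, _ in desc["species"])
    species_defaults = dict(desc["species"])
    params = [p for p, _ in desc["parameters"]]
    param_defaults = dict(desc["parameters"])
    for rx in desc["reactions"]:
        for pid, val in rx["local_parameters"]:
            if pid in param_defaults or pid in species_defaults:
                raise ModelFormatError(
                    f"local parameter '{pid}' shadows an existing name")
            params.append(pid)
            param_defaults[pid] = val
    params = tuple(params)
    sidx = {s: i for i, s in enumerate(species)}
    pidx = {p: i for i, p in enumerate(params)}

    n_s, n_r = len(species), len(desc["reactions"])
    stoich = np.zeros((n_r, n_s))
    factor_tbl = []
    for r, rx in enumerate(desc["reactions"]):
        for s, st in rx["reactants"]:
            stoich[r, sidx[s]] -= st
        for s, st in rx["products"]:
            stoich[r, sidx[s]] += st
        fl = []
        for kind, v in rx["factors"]:
            if kind == "const":
                fl.append(("c", float(v)))
            elif v in sidx:
                fl.append(("s", sidx[v]))
            elif v in pidx:
                fl.append(("p", pidx[v]))
            else:
                raise ModelFormatError(
                    f"kinetic law of '{rx['id']}' references unknown name '{v}'")
        factor_tbl.append(fl)

    def rhs_fn(Y, P):
        n = Y.shape[0]
        rates = np.ones((n, n_r))
        for r, fl in enumerate(factor_tbl):
            for kind, v in fl:
                if kind == "s":
                    rates[:, r] *= Y[:, v]
                elif kind == "p":
                    rates[:, r] *= P[:, v]
                else:
                    rates[:, r] *= v
        return rates @ stoich

    return ModelDefinition(species=species, params=params,
                           species_defaults=species_defaults,
                           param_defaults=param_defaults,
                           rhs_fn=rhs_fn, source=str(path))


class _Instances:
    """Per-model instance arrays; one row per cell instance."""

    def __init__(self, model: ModelDefinition, capacity: int = 64):
        self.model = model
        self.states = np.zeros((capacity, len(model.species)))
        self.params = np.zeros((capacity, len(model.params)))
        self.rows: dict[int, int] = {}
        self.ids = np.zeros(capacity, dtype=np.int64)
        self.n = 0

    def _grow(self):
        for name in ("states", "params"):
            arr = getattr(self, name)
            new = np.zeros((arr.shape[0] * 2, arr.shape[1]))
            new[: arr.shape[0]] = arr
            setattr(self, name, new)
        ids = np.zeros(self.ids.shape[0] * 2, dtype=np.int64)
        ids[: self.ids.shape[0]] = self.ids
        self.ids = ids

    def add(self, cell_id: int, state_row, param_row) -> int:
        if self.n >= self.states.shape[0]:
            self._grow()
        r = self.n
        self.n += 1
        self.states[r] = state_row
        self.params[r] = param_row
        self.rows[cell_id] = r
        self.ids[r] = cell_id
        return r

    def drop(self, cell_id: int):
        r = self.rows.pop(cell_id)
        last = self.n - 1
        if r != last:
            self.states[r] = self.states[last]
            self.params[r] = self.params[last]
            moved = int(self.ids[last])
            self.ids[r] = moved
            self.rows[moved] = r
        self.n = last


class Registry:
    """Named models, type-keyed template libraries and per-cell instances."""

    def __init__(self):
        self.models: dict[str, ModelDefinition] = {}
        self.keys: dict[str, str] = {}  # key -> model name
        self.templates: dict[str, dict] = {}
        self._inst: dict[str, _Instances] = {}
        self.dt: float | None = None
        self.initialized = False
        self.clip_events = 0

    # ------------------------------------------------------------------ load
    def load_model(self, name: str, source, key: str) -> ModelDefinition:
        """Register a model under ``name`` with addressing ``key``.

        ``source`` is a :class:`ModelDefinition` or a path to an SBML-subset
        file.  Re-registering an existing name replaces it with a warning.
        """
        if isinstance(source, ModelDefinition):
            model = source
        elif isinstance(source, (str, Path)):
            model = model_from_sbml(source)
        else:
            raise ModelFormatError(f"unsupported model source {type(source)!r}")
        if key in self.keys and self.keys[key] != name:
            raise ConfigurationError(
                f"model key '{key}' already addresses model '{self.keys[key]}'")
        if name in self.models:
            warnings.warn(f"model '{name}' re-registered; replacing", stacklevel=2)
            old_key = next(k for k, v in self.keys.items() if v == name)
            del self.keys[old_key]
        self.models[name] = model
        self.keys[key] = name
        return model

    def add_model_to_template_library(self, model_name: str, template_name: str):
        if model_name not in self.models:
            raise LookupError(f"unknown model '{model_name}'")
        tpl = self.templates.setdefault(template_name, {"models": [], "ic": {}})
        if model_name not in tpl["models"]:
            tpl["models"].append(model_name)

    # -------------------------------------------------------------- address
    def _resolve(self, address: str, model_names=None):
        """Return (model_name, kind, index) for '<key>_<variable>'."""
        names = model_names if model_names is not None else list(self.models)
        cands = []
        for key, mname in self.keys.items():
            if mname not in names:
                continue
            prefix = key + ADDRESS_SEP
            if address.startswith(prefix):
                var = address[len(prefix):]
                model = self.models[mname]
                if var in model.species:
                    cands.append((mname, "species", model.species.index(var)))
                elif var in model.params:
                    cands.append((mname, "param", model.params.index(var)))
        if len(cands) == 1:
            return cands[0]
        if not cands:
            options = sorted(
                f"{k}{ADDRESS_SEP}{v}"
                for k, m in self.keys.items() if m in names
                for v in (*self.models[m].species, *self.models[m].params))
            raise LookupError(
                f"cannot resolve address '{address}'; candidates: {options}")
        raise ConfigurationError(f"ambiguous address '{address}'")

    def set_initial_condition(self, template: str, address: str, value: float):
        """Store an override applied to every instance created for ``template``."""
        if template not in self.templates:
            raise LookupError(f"unknown template '{template}'")
        mname, kind, idx = self._resolve(address, self.templates[template]["models"])
        self.templates[template]["ic"][(mname, kind, idx)] = float(value)

    # ------------------------------------------------------------ lifecycle
    def _instance_for(self, template: str, model_name: str, cell_id: int):
        model = self.models[model_name]
        inst = self._inst.setdefault(model_name, _Instances(model))
        srow = np.array([model.species_defaults.get(s, 0.0) for s in model.species])
        prow = np.array([model.param_defaults.get(p, 0.0) for p in model.params])
        for (mn, kind, idx), val in self.templates[template]["ic"].items():
            if mn != model_name:
                continue
            if kind == "species":
                srow[idx] = val
            else:
                prow[idx] = val
        inst.add(cell_id, srow, prow)

    def create_cell_networks(self, cell_id: int, type_name: str):
        """Instantiate every template model for one (new) cell."""
        tpl = self.templates.get(type_name)
        if tpl is None:
            return
        for mname in tpl["models"]:
            inst = self._inst.get(mname)
            if inst is not None and cell_id in inst.rows:
                continue
            self._instance_for(type_name, mname, cell_id)

    def initialize_networks(self, dt: float, cells=None, type_names=None):
        """Create one instance per templated live cell; set the timestep."""
        if dt <= 0:
            raise ConfigurationError("timestep must be positive")
        self.dt = float(dt)
        if cells is not None:
            if type_names is None:
                raise ConfigurationError("type_names required with cells")
            for cid in cells.live_ids():
                self.create_cell_networks(int(cid), type_names[cells.ctype[cid]])
        self.initialized = True

    def timestep_networks(self):
        """Advance every instance of every model by the registry timestep."""
        if not self.initialized:
            raise LifecycleError("timestep_networks called before initialisation")
        for inst in self._inst.values():
            n = inst.n
            if n == 0:
                continue
            y, clips = kinetics.integrate_states(
                inst.states[:n], inst.params[:n], self.dt,
                rhs_fn=inst.model.rhs_fn, cell_ids=inst.ids[:n])
            inst.states[:n] = y
            self.clip_events += clips

    # ------------------------------------------------------------- accessors
    def _locate(self, address: str, cell_id: int):
        mname, kind, idx = self._resolve(address)
        inst = self._inst.get(mname)
        if inst is None or cell_id not in inst.rows:
            raise LookupError(f"cell {cell_id} has no instance of model '{mname}'")
        return inst, inst.rows[cell_id], kind, idx

    def get_value(self, address: str, cell_id: int) -> float:
        inst, row, kind, idx = self._locate(address, cell_id)
        arr = inst.states if kind == "species" else inst.params
        return float(arr[row, idx])

    def set_value(self, address: str, value: float, cell_id: int):
        inst, row, kind, idx = self._locate(address, cell_id)
        arr = inst.states if kind == "species" else inst.params
        arr[row, idx] = value

    def set_value_for_all(self, address: str, value: float):
        """Library-wide parameter change (e.g. the kappa trigger)."""
        mname, kind, idx = self._resolve(address)
        inst = self._inst.get(mname)
        if inst is None:
            return
        arr = inst.states if kind == "species" else inst.params
        arr[: inst.n, idx] = value

    def copy_from_parent(self, parent_id: int, child_id: int):
        """Duplicate the parent's full integrator state for the child."""
        found = False
        for inst in self._inst.values():
            if parent_id in inst.rows:
                r = inst.rows[parent_id]
                inst.add(child_id, inst.states[r].copy(), inst.params[r].copy())
                found = True
        if not found:
            raise LookupError(f"parent cell {parent_id} has no network instances")

    def dispose_cell(self, cell_id: int):
        for inst in self._inst.values():
            if cell_id in inst.rows:
                inst.drop(cell_id)

    def instance_count(self) -> int:
        return sum(inst.n for inst in self._inst.values())

    def arrays_for(self, model_name: str):
        """(cell_ids, states, params) views for vectorised coupling code."""
        inst = self._inst.get(model_name)
        if inst is None:
            model = self.models[model_name]
            return (np.zeros(0, dtype=np.int64),
                    np.zeros((0, len(model.species))),
                    np.zeros((0, len(model.params))))
        return inst.ids[: inst.n], inst.states[: inst.n], inst.params[: inst.n]

    def live_instance_ids(self, model_name: str):
        inst = self._inst.get(model_name)
        return list(inst.rows) if inst is not None else []
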
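"""Scenario configuration: geometry, schedule, growth, chemotaxis, output.

Configs are plain dataclasses with YAML round-tripping.  The three scenario
factories hold the package's standard desk-scale conditions; every value can
be overridden from a config file or keyword overrides.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .coupling import ScheduleConfig
from .energy import ChemotaxisSpec
from .errors import ConfigurationError
from .kinetics import KineticParams
from .lattice import PottsParams

SCENARIOS = ("layer_waves", "tumour_layer", "mts")

DEFAULT_CONTACT_TABLE = {
    ("Medium", "LowBetaCat"): 8.0,
    ("Medium", "HighBetaCat"): 4.0,
    ("Medium", "Medium"): 0.0,
    ("LowBetaCat", "LowBetaCat"): 3.0,
    ("LowBetaCat", "HighBetaCat"): 14.0,
    ("HighBetaCat", "HighBetaCat"): 14.0,
}


@dataclass
class GrowthConfig:
    enabled: bool = False
    volume_rate: float = 0.02       # Vt += rate * v per MCS during growth
    surface_rate: float = 0.0133    # St += rate * s per MCS
    division_multiple: float = 2.0  # divide when v > multiple * initial volume
    max_cells: int = 40             # population cap; growth/division stop here
    grow_detached: bool = False     # growth restricted to attached cells


@dataclass
class RemovalConfig:
    enabled: bool = False
    distance: float = 12.0
    cadence: int = 5


@dataclass
class ScenarioConfig:
    scenario: str = "layer_waves"
    lattice_dims: tuple = (64, 64, 10)
    cells_x: int = 10
    cells_y: int = 10
    cells_z: int = 1
    cell_edge: int = 5
    gap: int = 1
    margin: int = 2                  # empty border between sheet and lattice edge
    layer_axis: int = 2              # layer normal (z)
    pixel_scale: float = 1.0
    target_volume_factor: float = 1.728   # cube edge 5 -> confluent volume 216
    target_surface_factor: float = 1.44   # cube surface 150 -> 216
    timestep: float = 0.03           # dimensionless network time per MCS
    mcs_total: int = 600
    log_every: int = 1
    seed: int = 1
    max_id_hint: int = 64
    potts: PottsParams = field(default_factory=lambda: PottsParams(
        contact_table=dict(DEFAULT_CONTACT_TABLE)))
    kinetics: KineticParams = field(default_factory=KineticParams)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    removal: RemovalConfig = field(default_factory=RemovalConfig)
    chemotaxis: ChemotaxisSpec = field(default_factory=ChemotaxisSpec)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario '{self.scenario}'")
        self.lattice_dims = tuple(int(d) for d in self.lattice_dims)
        pitch = self.cell_edge + self.gap
        if self.scenario == "mts":
            if any(self.cell_edge + 2 > d for d in self.lattice_dims):
                raise ConfigurationError("central cell does not fit the lattice")
        else:
            need = (self.cells_x * pitch + self.margin,
                    self.cells_y * pitch + self.margin,
                    self.cells_z * pitch + self.margin)
            if any(n > d for n, d in zip(need, self.lattice_dims)):
                raise ConfigurationError(
                    f"cell sheet {need} does not fit lattice {self.lattice_dims} "
                    f"with gap {self.gap}")
        # the trigger lowers kappa; instances start from kappa_before
        self.kinetics = replace(self.kinetics,
                                binding_bcat_proteasome=self.schedule.kappa_before)

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = asdict(self)
        d["potts"]["contact_table"] = {
            f"{a}|{b}": v for (a, b), v in self.potts.contact_table.items()}
        d["potts"]["type_names"] = list(self.potts.type_names)
        d["chemotaxis"]["coefficient"] = dict(self.chemotaxis.coefficient)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "potts" in d:
            p = dict(d["potts"])
            if "contact_table" in p:
                p["contact_table"] = {
                    tuple(k.split("|")): float(v)
                    for k, v in p["contact_table"].items()}
            if "type_names" in p:
                p["type_names"] = tuple(p["type_names"])
            d["potts"] = PottsParams(**p)
        if "kinetics" in d:
            d["kinetics"] = KineticParams(**d["kinetics"])
        if "schedule" in d:
            d["schedule"] = ScheduleConfig(**d["schedule"])
        if "growth" in d:
            d["growth"] = GrowthConfig(**d["growth"])
        if "removal" in d:
            d["removal"] = RemovalConfig(**d["removal"])
        if "chemotaxis" in d:
            c = dict(d["chemotaxis"])
            if "origin" in c:
                c["origin"] = tuple(c["origin"])
            if "axis" in c:
                c["axis"] = tuple(c["axis"])
            d["chemotaxis"] = ChemotaxisSpec(**c)
        if "lattice_dims" in d:
            d["lattice_dims"] = tuple(d["lattice_dims"])
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def layer_waves_config(**overrides) -> ScenarioConfig:
    """Thin epithelial sheet; EMT induced by the kappa trigger at 70 MCS."""
    cfg = dict(
        scenario="layer_waves",
        lattice_dims=(64, 64, 10),
        cells_x=10, cells_y=10, cells_z=1,
        mcs_total=600,
        schedule=ScheduleConfig(integration_start_mcs=20, trigger_mcs=70,
                                kappa_before=5.0, kappa_after=1.0),
    )
    cfg.update(overrides)
    return ScenarioConfig(**cfg)


def tumour_layer_config(**overrides) -> ScenarioConfig:
    """Layer-seeded tumour: growth, division, a linear chemoattractant
    gradient away from the layer, and removal-based invasion assay."""
    dims = overrides.pop("lattice_dims", (40, 40, 36))
    cfg = dict(
        scenario="tumour_layer",
        lattice_dims=dims,
        cells_x=4, cells_y=4, cells_z=1,
        mcs_total=1200,
        schedule=ScheduleConfig(integration_start_mcs=20, trigger_mcs=150,
                                kappa_before=5.0, kappa_after=1.0),
        growth=GrowthConfig(enabled=True, max_cells=40),
        removal=RemovalConfig(enabled=True, distance=12.0, cadence=5),
        chemotaxis=ChemotaxisSpec(kind="linear", origin=(0.0, 0.0, 0.0),
                                  axis=(0.0, 0.0, 1.0), slope=1.0,
                                  coefficient={"HighBetaCat": 40.0}),
    )
    cfg.update(overrides)
    return ScenarioConfig(**cfg)


def mts_config(**overrides) -> ScenarioConfig:
    """Multicellular tumour spheroid grown from one central cell; radial
    chemoattractant gradient increasing outwardly; removal assay."""
    dims = overrides.pop("lattice_dims", (40, 40, 40))
    centre = tuple((d - 1) / 2.0 for d in dims)
    kin = overrides.pop("kinetics", KineticParams(threshold_beta=0.4))
    cfg = dict(
        scenario="mts",
        lattice_dims=dims,
        cells_x=1, cells_y=1, cells_z=1,
        mcs_total=900,
        kinetics=kin,
        schedule=ScheduleConfig(integration_start_mcs=20, trigger_mcs=250,
                                kappa_before=5.0, kappa_after=0.25),
        growth=GrowthConfig(enabled=True, max_cells=40),
        removal=RemovalConfig(enabled=True, distance=14.0, cadence=5),
        chemotaxis=ChemotaxisSpec(kind="radial", origin=centre, slope=1.0,
                                  coefficient={"HighBetaCat": 40.0}),
    )
    cfg.update(overrides)
    return ScenarioConfig(**cfg)
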
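"""Template libraries, per-cell instances and the SBML subset."""

import numpy as np
import pytest
from importlib import resources

from emtcpm.errors import (ConfigurationError, LifecycleError, ModelFormatError,
                           UnsupportedSBMLError)
from emtcpm.kinetics import KineticParams, PARAM_NAMES
from emtcpm.lattice import CellTable
from emtcpm.registry import Registry, builtin_emt_model, model_from_sbml

TYPE_NAMES = ("Medium", "LowBetaCat", "HighBetaCat")
_P = {n: i for i, n in enumerate(PARAM_NAMES)}


def bundled_sbml():
    return resources.files("emtcpm").joinpath("data/emt_ecad_bcat.sbml")


def make_cells(n=3, ctype=1):
    cells = CellTable()
    for _ in range(n):
        cid = cells.new_cell(ctype)
        cells.volume[cid] = 10
    return cells


def make_registry(cells, dt=0.03):
    reg = Registry()
    reg.load_model("SimpleModel", builtin_emt_model(), "SM")
    reg.add_model_to_template_library("SimpleModel", "LowBetaCat")
    reg.add_model_to_template_library("SimpleModel", "HighBetaCat")
    reg.initialize_networks(dt, cells, TYPE_NAMES)
    return reg


def test_one_instance_per_templated_cell():
    cells = make_cells(4)
    reg = make_registry(cells)
    assert reg.instance_count() == 4


def test_initial_condition_overrides_apply_per_template():
    cells = make_cells(2)
    reg = Registry()
    reg.load_model("SimpleModel", builtin_emt_model(), "SM")
    reg.add_model_to_template_library("SimpleModel", "LowBetaCat")
    reg.set_initial_condition("LowBetaCat", "SM_k1", 0.9)
    reg.initialize_networks(0.05, cells, TYPE_NAMES)
    assert reg.get_value("SM_k1", 1) == pytest.approx(0.9)
    # un-overridden variables keep the model-definition defaults
    assert reg.get_value("SM_alpha", 1) == pytest.approx(
        KineticParams().production_alpha)


def test_unknown_template_and_unresolvable_address():
    reg = Registry()
    reg.load_model("SimpleModel", builtin_emt_model(), "SM")
    reg.add_model_to_template_library("SimpleModel", "LowBetaCat")
    with pytest.raises(LookupError):
        reg.set_initial_condition("NoSuchTemplate", "SM_k1", 1.0)
    with pytest.raises(LookupError) as err:
        reg.set_initial_condition("LowBetaCat", "SM_not_a_variable", 1.0)
    assert "SM_k1" in str(err.value)  # candidates are listed


def test_duplicate_model_name_replaces_with_warning():
    reg = Registry()
    reg.load_model("M", builtin_emt_model(), "A")
    with pytest.warns(UserWarning):
        reg.load_model("M", builtin_emt_model(), "A")
    with pytest.raises(ConfigurationError):
        reg.load_model("Other", builtin_emt_model(), "A")  # key collision


def test_lifecycle_and_dead_cell_errors():
    reg = Registry()
    reg.load_model("SimpleModel", builtin_emt_model(), "SM")
    with pytest.raises(LifecycleError):
        reg.timestep_networks()
    cells = make_cells(1)
    reg.add_model_to_template_library("SimpleModel", "LowBetaCat")
    reg.initialize_networks(0.03, cells, TYPE_NAMES)
    with pytest.raises(LookupError):
        reg.get_value("SM_Bcat", 999)


def test_set_get_roundtrip_and_timestep():
    cells = make_cells(2)
    reg = make_registry(cells, dt=0.05)
    reg.set_value("SM_Bcat", 0.125, cell_id=2)
    assert reg.get_value("SM_Bcat", 2) == 0.125
    b1_before = reg.get_value("SM_Bcat", 1)
    reg.timestep_networks()
    # production alpha > 0: beta-catenin grows from an empty state
    assert reg.get_value("SM_Bcat", 1) > b1_before


def test_copy_from_parent_then_independent_evolution():
    cells = make_cells(1)
    reg = make_registry(cells)
    reg.set_value("SM_Bcat", 0.4, cell_id=1)
    reg.set_value("SM_Complex", 0.3, cell_id=1)
    child = cells.new_cell(1)
    reg.copy_from_parent(1, child)
    for var in ("SM_Ecad", "SM_Bcat", "SM_Complex", "SM_BcatPro"):
        assert reg.get_value(var, child) == reg.get_value(var, 1)
    # diverge under different forcings
    reg.set_value("SM_Jminus", 5.0, cell_id=child)
    reg.timestep_networks()
    assert reg.get_value("SM_Bcat", child) != reg.get_value("SM_Bcat", 1)


def test_instance_count_tracks_divisions_and_removals():
    cells = make_cells(3)
    reg = make_registry(cells)
    child = cells.new_cell(1)
    reg.copy_from_parent(2, child)
    assert reg.instance_count() == 4
    reg.dispose_cell(2)
    reg.dispose_cell(child)
    assert reg.instance_count() == 2
    with pytest.raises(LookupError):
        reg.get_value("SM_Bcat", 2)


def test_library_level_parameter_change_propagates():
    cells = make_cells(3)
    reg = make_registry(cells)
    reg.set_value_for_all("SM_kappa", 1.25)
    for cid in (1, 2, 3):
        assert reg.get_value("SM_kappa", cid) == 1.25


# ------------------------------------------------------------------- SBML

def test_sbml_subset_loads_bundled_model():
    model = model_from_sbml(bundled_sbml())
    assert set(model.species) == {"Ecad", "Bcat", "Complex", "BcatPro",
                                  "Proteasome"}
    assert model.species_defaults["Ecad"] == 1.0
    assert model.param_defaults["nu"] == pytest.approx(0.4)


def test_sbml_model_matches_builtin_dynamics():
    """The mass-action SBML form (explicit free proteasome) reproduces the
    built-in four-species trajectories."""
    kp = KineticParams()
    sb = model_from_sbml(bundled_sbml())
    jplus, jminus = 0.8, 0.5
    y0 = {"Ecad": 0.6, "Bcat": 0.2, "Complex": 0.4, "BcatPro": 0.1}

    # built-in route
    from emtcpm.kinetics import integrate_states
    row = kp.to_param_row("attached", (jplus, jminus))
    yb = np.array([[y0["Ecad"], y0["Bcat"], y0["Complex"], y0["BcatPro"]]])
    # SBML route: phi = J+ (attached), psi = J-, d_eff = d
    pvals = dict(sb.param_defaults)
    pvals.update({"phi": jplus, "psi": jminus, "d_eff": kp.dissoc_complex_d,
                  "kappa": kp.binding_bcat_proteasome})
    ps = np.array([[pvals[p] for p in sb.params]])
    ys = np.array([[y0.get(s, kp.proteasome_total_P0 - y0["BcatPro"])
                    for s in sb.species]])
    for _ in range(200):
        yb, _ = integrate_states(yb, row[None, :], 0.03)
        ys, _ = integrate_states(ys, ps, 0.03, rhs_fn=sb.rhs_fn)
    si = {s: i for i, s in enumerate(sb.species)}
    np.testing.assert_allclose(
        yb[0], [ys[0, si[s]] for s in ("Ecad", "Bcat", "Complex", "BcatPro")],
        rtol=1e-7)
    # implied free proteasome matches the explicit species
    assert ys[0, si["Proteasome"]] == pytest.approx(
        kp.proteasome_total_P0 - yb[0][3], rel=1e-7)


def test_sbml_unsupported_constructs_are_rejected(tmp_path):
    bad_math = """<?xml version="1.0"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="m"><listOfSpecies><species id="A" initialConcentration="1"/></listOfSpecies>
 <listOfParameters><parameter id="k" value="1"/></listOfParameters>
 <listOfReactions><reaction id="r">
   <listOfReactants><speciesReference species="A"/></listOfReactants>
   <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML">
     <apply><plus/><ci>k</ci><ci>A</ci></apply>
   </math></kineticLaw>
 </reaction></listOfReactions></model></sbml>"""
    f = tmp_path / "bad.sbml"
    f.write_text(bad_math)
    with pytest.raises(UnsupportedSBMLError) as err:
        model_from_sbml(f)
    assert "plus" in str(err.value)

    rules = """<?xml version="1.0"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="m"><listOfRules/></model></sbml>"""
    f2 = tmp_path / "rules.sbml"
    f2.write_text(rules)
    with pytest.raises(UnsupportedSBMLError):
        model_from_sbml(f2)

    with pytest.raises(ModelFormatError):
        model_from_sbml(tmp_path / "missing.sbml")
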
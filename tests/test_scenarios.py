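"""Scenario drivers: initial conditions, reproducibility, analyses, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from emtcpm.cli import main as cli_main
from emtcpm.config import ScenarioConfig, layer_waves_config, mts_config, \
    tumour_layer_config
from emtcpm.coupling import ScheduleConfig
from emtcpm.errors import ConfigurationError
from emtcpm.io import write_run_outputs, write_vtk_structured_points
from emtcpm.scenarios import (TimeSeriesLog, build_initial_condition,
                              invasion_curve, radius_trace, run_scenario,
                              _removal_origin)


def test_layer_initial_condition_geometry():
    cfg = layer_waves_config(cells_x=3, cells_y=3, cells_z=1,
                             lattice_dims=(24, 24, 10))
    lat, cells = build_initial_condition(cfg)
    assert cells.live_ids().size == 9
    assert int((lat.spin > 0).sum()) == 9 * 125
    assert np.all(cells.volume[1:10] == 125)
    assert np.all(cells.init_volume[1:10] == 125)
    assert np.all(cells.tvol[1:10] == pytest.approx(1.728 * 125))


def test_mts_initial_condition_single_central_cell():
    cfg = mts_config(lattice_dims=(21, 21, 21))
    lat, cells = build_initial_condition(cfg)
    assert cells.live_ids().size == 1
    rec = cells.record(1)
    np.testing.assert_allclose(rec.centroid, (10, 10, 10), atol=0.5)


def test_zero_cell_run_is_a_valid_noop():
    cfg = layer_waves_config(cells_x=0, cells_y=0, cells_z=0, mcs_total=5,
                             lattice_dims=(10, 10, 8))
    log = run_scenario(cfg, seed=1)
    assert log.cells.empty
    assert (log.events.event != "emt").all()


def test_geometry_that_does_not_fit_is_rejected():
    with pytest.raises(ConfigurationError):
        layer_waves_config(cells_x=30, lattice_dims=(30, 30, 10))


def test_seed_determinism_byte_identical_logs():
    kw = dict(mcs_total=60, log_every=1)
    a = run_scenario(tumour_layer_config(**kw), seed=7)
    b = run_scenario(tumour_layer_config(**kw), seed=7)
    pd.testing.assert_frame_equal(a.cells, b.cells)
    pd.testing.assert_frame_equal(a.events, b.events)
    pd.testing.assert_frame_equal(a.potts, b.potts)
    c = run_scenario(tumour_layer_config(**kw), seed=8)
    assert not a.potts.equals(c.potts)


def test_noop_trigger_equals_untriggered_dynamics():
    base = dict(mcs_total=120, log_every=1)
    sched = ScheduleConfig(integration_start_mcs=20, trigger_mcs=70,
                           kappa_before=5.0, kappa_after=5.0)
    a = run_scenario(layer_waves_config(schedule=sched, **base), seed=3)
    sched2 = ScheduleConfig(integration_start_mcs=20, trigger_mcs=10_000,
                            kappa_before=5.0, kappa_after=1.0)
    b = run_scenario(layer_waves_config(schedule=sched2, **base), seed=3)
    pd.testing.assert_frame_equal(a.cells, b.cells)
    assert (a.events.event != "emt").all()


def _synthetic_log(distances):
    mcs = np.arange(len(distances))
    df = pd.DataFrame({
        "mcs": mcs, "id": 1, "type": "LowBetaCat", "mode": "attached",
        "volume": 100, "surface": 120,
        "cx": np.asarray(distances, dtype=float), "cy": 0.0, "cz": 0.0,
        "g": 0.5, "Ecad": 1.0, "Bcat": 0.0, "Complex": 0.0, "BcatPro": 0.0})
    return TimeSeriesLog(cells=df, events=pd.DataFrame(
        columns=["mcs", "event", "cell_id", "detail"]),
        potts=pd.DataFrame(), manifest={"mcs_total": len(distances) - 1})


def test_radius_trace_stationary_track():
    log = _synthetic_log(np.full(300, 17.5))
    tr = radius_trace(log, 1, ("point", (0.0, 0.0, 0.0)))
    assert tr.plateau == pytest.approx(17.5)
    assert tr.onset_mcs is None


def test_radius_trace_rise_hold_then_linear_increase():
    track = np.concatenate([np.linspace(0, 40, 80), np.full(200, 40.0),
                            40 + 0.5 * np.arange(120)])
    log = _synthetic_log(track)
    tr = radius_trace(log, 1, ("point", (0.0, 0.0, 0.0)))
    assert tr.plateau == pytest.approx(40.0, abs=1.0)
    assert tr.onset_mcs is not None and 270 <= tr.onset_mcs <= 300


def test_invasion_curve_shape():
    ev = pd.DataFrame({"mcs": [10, 10, 25], "event": ["removal"] * 3,
                       "cell_id": [3, 4, 5], "detail": ""})
    log = TimeSeriesLog(cells=pd.DataFrame(), events=ev,
                        potts=pd.DataFrame(), manifest={"mcs_total": 40})
    curve = invasion_curve(log)
    assert curve.iloc[0] == 0
    assert curve.loc[10] == 2
    assert curve.iloc[-1] == 3
    assert (curve.diff().fillna(0) >= 0).all()


def test_invasion_curve_empty_run():
    log = TimeSeriesLog(cells=pd.DataFrame(),
                        events=pd.DataFrame(columns=["mcs", "event",
                                                     "cell_id", "detail"]),
                        potts=pd.DataFrame(), manifest={"mcs_total": 20})
    assert (invasion_curve(log) == 0).all()


def test_vtk_snapshot_roundtrip(tmp_path):
    spin = np.zeros((4, 3, 2), dtype=np.int32)
    spin[1, 1, 1] = 2
    ctype = np.array([0, 1, 2])
    bcat = np.array([0.0, 0.1, 0.7])
    path = tmp_path / "snap.vtk"
    write_vtk_structured_points(path, spin, ctype, bcat)
    text = path.read_text().splitlines()
    assert text[0].startswith("# vtk DataFile")
    assert "DIMENSIONS 4 3 2" in text
    assert f"POINT_DATA {spin.size}" in text
    flat = spin.ravel(order="F")
    idx = text.index("LOOKUP_TABLE default") + 1
    ids = [int(v) for v in text[idx: idx + spin.size]]
    assert ids == flat.tolist()
    assert "SCALARS bcat_free float 1" in text


def test_config_yaml_roundtrip(tmp_path):
    cfg = tumour_layer_config(mcs_total=77, seed=5)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = ScenarioConfig.from_yaml(path)
    assert back.to_dict() == cfg.to_dict()


def test_run_outputs_written(tmp_path):
    cfg = layer_waves_config(cells_x=2, cells_y=2, mcs_total=10,
                             lattice_dims=(20, 20, 10))
    log = run_scenario(cfg, seed=2)
    manifest = write_run_outputs(log, cfg, tmp_path)
    for name in ("cells.csv", "events.csv", "potts.csv", "manifest.json"):
        assert (tmp_path / name).exists()
    assert manifest["seed"] == 2
    assert "config_sha256" in manifest


def test_cli_layer_waves_smoke(tmp_path):
    runner = CliRunner()
    res = runner.invoke(cli_main, ["layer-waves", "--mcs", "12", "--seed", "3",
                                   "--out-dir", str(tmp_path)])
    assert res.exit_code == 0, res.output
    assert (tmp_path / "cells.csv").exists()
    assert "peak detached fraction" in res.output


def test_cli_invasion_sweep_smoke(tmp_path):
    runner = CliRunner()
    res = runner.invoke(cli_main, [
        "invasion-sweep", "--scenario", "tumour-layer", "--nu", "0.4",
        "--seeds", "1", "--mcs", "15", "--out-dir", str(tmp_path)])
    assert res.exit_code == 0, res.output
    df = pd.read_csv(tmp_path / "invasion_sweep.csv")
    assert set(df.columns) == {"nu", "seed", "removed", "scenario"}


def test_mass_conservation_through_full_run():
    """Total lattice sites = medium + sum of cell volumes at every stage,
    and the registry tracks exactly the live cells."""
    cfg = mts_config(mcs_total=150, log_every=10, lattice_dims=(26, 26, 26))
    log = run_scenario(cfg, seed=4)
    last = log.cells[log.cells.mcs == log.cells.mcs.max()]
    assert (last.volume > 0).all()
    n_divisions = int((log.events.event == "division").sum())
    assert last.shape[0] == 1 + n_divisions - \
        int((log.events.event.isin(("removal", "death"))).sum())
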
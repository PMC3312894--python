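"""Run outputs: CSV time series, event log, legacy-VTK voxel snapshots and a
run manifest with the config hash and seed."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np


def write_run_outputs(log, config, out_dir) -> dict:
    """Write cells.csv, events.csv, potts.csv and manifest.json; returns the
    manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.cells.to_csv(out / "cells.csv", index=False)
    log.events.to_csv(out / "events.csv", index=False)
    log.potts.to_csv(out / "potts.csv", index=False)
    manifest = dict(log.manifest)
    cfg = config.to_dict()
    manifest["config"] = cfg
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def write_vtk_structured_points(path, spin, ctype_per_cell,
                                bcat_per_cell=None, pixel_scale=1.0):
    """Legacy ASCII VTK structured-points snapshot of the voxel fields.

    Writes cell id, cell type and (optionally) per-voxel free beta-catenin
    concentration, each as a scalar field on the lattice.
    """
    spin = np.asarray(spin)
    nx, ny, nz = spin.shape
    flat = spin.ravel(order="F")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("emtcpm voxel snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {pixel_scale} {pixel_scale} {pixel_scale}\n")
        fh.write(f"POINT_DATA {flat.size}\n")

        def scalars(name, values, fmt="%d"):
            fh.write(f"SCALARS {name} {'int' if fmt == '%d' else 'float'} 1\n")
            fh.write("LOOKUP_TABLE default\n")
            np.savetxt(fh, values.reshape(-1, 1), fmt=fmt)

        scalars("cell_id", flat)
        scalars("cell_type", np.asarray(ctype_per_cell)[flat])
        if bcat_per_cell is not None:
            scalars("bcat_free", np.asarray(bcat_per_cell, dtype=float)[flat],
                    fmt="%.6g")


def bcat_voxel_values(cells_capacity, ids, bcat_values):
    """Dense per-cell-id array of free beta-catenin for snapshot writing."""
    arr = np.zeros(cells_capacity, dtype=float)
    arr[np.asarray(ids, dtype=int)] = bcat_values
    return arr
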
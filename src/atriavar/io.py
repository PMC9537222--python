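"""Plain-text export helpers: legacy ASCII VTK and CSV tables.

VTK files are written in the legacy ASCII STRUCTURED_POINTS format, which
every mainstream scientific viewer reads, so no binary dependency is
needed.  Node-ordered arrays (voltage frames, activation maps, APD maps,
model/region ids) map directly onto the structured lattice because the
grid numbers nodes x-fastest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tissue import TissueGrid

__all__ = ["write_vtk", "write_activation_vtk", "trace_to_csv",
           "calibration_table"]


def write_vtk(grid: TissueGrid, point_data: dict, path,
              title: str = "atriavar export") -> None:
    """Write node-valued scalar fields on the grid as legacy ASCII VTK.

    ``point_data`` maps field name -> array of length ``grid.n_nodes``.
    NaNs are preserved (most viewers render them as blanks).
    """
    npx, npy, npz = grid.nx + 1, grid.ny + 1, grid.nz + 1
    nn = grid.n_nodes
    for name, arr in point_data.items():
        if len(arr) != nn:
            raise ValueError(f"field {name!r} has length {len(arr)}, "
                             f"expected {nn}")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title.replace("\n", " ")[:255] + "\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {npx} {npy} {npz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {grid.h} {grid.h} {grid.h}\n")
        fh.write(f"POINT_DATA {nn}\n")
        for name, arr in point_data.items():
            safe = name.replace(" ", "_")
            fh.write(f"SCALARS {safe} float 1\nLOOKUP_TABLE default\n")
            vals = np.asarray(arr, dtype=float)
            for start in range(0, nn, 9):
                row = vals[start:start + 9]
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def write_activation_vtk(solution, path) -> None:
    """Export activation/crossing times and node metadata of a tissue run."""
    grid = solution.grid
    data = {"activation_ms": solution.activation,
            "crossing_ms": solution.crossing}
    if grid.node_model is not None:
        data["model_id"] = grid.node_model.astype(float)
    data["material_id"] = grid.node_material.astype(float)
    write_vtk(grid, data, path, title="activation map")


def trace_to_csv(trace, path) -> None:
    """Write a single-cell action-potential trace as time,voltage CSV."""
    pd.DataFrame({"time_ms": trace.times,
                  "voltage_mV": trace.voltages}).to_csv(path, index=False)


def calibration_table(results) -> pd.DataFrame:
    """Tabulate a list of CalibrationResult objects."""
    return pd.DataFrame([{
        "material": r.material, "mode": r.mode, "seed": r.seed,
        "sigma_L_mS_per_cm": r.sigma_L, "sigma_T_mS_per_cm": r.sigma_T,
        "cv_L_cm_per_s": r.cv_L, "cv_T_cm_per_s": r.cv_T,
        "iterations": r.iterations} for r in results])
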
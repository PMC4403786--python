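"""Minimal legacy-VTK (ASCII) export of meshes and fields.

The uniform cell grid maps onto the VTK ``STRUCTURED_POINTS`` dataset;
subdomain labels and nodal fields are written as cell data, readable by
ParaView/VisIt for inspection.
"""

from __future__ import annotations

import numpy as np

from .geometry import LabeledMesh


def write_vtk(path, mesh: LabeledMesh, cell_data: dict | None = None) -> None:
    """Write the mesh (and optional per-cell scalar fields) to ``path``.

    ``cell_data`` maps field names to arrays of shape (ny, nx) or flat
    length nx*ny.
    """
    nx, ny, h = mesh.nx, mesh.ny, mesh.h
    fields = {"subdomain": mesh.labels.astype(float)}
    for name, arr in (cell_data or {}).items():
        fields[name] = np.asarray(arr, float).reshape(ny, nx)
    with open(path, "w", encoding="ascii") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("isletsim perifusion chamber\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        # cell-centered data on an (nx+1) x (ny+1) point lattice
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {h:.9e} {h:.9e} {h:.9e}\n")
        fh.write(f"CELL_DATA {nx * ny}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.ravel()[None].T, fmt="%.9e")
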
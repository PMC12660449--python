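"""Legacy-ASCII VTK unstructured-grid export for tetrahedral meshes.

Writes the simple text variant of the VTK file format (DATASET
UNSTRUCTURED_GRID, cell type 10 = linear tetrahedron) with per-cell data
fields, plus an optional JSON sidecar mapping element-set ids to names.
A minimal reader for the same subset is provided for round-trip checks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_vtk", "read_vtk_cell_data", "write_set_sidecar"]

_VTK_TET = 10


def write_vtk(path, mesh, cell_data: dict[str, np.ndarray] | None = None, comment="osteoadapt mesh"):
    """Write a tet mesh and per-element scalar fields as legacy ASCII VTK."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        comment,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines.extend(" ".join(f"{c:.10g}" for c in p) for p in mesh.nodes)
    m = mesh.n_elements
    lines.append(f"CELLS {m} {5 * m}")
    lines.extend("4 " + " ".join(str(i) for i in t) for t in mesh.tets)
    lines.append(f"CELL_TYPES {m}")
    lines.extend([str(_VTK_TET)] * m)
    if cell_data:
        lines.append(f"CELL_DATA {m}")
        for name, values in cell_data.items():
            values = np.asarray(values, float)
            if len(values) != m:
                raise ValueError(
                    f"cell field {name!r} has {len(values)} values for {m} cells"
                )
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.10g}" for v in values)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk_cell_data(path) -> dict[str, np.ndarray]:
    """Read back the scalar cell fields written by :func:`write_vtk`."""
    tokens = Path(path).read_text().split("\n")
    fields: dict[str, np.ndarray] = {}
    i = 0
    n_cells = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("CELL_DATA"):
            n_cells = int(line.split()[1])
        elif line.startswith("SCALARS") and n_cells:
            name = line.split()[1]
            i += 2  # skip LOOKUP_TABLE
            vals = [float(tokens[i + k]) for k in range(n_cells)]
            fields[name] = np.array(vals)
            i += n_cells - 1
        i += 1
    return fields


def write_set_sidecar(path, mesh):
    """JSON sidecar with element/node set membership for a VTK file."""
    data = {
        "element_sets": {k: v.tolist() for k, v in mesh.element_sets.items()},
        "node_sets": {k: v.tolist() for k, v in mesh.node_sets.items()},
    }
    Path(path).write_text(json.dumps(data))
    return Path(path)
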
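"""File output: legacy-VTK fields on the axisymmetric mesh, CSV descriptors."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._fem import AxisymMesh

__all__ = ["write_vtk", "write_outline_csv", "write_thickness_csv"]


def write_vtk(
    path: str | Path,
    mesh: AxisymMesh,
    displacement: np.ndarray | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    deformed: bool = True,
) -> Path:
    """ASCII legacy-VTK unstructured grid of the (r, z) section.

    The axisymmetric section is written as quads in the x-y plane
    (x = r, y = z); per-node and per-element fields are attached as
    scalars/vectors.
    """
    path = Path(path)
    nodes = mesh.nodes.copy()
    if displacement is not None and deformed:
        nodes = nodes + displacement.reshape(-1, 2)
    lines = [
        "# vtk DataFile Version 3.0",
        "axisymmetric disc section",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [f"{r:.10g} {z:.10g} 0" for r, z in nodes]
    lines.append(f"CELLS {mesh.n_elems} {mesh.n_elems * 5}")
    lines += ["4 " + " ".join(map(str, e)) for e in mesh.elems]
    lines.append(f"CELL_TYPES {mesh.n_elems}")
    lines += ["9"] * mesh.n_elems
    pdata = dict(point_data or {})
    if displacement is not None:
        pdata.setdefault("displacement", displacement.reshape(-1, 2))
    if pdata:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in pdata.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 2:
                lines.append(f"VECTORS {name} double")
                lines += [f"{a:.10g} {b:.10g} 0" for a, b in arr]
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.10g}" for v in arr.ravel()]
    cdata = dict(cell_data or {})
    cdata.setdefault("layer", mesh.elem_layer.astype(float))
    lines.append(f"CELL_DATA {mesh.n_elems}")
    for name, arr in cdata.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.10g}" for v in np.asarray(arr).ravel()]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_outline_csv(path: str | Path, outline: np.ndarray) -> Path:
    path = Path(path)
    pd.DataFrame(outline, columns=["r", "z"]).to_csv(path, index=False)
    return path


def write_thickness_csv(path: str | Path, rows: list[dict]) -> Path:
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
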
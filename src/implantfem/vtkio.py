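"""Legacy-VTK (ASCII) export of tet meshes with cell and point data.

A deliberately small writer for inspection in ParaView: unstructured grid,
cell type 10 (tetrahedron), per-element scalars (label, density, modulus,
equivalent stress, ...) as CELL_DATA and nodal vectors (displacement) as
POINT_DATA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .meshing import TetMesh

__all__ = ["write_vtk"]


def write_vtk(
    mesh: TetMesh,
    path: str | Path,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    title: str = "implantfem mesh",
) -> Path:
    path = Path(path)
    cell_data = dict(cell_data or {})
    cell_data.setdefault("label", mesh.labels)
    if mesh.E is not None:
        cell_data.setdefault("youngs_modulus_mpa", mesh.E)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}")
    lines += ["4 " + " ".join(str(i) for i in tet) for tet in mesh.tets]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += ["10"] * mesh.n_elements

    if cell_data:
        lines.append(f"CELL_DATA {mesh.n_elements}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.shape[0] != mesh.n_elements:
                raise ValueError(f"cell data '{name}' has wrong length")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{float(v):.9g}" for v in arr]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.shape[0] != mesh.n_nodes:
                raise ValueError(f"point data '{name}' has wrong length")
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{v:.9g}" for v in row) for row in arr]
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{float(v):.9g}" for v in arr]
    path.write_text("\n".join(lines) + "\n")
    return path
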
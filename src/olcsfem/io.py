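"""File output: VTU / Gmsh MSH mesh export, CSV/JSON result tables.

Minimal ASCII writers for the two interchange formats (unstructured
VTK XML with linear tetrahedra, and Gmsh 2.2 with region labels as
physical tags); enough for ParaView / Gmsh to open the results.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .meshing import Mesh

__all__ = ["write_vtu", "write_msh", "write_json"]

_VTK_TET = 10


def _fmt_array(a: np.ndarray, per_line: int = 6) -> str:
    flat = np.asarray(a).ravel()
    if np.issubdtype(flat.dtype, np.integer):
        body = " ".join(str(int(x)) for x in flat)
    else:
        body = " ".join(f"{x:.9g}" for x in flat)
    return body


def write_vtu(
    path: str | Path,
    mesh: Mesh,
    point_data: Mapping[str, np.ndarray] | None = None,
    cell_data: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh (plus optional fields) as an ASCII .vtu file.

    Region labels are always included as cell data ``region``.
    """
    cell_data = {"region": mesh.labels, **(cell_data or {})}
    point_data = dict(point_data or {})
    n_pts, n_cells = mesh.n_nodes, mesh.n_elements

    def data_array(name, arr):
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        dtype = "Int32" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        return (
            f'<DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n'
            f"{_fmt_array(arr)}\n</DataArray>\n"
        )

    parts = [
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        "<UnstructuredGrid>\n"
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">\n'
    ]
    parts.append("<Points>\n" + data_array("points", mesh.nodes) + "</Points>\n")
    parts.append("<Cells>\n")
    parts.append(data_array("connectivity", mesh.elems.astype(np.int64)))
    parts.append(
        data_array("offsets", 4 * np.arange(1, n_cells + 1, dtype=np.int64))
    )
    parts.append(
        data_array("types", np.full(n_cells, _VTK_TET, dtype=np.int64))
    )
    parts.append("</Cells>\n")
    if point_data:
        parts.append("<PointData>\n")
        for name, arr in point_data.items():
            parts.append(data_array(name, arr))
        parts.append("</PointData>\n")
    parts.append("<CellData>\n")
    for name, arr in cell_data.items():
        parts.append(data_array(name, arr))
    parts.append("</CellData>\n")
    parts.append("</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
    Path(path).write_text("".join(parts))


def write_msh(path: str | Path, mesh: Mesh) -> None:
    """Write the mesh in Gmsh 2.2 ASCII format.

    Volume elements carry their region label as physical and geometrical
    tag; boundary triangles are emitted per facet set with tags 100+index.
    """
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.9g} {y:.9g} {z:.9g}")
    lines.append("$EndNodes")

    facet_items = sorted(mesh.facets.items())
    n_tris = sum(len(t) for _, t in facet_items)
    lines.append("$Elements")
    lines.append(str(mesh.n_elements + n_tris))
    eid = 1
    for tag, (_, tris) in enumerate(facet_items, start=100):
        for tri in tris:
            a, b, c = (int(v) + 1 for v in tri)
            lines.append(f"{eid} 2 2 {tag} {tag} {a} {b} {c}")
            eid += 1
    for elem, lab in zip(mesh.elems, mesh.labels):
        a, b, c, d = (int(v) + 1 for v in elem)
        lines.append(f"{eid} 4 2 {int(lab)} {int(lab)} {a} {b} {c} {d}")
        eid += 1
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(path: str | Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
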
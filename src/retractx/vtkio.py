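"""Minimal VTU (VTK XML unstructured grid) export for meshes and solutions.

ASCII only, hexahedral cells only — enough for ParaView/meshio consumers to
load the mesh with point-data displacements and cell-data cut flags.
"""
from __future__ import annotations

import numpy as np

from .mesh import HexMesh

__all__ = ["write_vtu"]

_VTK_HEX = 12


def _ascii(a: np.ndarray) -> str:
    return " ".join(map(str, np.asarray(a).ravel().tolist()))


def write_vtu(
    path,
    mesh: HexMesh,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write the hexahedral mesh (and optional per-node / per-element arrays)
    as an ASCII .vtu file."""
    n_pts, n_cells = mesh.n_nodes, mesh.n_elements
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _ascii(mesh.nodes),
        "</DataArray>", "</Points>", "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _ascii(mesh.elements),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _ascii(8 * np.arange(1, n_cells + 1)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _ascii(np.full(n_cells, _VTK_HEX, dtype=np.uint8)),
        "</DataArray>", "</Cells>",
    ]

    def data_section(tag: str, arrays: dict | None):
        out = [f"<{tag}>"]
        for name, arr in (arrays or {}).items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            out.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            out.append(_ascii(arr.astype(float)))
            out.append("</DataArray>")
        out.append(f"</{tag}>")
        return out

    lines += data_section("PointData", point_data)
    lines += data_section("CellData", cell_data)
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
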
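"""Minimal ascii VTU (VTK UnstructuredGrid XML) reader/writer.

Writes quadratic tetrahedra (VTK cell type 24) with point/cell data arrays;
named element sets are encoded as an integer cell array plus a companion
``<file>.sets.json`` carrying the set-name table, surface facet sets,
reference points and tie records, so a mesh round-trips losslessly.
Readers of foreign VTU files get whatever point/cell data is present
(postprocessing-only mode).
"""

from __future__ import annotations

import json
import os
import xml.etree.ElementTree as ET

import numpy as np

from .mesh import Mesh

VTK_QUADRATIC_TETRA = 24


def _fmt(arr: np.ndarray) -> str:
    a = np.asarray(arr)
    if a.dtype.kind in "iu":
        return "\n".join(" ".join(str(v) for v in row) for row in np.atleast_2d(a))
    return "\n".join(
        " ".join(repr(float(v)) for v in row) for row in np.atleast_2d(a)
    )


def _data_array(name, arr, dtype):
    a = np.asarray(arr)
    ncomp = 1 if a.ndim == 1 else a.shape[1]
    return (
        f'<DataArray type="{dtype}" Name="{name}" '
        f'NumberOfComponents="{ncomp}" format="ascii">\n'
        f"{_fmt(a.reshape(len(a), -1))}\n</DataArray>\n"
    )


def write_vtu(
    path, nodes, elements, point_data=None, cell_data=None
) -> str:
    """Write an ascii .vtu file of quadratic tets; returns the path."""
    n, m = len(nodes), len(elements)
    parts = [
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
        "<UnstructuredGrid>\n"
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n',
        "<Points>\n",
        _data_array("Points", np.asarray(nodes, float), "Float64"),
        "</Points>\n<Cells>\n",
        _data_array("connectivity", np.asarray(elements).ravel(), "Int64"),
        _data_array(
            "offsets", (np.arange(1, m + 1) * 10).astype(np.int64), "Int64"
        ),
        _data_array(
            "types", np.full(m, VTK_QUADRATIC_TETRA, dtype=np.int64), "Int64"
        ),
        "</Cells>\n",
    ]
    parts.append("<PointData>\n")
    for name, arr in (point_data or {}).items():
        parts.append(_data_array(name, np.asarray(arr, float), "Float64"))
    parts.append("</PointData>\n<CellData>\n")
    for name, arr in (cell_data or {}).items():
        a = np.asarray(arr)
        dtype = "Int64" if a.dtype.kind in "iu" else "Float64"
        parts.append(_data_array(name, a, dtype))
    parts.append("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
    with open(path, "w") as fh:
        fh.write("".join(parts))
    return str(path)


def read_vtu(path):
    """Read an ascii .vtu file -> (nodes, elements, point_data, cell_data).

    Raises ValueError with the file location on malformed input.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"malformed VTU file {path}: {exc}") from exc
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise ValueError(f"{path}: no <Piece> element")

    def parse_da(da):
        text = (da.text or "").split()
        dtype = float if da.get("type", "").startswith("Float") else np.int64
        arr = np.array(text, dtype=dtype)
        ncomp = int(da.get("NumberOfComponents", "1"))
        return arr.reshape(-1, ncomp) if ncomp > 1 else arr

    points = parse_da(piece.find("Points/DataArray"))
    cells = {da.get("Name"): parse_da(da) for da in piece.findall("Cells/DataArray")}
    types = cells["types"]
    if not np.all(types == VTK_QUADRATIC_TETRA):
        raise ValueError(f"{path}: only quadratic tetrahedra are supported")
    elements = cells["connectivity"].reshape(-1, 10)
    pdata = {
        da.get("Name"): parse_da(da)
        for da in piece.findall("PointData/DataArray")
    }
    cdata = {
        da.get("Name"): parse_da(da)
        for da in piece.findall("CellData/DataArray")
    }
    return points, elements, pdata, cdata


# ---------------------------------------------------------------------------
# mesh and solution round-trips


def save_mesh(mesh: Mesh, path) -> str:
    """Write mesh + companion ``.sets.json`` (sets, facets, ties, points)."""
    set_names = sorted(mesh.element_sets)
    labels = np.full(mesh.n_elements, -1, dtype=np.int64)
    for i, name in enumerate(set_names):
        labels[mesh.element_sets[name]] = i
    write_vtu(path, mesh.nodes, mesh.elements, cell_data={"element_set": labels})
    companion = {
        "element_set_names": set_names,
        "surface_sets": {k: v.tolist() for k, v in mesh.surface_sets.items()},
        "reference_points": {
            k: list(map(float, v)) for k, v in mesh.reference_points.items()
        },
        "ties": mesh.ties.tolist() if mesh.ties is not None else None,
    }
    with open(str(path) + ".sets.json", "w") as fh:
        json.dump(companion, fh)
    return str(path)


def load_mesh(path) -> Mesh:
    """Read a mesh written by :func:`save_mesh`."""
    nodes, elements, _, cdata = read_vtu(path)
    mesh = Mesh(nodes=nodes, elements=elements)
    side = str(path) + ".sets.json"
    if os.path.exists(side):
        with open(side) as fh:
            companion = json.load(fh)
        labels = cdata.get("element_set")
        for i, name in enumerate(companion["element_set_names"]):
            mesh.element_sets[name] = np.flatnonzero(labels == i)
        mesh.surface_sets = {
            k: np.asarray(v, dtype=int).reshape(-1, 6)
            for k, v in companion["surface_sets"].items()
        }
        mesh.reference_points = {
            k: np.asarray(v) for k, v in companion["reference_points"].items()
        }
        if companion.get("ties") is not None:
            mesh.ties = np.asarray(companion["ties"])
    return mesh


def save_solution(mesh: Mesh, solution, path) -> str:
    """Write displacement/stress fields of a solution, plus metadata JSON.

    Voigt stress order in the file is (xx, yy, zz, xy, yz, xz).
    """
    write_vtu(
        path, mesh.nodes, mesh.elements,
        point_data={"u": solution.u},
        cell_data={"stress": solution.stress},
    )
    meta = {
        "converged": bool(solution.converged),
        "iterations": int(solution.iterations),
        "residual": float(solution.residual),
        "stress_order": "xx yy zz xy yz xz",
        "units": {"u": "mm", "stress": "MPa"},
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh)
    return str(path)


def load_fields(path):
    """Read displacement (and stress, if present) fields from any VTU.

    Returns ``(nodes, elements, u, stress)`` with ``stress`` possibly None:
    foreign files without stress still support the gap-kinematics
    postprocessing, which needs displacements only.
    """
    nodes, elements, pdata, cdata = read_vtu(path)
    u = pdata.get("u")
    stress = cdata.get("stress")
    return nodes, elements, u, stress
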
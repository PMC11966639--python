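"""ASCII VTU (VTK XML unstructured-grid) I/O and landmark/config sidecars.

The dialect written here is deliberately plain: tetrahedra first, then tagged
boundary triangles, with an integer cell-data array ``boundary_tag`` (value -1
on volume cells) and landmarks in a JSON sidecar ``<path>.landmarks.json``.
Only the features this package needs are supported -- ASCII format, tet and
triangle cells -- which keeps every artifact human-readable and diffable.
"""

from __future__ import annotations

import json
import pathlib
import xml.etree.ElementTree as ET

import numpy as np
import yaml

from .mesh import LabeledTetMesh, MeshFormatError
from .tags import NAME_TO_TAG

VTK_TETRA = 10
VTK_TRIANGLE = 5

TAG_ARRAY = "boundary_tag"
CHAMBER_ARRAY = "chamber_truth"


def _fmt(a: np.ndarray) -> str:
    if np.issubdtype(a.dtype, np.integer):
        return " ".join(str(int(x)) for x in a.ravel())
    return " ".join(format(float(x), ".17g") for x in a.ravel())


def _data_array(parent, name, a, components=None):
    a = np.asarray(a)
    if np.issubdtype(a.dtype, np.integer):
        typ = "Int64"
        a = a.astype(np.int64)
    else:
        typ = "Float64"
        a = a.astype(np.float64)
    el = ET.SubElement(parent, "DataArray", type=typ, format="ascii")
    if name is not None:
        el.set("Name", name)
    if components is not None:
        el.set("NumberOfComponents", str(components))
    el.text = _fmt(a)
    return el


def write_mesh(path, mesh: LabeledTetMesh, point_data=None, cell_data=None) -> None:
    """Write mesh plus named node/cell data arrays to an ASCII VTU file.

    ``point_data`` maps name -> (N,) or (N, 3) array; ``cell_data`` maps
    name -> array over all cells (tets then boundary triangles).  Raises on
    size mismatches.
    """
    path = pathlib.Path(path)
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})

    n_pts = mesh.n_nodes
    cells = [mesh.tets, mesh.boundary_tris]
    n_cells = mesh.n_tets + mesh.boundary_tris.shape[0]

    for name, arr in point_data.items():
        if np.asarray(arr).shape[0] != n_pts:
            raise MeshFormatError(f"point data {name!r} has wrong length")
    for name, arr in cell_data.items():
        if np.asarray(arr).shape[0] != n_cells:
            raise MeshFormatError(f"cell data {name!r} has wrong length")

    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="1.0", byte_order="LittleEndian"
    )
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        grid, "Piece", NumberOfPoints=str(n_pts), NumberOfCells=str(n_cells)
    )

    pts = ET.SubElement(piece, "Points")
    _data_array(pts, None, mesh.nodes, components=3)

    cel = ET.SubElement(piece, "Cells")
    conn = np.concatenate([c.ravel() for c in cells])
    offsets = np.concatenate(
        [4 * np.arange(1, mesh.n_tets + 1),
         4 * mesh.n_tets + 3 * np.arange(1, mesh.boundary_tris.shape[0] + 1)]
    )
    types = np.concatenate(
        [np.full(mesh.n_tets, VTK_TETRA), np.full(mesh.boundary_tris.shape[0], VTK_TRIANGLE)]
    )
    _data_array(cel, "connectivity", conn)
    _data_array(cel, "offsets", offsets)
    _data_array(cel, "types", types)

    pd = ET.SubElement(piece, "PointData")
    if mesh.node_chamber is not None and CHAMBER_ARRAY not in point_data:
        point_data[CHAMBER_ARRAY] = mesh.node_chamber
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        comp = arr.shape[1] if arr.ndim == 2 else None
        _data_array(pd, name, arr, components=comp)

    cd = ET.SubElement(piece, "CellData")
    tag_cells = np.concatenate(
        [np.full(mesh.n_tets, -1, dtype=np.int64), mesh.tri_tags]
    )
    _data_array(cd, TAG_ARRAY, tag_cells)
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        comp = arr.shape[1] if arr.ndim == 2 else None
        _data_array(cd, name, arr, components=comp)

    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")

    if mesh.landmarks:
        sidecar = path.with_suffix(path.suffix + ".landmarks.json")
        sidecar.write_text(
            json.dumps({k: int(v) for k, v in mesh.landmarks.items()}, indent=1)
        )


def _parse_array(el) -> np.ndarray:
    tokens = (el.text or "").split()
    if el.get("type", "Float64").startswith(("Int", "UInt")):
        a = np.array(tokens, dtype=np.int64)
    else:
        a = np.array(tokens, dtype=np.float64)
    comp = int(el.get("NumberOfComponents", "1"))
    return a.reshape(-1, comp) if comp > 1 else a


def read_mesh(path, units: str = "m", tag_remap: dict | None = None,
              with_fields: bool = False):
    """Read a labeled tet mesh (and optionally its data arrays) from VTU.

    Parameters
    ----------
    units : "m" or "mm"; coordinates are rescaled to meters.
    tag_remap : optional mapping of on-disk integer tag codes to taxonomy
        names or codes, for ingesting externally labeled meshes.
    with_fields : if True, also return ``(point_data, cell_data)`` dicts.
    """
    path = pathlib.Path(path)
    root = ET.parse(path).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise MeshFormatError(f"{path}: not a VTU unstructured grid")

    pts_el = piece.find("./Points/DataArray")
    nodes = _parse_array(pts_el).reshape(-1, 3)
    if units == "mm":
        nodes = nodes * 1e-3
    elif units != "m":
        raise ValueError(f"unsupported units {units!r}")

    cells = {el.get("Name"): _parse_array(el) for el in piece.findall("./Cells/DataArray")}
    conn, offsets, types = cells["connectivity"], cells["offsets"], cells["types"]

    point_data = {el.get("Name"): _parse_array(el)
                  for el in piece.findall("./PointData/DataArray")}
    cell_data = {el.get("Name"): _parse_array(el)
                 for el in piece.findall("./CellData/DataArray")}
    if TAG_ARRAY not in cell_data:
        raise MeshFormatError(f"{path}: missing required cell-data array {TAG_ARRAY!r}")
    tag_cells = np.asarray(cell_data[TAG_ARRAY], dtype=np.int64)

    starts = np.concatenate([[0], offsets[:-1]]).astype(int)
    bad = set(np.unique(types)) - {VTK_TETRA, VTK_TRIANGLE}
    if bad:
        raise MeshFormatError(f"{path}: unsupported cell types {sorted(bad)}")

    tet_mask = types == VTK_TETRA
    tri_mask = types == VTK_TRIANGLE
    tets = np.stack([conn[s:s + 4] for s in starts[tet_mask]]) if tet_mask.any() \
        else np.empty((0, 4), dtype=np.int64)
    tris = np.stack([conn[s:s + 3] for s in starts[tri_mask]]) if tri_mask.any() \
        else np.empty((0, 3), dtype=np.int64)
    tri_tags = tag_cells[tri_mask]

    if tag_remap:
        remap = {}
        for k, v in tag_remap.items():
            remap[int(k)] = int(NAME_TO_TAG[v]) if isinstance(v, str) else int(v)
        tri_tags = np.array([remap.get(int(t), int(t)) for t in tri_tags], dtype=np.int64)

    landmarks = {}
    sidecar = path.with_suffix(path.suffix + ".landmarks.json")
    if sidecar.exists():
        landmarks = {k: int(v) for k, v in json.loads(sidecar.read_text()).items()}

    chamber = None
    if CHAMBER_ARRAY in point_data:
        chamber = np.asarray(point_data.pop(CHAMBER_ARRAY)).astype(np.int64)

    mesh = LabeledTetMesh(
        nodes=nodes, tets=tets, boundary_tris=tris, tri_tags=tri_tags,
        landmarks=landmarks, node_chamber=chamber,
    )
    if with_fields:
        cell_data.pop(TAG_ARRAY, None)
        return mesh, point_data, cell_data
    return mesh


# ---------------------------------------------------------------------------
# YAML run configuration
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Load a YAML run configuration (units, tag remapping, parameters)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
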
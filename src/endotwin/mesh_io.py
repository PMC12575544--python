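"""Minimal volume-mesh I/O: Gmsh MSH (v2.2 write, v2.2/v4.1 read) and legacy
ASCII VTK unstructured grids.

Only the element types this package uses are supported: 4-node tetrahedra and
3-node triangles.  Surface formats (STL, OBJ) go through :mod:`trimesh`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


class MeshIOError(ValueError):
    pass


def write_msh(path: str | Path, vertices: np.ndarray, tets: np.ndarray | None = None,
              triangles: np.ndarray | None = None) -> None:
    """Write an ASCII Gmsh MSH v2.2 file (0-based arrays in, 1-based on disk)."""
    v = np.asarray(vertices, dtype=float)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(len(v))]
    lines += [f"{i + 1} {x:.17g} {y:.17g} {z:.17g}" for i, (x, y, z) in enumerate(v)]
    lines += ["$EndNodes", "$Elements"]
    elems = []
    eid = 1
    for arr, etype in ((triangles, 2), (tets, 4)):
        if arr is None:
            continue
        for row in np.asarray(arr, dtype=int):
            conn = " ".join(str(i + 1) for i in row)
            elems.append(f"{eid} {etype} 2 0 0 {conn}")
            eid += 1
    lines.append(str(len(elems)))
    lines += elems
    lines += ["$EndElements", ""]
    Path(path).write_text("\n".join(lines))


def read_msh(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an ASCII Gmsh MSH v2.2 or v4.1 file.

    Returns (vertices, tets, triangles) with 0-based connectivity; element
    types other than tetrahedra and triangles are ignored.
    """
    text = Path(path).read_text().split("\n")
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            block = []
            while j < len(text) and text[j].strip() != f"$End{name}":
                block.append(text[j])
                j += 1
            sections[name] = block
            i = j + 1
        else:
            i += 1
    if "MeshFormat" not in sections:
        raise MeshIOError(f"{path}: not a Gmsh MSH file")
    version = sections["MeshFormat"][0].split()[0]
    if version.startswith("2"):
        return _parse_msh2(sections)
    if version.startswith("4"):
        return _parse_msh4(sections)
    raise MeshIOError(f"{path}: unsupported MSH version {version}")


def _parse_msh2(sections):
    node_lines = sections["Nodes"]
    n_nodes = int(node_lines[0])
    ids = np.empty(n_nodes, dtype=int)
    verts = np.empty((n_nodes, 3))
    for k, line in enumerate(node_lines[1:1 + n_nodes]):
        parts = line.split()
        ids[k] = int(parts[0])
        verts[k] = [float(p) for p in parts[1:4]]
    remap = {nid: k for k, nid in enumerate(ids)}
    elem_lines = sections["Elements"]
    n_elems = int(elem_lines[0])
    tets, tris = [], []
    for line in elem_lines[1:1 + n_elems]:
        parts = line.split()
        etype = int(parts[1])
        n_tags = int(parts[2])
        conn = [remap[int(p)] for p in parts[3 + n_tags:]]
        if etype == 4:
            tets.append(conn)
        elif etype == 2:
            tris.append(conn)
    return (verts, np.asarray(tets, dtype=int).reshape(-1, 4),
            np.asarray(tris, dtype=int).reshape(-1, 3))


def _parse_msh4(sections):
    node_lines = [ln for ln in sections["Nodes"] if ln.strip()]
    header = node_lines[0].split()
    n_blocks, n_nodes = int(header[0]), int(header[1])
    ids = []
    coords = []
    pos = 1
    for _ in range(n_blocks):
        blk = node_lines[pos].split()
        n_in_block = int(blk[3])
        pos += 1
        blk_ids = [int(node_lines[pos + k]) for k in range(n_in_block)]
        pos += n_in_block
        for k in range(n_in_block):
            coords.append([float(x) for x in node_lines[pos + k].split()[:3]])
        pos += n_in_block
        ids.extend(blk_ids)
    verts = np.asarray(coords)
    remap = {nid: k for k, nid in enumerate(ids)}
    elem_lines = [ln for ln in sections["Elements"] if ln.strip()]
    n_blocks = int(elem_lines[0].split()[0])
    tets, tris = [], []
    pos = 1
    for _ in range(n_blocks):
        blk = elem_lines[pos].split()
        etype, n_in_block = int(blk[2]), int(blk[3])
        pos += 1
        for k in range(n_in_block):
            parts = [int(p) for p in elem_lines[pos + k].split()]
            conn = [remap[p] for p in parts[1:]]
            if etype == 4:
                tets.append(conn)
            elif etype == 2:
                tris.append(conn)
        pos += n_in_block
    if len(verts) != n_nodes:
        raise MeshIOError("MSH4 node count mismatch")
    return (verts, np.asarray(tets, dtype=int).reshape(-1, 4),
            np.asarray(tris, dtype=int).reshape(-1, 3))


def write_vtk(path: str | Path, vertices: np.ndarray,
              tets: np.ndarray | None = None, triangles: np.ndarray | None = None,
              point_data: dict[str, np.ndarray] | None = None,
              title: str = "endotwin mesh") -> None:
    """Write a legacy ASCII VTK unstructured grid (tets and/or triangles)."""
    v = np.asarray(vertices, dtype=float)
    cells = []
    types = []
    for arr, vtk_type in ((tets, 10), (triangles, 5)):
        if arr is None:
            continue
        for row in np.asarray(arr, dtype=int):
            cells.append([len(row)] + list(row))
            types.append(vtk_type)
    lines = ["# vtk DataFile Version 3.0", title, "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(v)} double"]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in v]
    total = sum(len(c) for c in cells)
    lines.append(f"CELLS {len(cells)} {total}")
    lines += [" ".join(str(i) for i in c) for c in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += [str(t) for t in types]
    if point_data:
        lines.append(f"POINT_DATA {len(v)}")
        for name, data in point_data.items():
            arr = np.asarray(data, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{x:.17g}" for x in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in arr]
    lines.append("")
    Path(path).write_text("\n".join(lines))


def read_vtk(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a legacy ASCII VTK unstructured grid; returns (vertices, tets, tris)."""
    tokens = Path(path).read_text().split()
    def find(word):
        for k, t in enumerate(tokens):
            if t == word:
                return k
        raise MeshIOError(f"{path}: missing {word} section")
    kp = find("POINTS")
    n_pts = int(tokens[kp + 1])
    verts = np.array(tokens[kp + 3:kp + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    kc = find("CELLS")
    n_cells = int(tokens[kc + 1])
    pos = kc + 3
    cells = []
    for _ in range(n_cells):
        n = int(tokens[pos])
        cells.append([int(t) for t in tokens[pos + 1:pos + 1 + n]])
        pos += n + 1
    kt = find("CELL_TYPES")
    ctypes = [int(t) for t in tokens[kt + 2:kt + 2 + n_cells]]
    tets = [c for c, t in zip(cells, ctypes) if t == 10]
    tris = [c for c, t in zip(cells, ctypes) if t == 5]
    return (verts, np.asarray(tets, dtype=int).reshape(-1, 4),
            np.asarray(tris, dtype=int).reshape(-1, 3))
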
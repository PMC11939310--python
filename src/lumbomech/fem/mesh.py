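"""Finite-element mesh container and text-based mesh I/O.

Volume meshes (Tet4, Hex8, Wedge6) and triangle shells (Tri3) are stored
in a single :class:`FEMesh` with one connectivity block per element type
and a per-element material id.  Surfaces travel as :class:`trimesh.Trimesh`
objects; volume meshes are written/read as legacy ASCII VTK unstructured
grids so they can be inspected in ParaView.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

# VTK cell type codes
VTK_CELL = {"Tet4": 10, "Hex8": 12, "Wedge6": 13, "Tri3": 5}
_VTK_CELL_INV = {v: k for k, v in VTK_CELL.items()}
NODES_PER_ELEM = {"Tet4": 4, "Hex8": 8, "Wedge6": 6, "Tri3": 3}


@dataclass
class ElementBlock:
    """Homogeneous block of elements of a single type.

    ``material_id`` holds one integer per element indexing into the mesh's
    material table; ``tags`` may carry named element subsets (e.g. the
    nucleus of a disc)."""

    kind: str
    conn: np.ndarray  # (nelem, nodes_per_elem) int
    material_id: np.ndarray | None = None
    tags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.conn = np.asarray(self.conn, dtype=int)
        if self.conn.ndim != 2 or self.conn.shape[1] != NODES_PER_ELEM[self.kind]:
            raise ValueError(f"bad connectivity shape for {self.kind}: {self.conn.shape}")
        if self.material_id is None:
            self.material_id = np.zeros(len(self.conn), dtype=int)
        else:
            self.material_id = np.asarray(self.material_id, dtype=int)

    @property
    def n(self) -> int:
        return len(self.conn)


@dataclass
class FEMesh:
    """Nodes + element blocks, in a consistent N-mm unit system."""

    nodes: np.ndarray  # (nnode, 3) float, mm
    blocks: list[ElementBlock] = field(default_factory=list)
    materials: list = field(default_factory=list)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        for b in self.blocks:
            if b.conn.size and b.conn.max() >= len(self.nodes):
                raise ValueError("connectivity index out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return sum(b.n for b in self.blocks)

    def block(self, kind: str) -> ElementBlock:
        for b in self.blocks:
            if b.kind == kind:
                return b
        raise KeyError(kind)

    def copy(self) -> "FEMesh":
        return FEMesh(
            self.nodes.copy(),
            [ElementBlock(b.kind, b.conn.copy(), b.material_id.copy(), dict(b.tags))
             for b in self.blocks],
            list(self.materials),
        )

    def content_hash(self) -> str:
        """Stable hash of geometry + connectivity, for reproducibility checks."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        for b in self.blocks:
            h.update(b.kind.encode())
            h.update(np.ascontiguousarray(b.conn).tobytes())
            h.update(np.ascontiguousarray(b.material_id).tobytes())
        return h.hexdigest()


def write_vtk(mesh: FEMesh, path, cell_fields: dict | None = None) -> None:
    """Write a legacy ASCII VTK unstructured grid with per-cell material ids."""
    lines = ["# vtk DataFile Version 3.0", "lumbomech mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} float"]
    for p in mesh.nodes:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    ncell = mesh.n_elements
    size = sum((b.conn.shape[1] + 1) * b.n for b in mesh.blocks)
    lines.append(f"CELLS {ncell} {size}")
    for b in mesh.blocks:
        npe = b.conn.shape[1]
        for row in b.conn:
            lines.append(str(npe) + " " + " ".join(map(str, row)))
    lines.append(f"CELL_TYPES {ncell}")
    for b in mesh.blocks:
        code = VTK_CELL[b.kind]
        lines.extend([str(code)] * b.n)
    lines.append(f"CELL_DATA {ncell}")
    lines.append("SCALARS material_id int 1")
    lines.append("LOOKUP_TABLE default")
    for b in mesh.blocks:
        lines.extend(map(str, b.material_id))
    for name, values in (cell_fields or {}).items():
        values = np.asarray(values, float).ravel()
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9g}" for v in values)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path) -> tuple[FEMesh, dict]:
    """Read back a legacy ASCII VTK unstructured grid written by :func:`write_vtk`."""
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(range(len(tokens)))

    def find(word, start=0):
        for i in range(start, len(tokens)):
            if tokens[i] == word:
                return i
        raise ValueError(f"{word} not found in {path}")

    i = find("POINTS")
    npts = int(tokens[i + 1])
    pts = np.array(tokens[i + 3:i + 3 + 3 * npts], float).reshape(npts, 3)
    i = find("CELLS")
    ncell = int(tokens[i + 1])
    j = i + 3
    conns = []
    for _ in range(ncell):
        k = int(tokens[j])
        conns.append([int(t) for t in tokens[j + 1:j + 1 + k]])
        j += k + 1
    i = find("CELL_TYPES")
    types = [int(t) for t in tokens[i + 2:i + 2 + ncell]]
    mat = np.zeros(ncell, int)
    fields: dict[str, np.ndarray] = {}
    try:
        i = find("CELL_DATA")
        j = i + 2
        while j < len(tokens) and tokens[j] == "SCALARS":
            name, typ = tokens[j + 1], tokens[j + 2]
            j += 6  # SCALARS name type 1 LOOKUP_TABLE default
            vals = np.array(tokens[j:j + ncell], float)
            if name == "material_id":
                mat = vals.astype(int)
            else:
                fields[name] = vals
            j += ncell
    except ValueError:
        pass
    # group contiguous cells of the same type into blocks
    blocks = []
    start = 0
    while start < ncell:
        end = start
        while end < ncell and types[end] == types[start]:
            end += 1
        kind = _VTK_CELL_INV[types[start]]
        blocks.append(ElementBlock(kind, np.array(conns[start:end], int),
                                   mat[start:end]))
        start = end
    return FEMesh(pts, blocks), fields


def write_surface(surface: trimesh.Trimesh, path) -> None:
    """Export a triangulated surface as STL or OBJ (by file extension)."""
    surface.export(path)


def read_surface(path) -> trimesh.Trimesh:
    m = trimesh.load(path, force="mesh")
    return m
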
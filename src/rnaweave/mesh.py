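"""Wireframe meshes: loading, validation, and built-in fixtures.

A mesh is a set of 3D vertices (nm) plus an undirected edge set,
optionally with faces.  The edge graph must be connected for a
single-strand design to exist.  Wavefront OBJ is supported as the
interchange format (``v``/``f``/``l`` records only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Mesh",
    "MeshError",
    "BUILTIN_NAMES",
    "builtin_mesh",
    "load_mesh",
    "write_obj",
    "validate_mesh",
]


class MeshError(ValueError):
    """Raised for malformed, degenerate, or disconnected meshes."""


@dataclass
class Mesh:
    """A 3D wireframe: vertices (nm), undirected edges, optional faces.

    Edges are stored as sorted ``(u, v)`` tuples with ``u < v``.  Faces,
    when present, are vertex-index cycles; their boundary edges must be
    a subset of ``edges``.
    """

    vertices: np.ndarray
    edges: list[tuple[int, int]]
    faces: list[list[int]] | None = None
    name: str = "mesh"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (N, 3) array")
        self.edges = [tuple(sorted(map(int, e))) for e in self.edges]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_length(self, edge_index: int) -> float:
        u, v = self.edges[edge_index]
        return float(np.linalg.norm(self.vertices[v] - self.vertices[u]))

    def edge_lengths(self) -> np.ndarray:
        return np.array([self.edge_length(i) for i in range(self.n_edges)])

    def adjacency(self) -> dict[int, list[tuple[int, int]]]:
        """vertex -> list of (edge index, other endpoint), edge-index order."""
        adj: dict[int, list[tuple[int, int]]] = {v: [] for v in range(self.n_vertices)}
        for i, (u, v) in enumerate(self.edges):
            adj[u].append((i, v))
            adj[v].append((i, u))
        return adj

    def is_connected(self) -> bool:
        if self.n_vertices == 0:
            return False
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            v = stack.pop()
            for _, w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n_vertices


def validate_mesh(mesh: Mesh) -> list[str]:
    """Return one diagnostic string per invariant violation (empty if valid)."""
    diags: list[str] = []
    n = mesh.n_vertices
    seen: set[tuple[int, int]] = set()
    in_range = True
    for u, v in mesh.edges:
        if u == v:
            diags.append(f"edge endpoints identical: ({u}, {v})")
            continue
        if not (0 <= u < n and 0 <= v < n):
            diags.append(f"edge endpoint out of range: ({u}, {v})")
            in_range = False
            continue
        if (u, v) in seen:
            diags.append(f"duplicate edge: ({u}, {v})")
        seen.add((u, v))
        if np.linalg.norm(mesh.vertices[v] - mesh.vertices[u]) <= 1e-12:
            diags.append(f"degenerate edge: ({u}, {v})")
    if in_range and not mesh.is_connected():
        diags.append("mesh not connected")
    if not np.all(np.isfinite(mesh.vertices)):
        diags.append("non-finite vertex coordinate")
    return diags


# ---------------------------------------------------------------------------
# OBJ I/O (minimal dialect: v, f, l; normals/textures/materials ignored)
# ---------------------------------------------------------------------------

def _obj_index(token: str, n_vertices: int, lineno: int) -> int:
    # "3/1/2" face tokens carry texture/normal refs after slashes
    head = token.split("/")[0]
    try:
        idx = int(head)
    except ValueError as exc:
        raise MeshError(f"line {lineno}: bad vertex index {token!r}") from exc
    if idx < 0:  # OBJ relative indexing
        idx = n_vertices + idx
    else:
        idx -= 1
    if not (0 <= idx < n_vertices):
        raise MeshError(f"line {lineno}: vertex index {token!r} out of range")
    return idx


def load_mesh(path: str, units: float = 1.0, name: str | None = None) -> Mesh:
    """Load a Wavefront OBJ file (``v``, ``f``, ``l`` records).

    Faces are decomposed into their boundary edges; duplicate edges are
    merged.  ``units`` rescales coordinates into nm.

    Raises :class:`MeshError` for unparsable records (with the line
    number), degenerate edges, or a disconnected edge graph.
    """
    vertices: list[list[float]] = []
    edge_set: set[tuple[int, int]] = set()
    faces: list[list[int]] = []

    with open(path) as fh:
        lines = fh.readlines()

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rec = parts[0]
        if rec == "v":
            if len(parts) < 4:
                raise MeshError(f"line {lineno}: vertex record needs 3 coordinates")
            try:
                vertices.append([float(x) * units for x in parts[1:4]])
            except ValueError as exc:
                raise MeshError(f"line {lineno}: bad coordinate in {line!r}") from exc
        elif rec == "f":
            if len(parts) < 4:
                raise MeshError(f"line {lineno}: face needs at least 3 vertices")
            cycle = [_obj_index(t, len(vertices), lineno) for t in parts[1:]]
            faces.append(cycle)
            for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                if a == b:
                    raise MeshError(f"line {lineno}: repeated vertex in face")
                edge_set.add(tuple(sorted((a, b))))
        elif rec == "l":
            if len(parts) < 3:
                raise MeshError(f"line {lineno}: line record needs 2 vertices")
            chain = [_obj_index(t, len(vertices), lineno) for t in parts[1:]]
            for a, b in zip(chain, chain[1:]):
                if a == b:
                    raise MeshError(f"line {lineno}: degenerate line segment")
                edge_set.add(tuple(sorted((a, b))))
        # all other record types ignored (vn, vt, o, g, s, usemtl, mtllib, ...)

    if not vertices:
        raise MeshError("no vertex records in OBJ file")
    if not edge_set:
        raise MeshError("no edge-bearing records (f or l) in OBJ file")

    mesh = Mesh(
        vertices=np.array(vertices),
        edges=sorted(edge_set),
        faces=faces or None,
        name=name or "obj-mesh",
    )
    for i, (u, v) in enumerate(mesh.edges):
        if mesh.edge_length(i) <= 1e-12:
            raise MeshError(f"degenerate edge: ({u}, {v})")
    if not mesh.is_connected():
        raise MeshError("mesh not connected")
    return mesh


def write_obj(mesh: Mesh, path: str) -> None:
    """Write the mesh as OBJ (``v`` + ``f`` for faces, ``l`` for bare edges)."""
    face_edges: set[tuple[int, int]] = set()
    with open(path, "w") as fh:
        fh.write(f"# rnaweave mesh: {mesh.name}\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.9f} {y:.9f} {z:.9f}\n")
        if mesh.faces:
            for cycle in mesh.faces:
                fh.write("f " + " ".join(str(i + 1) for i in cycle) + "\n")
                for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                    face_edges.add(tuple(sorted((a, b))))
        for u, v in mesh.edges:
            if (u, v) not in face_edges:
                fh.write(f"l {u + 1} {v + 1}\n")


# ---------------------------------------------------------------------------
# Built-in fixtures
# ---------------------------------------------------------------------------

BUILTIN_NAMES = (
    "tetrahedron",
    "bipyramid",
    "prism_triangulated",
    "cube",
    "dodecahedron",
    "grid",
)


def _scaled(points: Sequence[Sequence[float]], current_edge: float, target: float) -> np.ndarray:
    return np.asarray(points, dtype=float) * (target / current_edge)


def _edges_from_faces(faces: Iterable[Sequence[int]]) -> list[tuple[int, int]]:
    out: set[tuple[int, int]] = set()
    for cycle in faces:
        for a, b in zip(cycle, list(cycle[1:]) + [cycle[0]]):
            out.add(tuple(sorted((a, b))))
    return sorted(out)


def _faces_from_hull(points: np.ndarray) -> list[list[int]]:
    """Merge the convex hull's coplanar triangles into polygonal faces."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points)
    groups: dict[tuple, list[np.ndarray]] = {}
    for simplex, eq in zip(hull.simplices, hull.equations):
        key = tuple(np.round(eq, 6))
        groups.setdefault(key, []).append(simplex)
    faces: list[list[int]] = []
    for tris in groups.values():
        counts: dict[tuple[int, int], int] = {}
        for tri in tris:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                counts[tuple(sorted((int(a), int(b))))] = (
                    counts.get(tuple(sorted((int(a), int(b)))), 0) + 1
                )
        boundary = [e for e, c in counts.items() if c == 1]
        adj: dict[int, list[int]] = {}
        for a, b in boundary:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        start = min(adj)
        cycle = [start]
        prev = None
        while True:
            nxts = [w for w in adj[cycle[-1]] if w != prev]
            prev = cycle[-1]
            cycle.append(nxts[0])
            if cycle[-1] == start:
                cycle.pop()
                break
        faces.append(cycle)
    return faces


def _tetrahedron(scale: float) -> Mesh:
    pts = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
    faces = [[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]]
    verts = _scaled(pts, 2.0 * math.sqrt(2.0), scale)
    return Mesh(verts, _edges_from_faces(faces), faces, "tetrahedron")


def _bipyramid(scale: float) -> Mesh:
    # equilateral equator triangle (0, 1, 2) + apexes (3, 4); all edges equal
    r = 1.0 / math.sqrt(3.0)
    h = math.sqrt(2.0 / 3.0)
    pts = [
        (r * math.cos(a), r * math.sin(a), 0.0)
        for a in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)
    ] + [(0.0, 0.0, h), (0.0, 0.0, -h)]
    faces = [[0, 1, 3], [1, 2, 3], [2, 0, 3], [1, 0, 4], [2, 1, 4], [0, 2, 4]]
    verts = _scaled(pts, 1.0, scale)
    return Mesh(verts, _edges_from_faces(faces), faces, "bipyramid")


def _prism_triangulated(scale: float) -> Mesh:
    # triangular prism, side quads split by diagonals (0,4), (1,5), (2,3)
    r = 1.0 / math.sqrt(3.0)
    base = [(r * math.cos(a), r * math.sin(a)) for a in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)]
    pts = [(x, y, 0.0) for x, y in base] + [(x, y, 1.0) for x, y in base]
    faces = [
        [0, 2, 1],
        [3, 4, 5],
        [0, 1, 4],
        [0, 4, 3],
        [1, 2, 5],
        [1, 5, 4],
        [2, 0, 3],
        [2, 3, 5],
    ]
    verts = _scaled(pts, 1.0, scale)
    return Mesh(verts, _edges_from_faces(faces), faces, "prism_triangulated")


def _cube(scale: float) -> Mesh:
    pts = [(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)]
    faces = [
        [0, 1, 3, 2],
        [4, 6, 7, 5],
        [0, 4, 5, 1],
        [2, 3, 7, 6],
        [0, 2, 6, 4],
        [1, 5, 7, 3],
    ]
    verts = _scaled(pts, 1.0, scale)
    return Mesh(verts, _edges_from_faces(faces), faces, "cube")


def _dodecahedron(scale: float) -> Mesh:
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    inv = 1.0 / phi
    pts: list[tuple[float, float, float]] = []
    pts += [(x, y, z) for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)]
    pts += [(0, y, z) for y in (-inv, inv) for z in (-phi, phi)]
    pts += [(x, y, 0) for x in (-inv, inv) for y in (-phi, phi)]
    pts += [(x, 0, z) for x in (-phi, phi) for z in (-inv, inv)]
    verts = _scaled(pts, 2.0 * inv, scale)
    faces = _faces_from_hull(verts)
    return Mesh(verts, _edges_from_faces(faces), faces, "dodecahedron")


def _grid(scale: float, nx: int, ny: int, nz: int) -> Mesh:
    """Axis-aligned lattice of nx*ny*nz unit cells (a non-polyhedral mesh)."""
    dims = (nx + 1, ny + 1, nz + 1)
    index = {}
    pts = []
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                index[(i, j, k)] = len(pts)
                pts.append((i * scale, j * scale, k * scale))
    edges = []
    for (i, j, k), a in index.items():
        for di, dj, dk in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = (i + di, j + dj, k + dk)
            if nb in index:
                edges.append(tuple(sorted((a, index[nb]))))
    return Mesh(np.array(pts, dtype=float), sorted(set(edges)), None, f"grid{nx}x{ny}x{nz}")


def builtin_mesh(
    name: str,
    edge_scale: float = 10.0,
    nx: int = 2,
    ny: int = 2,
    nz: int = 2,
) -> Mesh:
    """Return a canonical built-in mesh scaled to a nominal edge length (nm).

    Names: ``tetrahedron``, ``bipyramid``, ``prism_triangulated``,
    ``cube``, ``dodecahedron``, ``grid`` (with ``nx``/``ny``/``nz`` cells).
    """
    if edge_scale <= 0:
        raise MeshError("edge_scale must be positive")
    if name == "tetrahedron":
        return _tetrahedron(edge_scale)
    if name == "bipyramid":
        return _bipyramid(edge_scale)
    if name == "prism_triangulated":
        return _prism_triangulated(edge_scale)
    if name == "cube":
        return _cube(edge_scale)
    if name == "dodecahedron":
        return _dodecahedron(edge_scale)
    if name == "grid":
        return _grid(edge_scale, nx, ny, nz)
    raise MeshError(f"unknown builtin mesh {name!r}; choose from {BUILTIN_NAMES}")
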
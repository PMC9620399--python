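"""Strand routing over a spanning tree with kissing-loop hairpin extrusions.

The strand traverses every spanning-tree edge twice, once per direction,
and extrudes a half-edge hairpin along each discarded (non-tree) edge at
both of its endpoints.  Hairpin pairs across an edge later become
kissing-loop connectors.

Unknottedness is obtained by construction: at each vertex the incident
strand ends are placed as ports on a small sphere in cyclic (rotation)
order, and the traversal always connects an incoming port to the next
port in that cyclic order.  All vertex matchings are therefore chords
between adjacent ports and can never cross, so the closed routing bounds
a ribbon tree (a disk) and is an unknot.  :func:`routing_centerline` plus
:func:`rnaweave.knots.knot_determinant` provide a diagnostic check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh, MeshError

__all__ = [
    "RoutingEvent",
    "PortOrder",
    "RoutingPlan",
    "spanning_tree",
    "route",
    "vertex_matching",
    "is_noncrossing",
    "enumerate_noncrossing_matchings",
    "routing_centerline",
]


@dataclass(frozen=True)
class RoutingEvent:
    """One step of the cyclic strand traversal.

    ``kind == "tree"``: the strand runs along tree edge ``edge`` from
    vertex ``u`` to vertex ``v``.
    ``kind == "kl"``: the strand makes a kissing-loop hairpin at vertex
    ``u`` along non-tree edge ``edge`` (whose far endpoint is ``v``).
    """

    kind: str
    edge: int
    u: int
    v: int


@dataclass
class PortOrder:
    """Cyclic order of strand ports on the sphere around one vertex.

    ``items`` lists the incident routing elements (tree edges and
    kissing-loop half-edges) in cyclic order by projected angle; each
    item owns two consecutive ports (out-port ``2*i``, in-port
    ``2*i + 1``).
    """

    vertex: int
    items: list[tuple[str, int, int]]  # (kind, edge index, far vertex)
    directions: list[np.ndarray]  # unit vectors, same order as items
    normal: np.ndarray  # projection-plane normal used for the angle sort

    @property
    def n_ports(self) -> int:
        return 2 * len(self.items)


@dataclass
class RoutingPlan:
    tree_edges: list[int]
    kl_edges: list[int]
    traversal: list[RoutingEvent]
    port_orders: dict[int, PortOrder]
    vertex_matchings: dict[int, list[tuple[int, int]]]
    nick: str = "mid"  # "mid": nick at midpoint of first tree edge; "start": at its start vertex

    def kl_pairs(self) -> list[int]:
        """Edge ids of the kissing-loop pairs (one per non-tree edge)."""
        return list(self.kl_edges)

    def to_json_dict(self) -> dict:
        return {
            "tree_edges": self.tree_edges,
            "kl_edges": self.kl_edges,
            "nick": self.nick,
            "traversal": [
                {"kind": e.kind, "edge": e.edge, "u": e.u, "v": e.v} for e in self.traversal
            ],
            "vertex_matchings": {str(v): m for v, m in self.vertex_matchings.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=1)


# ---------------------------------------------------------------------------
# Spanning trees
# ---------------------------------------------------------------------------

def spanning_tree(mesh: Mesh, strategy: str = "bfs", seed: int = 0) -> list[int]:
    """Return edge indices of a spanning tree (deterministic per strategy+seed).

    Strategies: ``bfs`` (from vertex 0, edge-index tie-break),
    ``prim_shortest`` (Prim, shortest edge first), ``seeded_random``
    (Kruskal on a seed-shuffled edge order).
    """
    if not mesh.is_connected():
        raise MeshError("mesh not connected")
    adj = mesh.adjacency()

    if strategy == "bfs":
        from collections import deque

        tree: list[int] = []
        seen = {0}
        queue = deque([0])
        while queue:
            v = queue.popleft()
            for ei, w in sorted(adj[v]):
                if w not in seen:
                    seen.add(w)
                    tree.append(ei)
                    queue.append(w)
        return sorted(tree)

    if strategy == "prim_shortest":
        import heapq

        lengths = mesh.edge_lengths()
        tree = []
        seen = {0}
        heap = [(lengths[ei], ei, w) for ei, w in adj[0]]
        heapq.heapify(heap)
        while heap and len(seen) < mesh.n_vertices:
            _, ei, w = heapq.heappop(heap)
            if w in seen:
                continue
            seen.add(w)
            tree.append(ei)
            for ej, x in adj[w]:
                if x not in seen:
                    heapq.heappush(heap, (lengths[ej], ej, x))
        return sorted(tree)

    if strategy == "seeded_random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(mesh.n_edges)
        parent = list(range(mesh.n_vertices))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        tree = []
        for ei in order:
            u, v = mesh.edges[ei]
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
                tree.append(int(ei))
        return sorted(tree)

    raise ValueError(f"unknown spanning-tree strategy {strategy!r}")


def _check_tree(mesh: Mesh, tree: list[int]) -> None:
    if len(tree) != mesh.n_vertices - 1:
        raise ValueError("not a spanning tree: wrong edge count")
    parent = list(range(mesh.n_vertices))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ei in tree:
        u, v = mesh.edges[ei]
        ru, rv = find(u), find(v)
        if ru == rv:
            raise ValueError("not a spanning tree: contains a cycle")
        parent[ru] = rv


# ---------------------------------------------------------------------------
# Rotation systems and the double-trace boundary walk
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length direction")
    return v / n


def _port_order(mesh: Mesh, vertex: int, items: list[tuple[str, int, int]]) -> PortOrder:
    """Sort incident items cyclically by angle in a projection plane."""
    dirs = [_unit(mesh.vertices[far] - mesh.vertices[vertex]) for _, _, far in items]
    normal = np.sum(dirs, axis=0)
    if np.linalg.norm(normal) < 1e-8:
        if len(dirs) >= 2:
            normal = np.cross(dirs[0], dirs[1])
        if np.linalg.norm(normal) < 1e-8:
            # collinear incident edges: any perpendicular works
            probe = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(probe, dirs[0])) > 0.9:
                probe = np.array([0.0, 1.0, 0.0])
            normal = np.cross(dirs[0], probe)
    normal = _unit(normal)
    ref = dirs[0] - np.dot(dirs[0], normal) * normal
    if np.linalg.norm(ref) < 1e-8:
        probe = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(probe, normal)) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        ref = probe - np.dot(probe, normal) * normal
    ref = _unit(ref)
    ref2 = np.cross(normal, ref)

    def key(i: int):
        d = dirs[i]
        ang = float(np.arctan2(np.dot(d, ref2), np.dot(d, ref)))
        return (ang, items[i][0], items[i][1])

    order = sorted(range(len(items)), key=key)
    return PortOrder(
        vertex=vertex,
        items=[items[i] for i in order],
        directions=[dirs[i] for i in order],
        normal=normal,
    )


def route(mesh: Mesh, tree: list[int], nick: str = "mid") -> RoutingPlan:
    """Compute the cyclic double routing of ``mesh`` over spanning tree ``tree``.

    Every tree edge appears twice (antiparallel) in the traversal; every
    non-tree edge contributes one hairpin event at each endpoint.  The
    connection at each vertex always proceeds to the next item in that
    vertex's cyclic port order, which makes every vertex matching
    non-crossing by construction.
    """
    _check_tree(mesh, tree)
    if nick not in ("mid", "start"):
        raise ValueError("nick must be 'mid' or 'start'")
    tree_set = set(tree)
    kl_edges = [i for i in range(mesh.n_edges) if i not in tree_set]

    incident: dict[int, list[tuple[str, int, int]]] = {v: [] for v in range(mesh.n_vertices)}
    for ei, (u, v) in enumerate(mesh.edges):
        kind = "tree" if ei in tree_set else "kl"
        incident[u].append((kind, ei, v))
        incident[v].append((kind, ei, u))

    port_orders = {v: _port_order(mesh, v, its) for v, its in incident.items()}
    item_index = {
        (v, it): i for v, po in port_orders.items() for i, it in enumerate(po.items)
    }

    # start at vertex 0, departing via its lowest-index tree edge
    v0 = 0
    tree_items = [
        (i, it) for i, it in enumerate(port_orders[v0].items) if it[0] == "tree"
    ]
    i0 = min(tree_items, key=lambda t: t[1][1])[0]

    traversal: list[RoutingEvent] = []
    matchings: dict[int, list[tuple[int, int]]] = {
        v: [] for v in range(mesh.n_vertices)
    }
    v, depart = v0, i0
    guard = 0
    limit = 4 * (mesh.n_edges + mesh.n_vertices) + 16
    while True:
        guard += 1
        if guard > limit:
            raise RuntimeError("routing walk failed to close")
        kind, ei, far = port_orders[v].items[depart]
        if kind == "tree":
            traversal.append(RoutingEvent("tree", ei, v, far))
            arrive_vertex = far
            arrive_idx = item_index[(far, ("tree", ei, v))]
        else:
            traversal.append(RoutingEvent("kl", ei, v, far))
            arrive_vertex = v
            arrive_idx = depart
        nxt = (arrive_idx + 1) % len(port_orders[arrive_vertex].items)
        matchings[arrive_vertex].append((2 * arrive_idx + 1, 2 * nxt))
        v, depart = arrive_vertex, nxt
        if (v, depart) == (v0, i0):
            break

    n_tree_events = sum(1 for e in traversal if e.kind == "tree")
    n_kl_events = sum(1 for e in traversal if e.kind == "kl")
    assert n_tree_events == 2 * (mesh.n_vertices - 1)
    assert n_kl_events == 2 * len(kl_edges)

    return RoutingPlan(
        tree_edges=sorted(tree),
        kl_edges=kl_edges,
        traversal=traversal,
        port_orders=port_orders,
        vertex_matchings=matchings,
        nick=nick,
    )


# ---------------------------------------------------------------------------
# Non-crossing matchings
# ---------------------------------------------------------------------------

def _crosses(a: tuple[int, int], b: tuple[int, int], n: int) -> bool:
    """Do chords a and b cross in the cyclic order of n ports?"""
    a1, a2 = a
    inside = {(a1 + k) % n for k in range(1, (a2 - a1) % n)}
    return (b[0] in inside) != (b[1] in inside)


def is_noncrossing(pairs: list[tuple[int, int]], n_ports: int) -> bool:
    """True iff no two chords cross in cyclic port order."""
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            if _crosses(pairs[i], pairs[j], n_ports):
                return False
    return True


def enumerate_noncrossing_matchings(n_ports: int) -> list[list[tuple[int, int]]]:
    """Brute force: all perfect matchings of ``n_ports`` ports, crossing-free only.

    Intended as a test oracle; feasible up to ~14 ports.
    """
    if n_ports % 2:
        raise ValueError("odd number of ports")

    results: list[list[tuple[int, int]]] = []

    def rec(remaining: list[int], acc: list[tuple[int, int]]) -> None:
        if not remaining:
            if is_noncrossing(acc, n_ports):
                results.append(list(acc))
            return
        first = remaining[0]
        for k in range(1, len(remaining)):
            pair = (first, remaining[k])
            rest = remaining[1:k] + remaining[k + 1 :]
            rec(rest, acc + [pair])

    rec(list(range(n_ports)), [])
    return results


def vertex_matching(port_order: PortOrder) -> list[tuple[int, int]]:
    """The construction's matching at a vertex: in-port of each item to the
    out-port of the next item in cyclic order (always non-crossing)."""
    k = len(port_order.items)
    return [(2 * i + 1, (2 * i + 2) % (2 * k)) for i in range(k)]


# ---------------------------------------------------------------------------
# Routed centerline (for the knot diagnostic)
# ---------------------------------------------------------------------------

def routing_centerline(
    mesh: Mesh,
    plan: RoutingPlan,
    sphere_frac: float = 0.18,
    lateral_frac: float = 0.3,
    stub_frac: float = 0.45,
) -> np.ndarray:
    """Closed 3D polyline tracing the strand routing.

    Each vertex is expanded to a small sphere (radius ``sphere_frac`` of
    the shortest edge); every port sits near its edge direction, offset
    tangentially so the two antiparallel passes of an edge are distinct.
    Kissing-loop hairpins extend ``stub_frac`` of the way along their
    edge.  Consecutive points are joined by straight segments; the
    polyline is cyclic (last point connects to the first).
    """
    min_len = float(np.min(mesh.edge_lengths()))
    r = sphere_frac * min_len
    eps = lateral_frac * r

    def port_point(vertex: int, item: tuple[str, int, int], plus: bool) -> np.ndarray:
        po = plan.port_orders[vertex]
        i = po.items.index(item)
        d = po.directions[i]
        t = np.cross(po.normal, d)
        tn = np.linalg.norm(t)
        if tn < 1e-9:
            probe = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(probe, d)) > 0.9:
                probe = np.array([0.0, 1.0, 0.0])
            t = np.cross(probe, d)
            tn = np.linalg.norm(t)
        t = t / tn
        sign = 1.0 if plus else -1.0
        return mesh.vertices[vertex] + r * d + sign * eps * t

    pts: list[np.ndarray] = []
    for ev in plan.traversal:
        if ev.kind == "tree":
            item_u = ("tree", ev.edge, ev.v)
            item_v = ("tree", ev.edge, ev.u)
            pts.append(port_point(ev.u, item_u, plus=False))
            pts.append(port_point(ev.v, item_v, plus=True))
        else:
            item = ("kl", ev.edge, ev.v)
            d = _unit(mesh.vertices[ev.v] - mesh.vertices[ev.u])
            tip = mesh.vertices[ev.u] + stub_frac * np.linalg.norm(
                mesh.vertices[ev.v] - mesh.vertices[ev.u]
            ) * d
            pts.append(port_point(ev.u, item, plus=False))
            pts.append(tip)
            pts.append(port_point(ev.u, item, plus=True))
    return np.array(pts)
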
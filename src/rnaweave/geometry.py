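"""A-form helix embedding of a routed design.

Every mesh edge is rendered as an idealized rigid A-form duplex along
the edge axis.  Non-tree edges are split into two hairpin semi-helices
joined mid-edge by a coaxial kissing-loop duplex, so the pair acts as
one effectively contiguous helix.  Per-edge rotation phases and
per-vertex-transition unpaired linker counts are chosen by a seeded
coordinate-descent optimizer that minimizes cross-vertex backbone strain.
Coordinates are idealized; relaxation is left to downstream simulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh
from .routing import RoutingPlan

__all__ = [
    "HelixParams",
    "HelixFrame",
    "Domain",
    "Transition",
    "EmbeddedDesign",
    "bp_count_for_edge",
    "split_kl_edge",
    "optimize_phases_and_linkers",
    "nucleotide_coordinates",
    "open_variant_coordinates",
    "radius_of_gyration",
    "embed_design",
]


@dataclass
class HelixParams:
    """Geometric parameters of the helix model (A-form RNA defaults)."""

    rise_per_bp: float = 0.281  # nm
    twist_per_bp: float = 32.7  # degrees (~11 bp/turn)
    helix_radius: float = 1.15  # nm (backbone radius)
    kl_pair_len: int = 6  # bases in the loop-loop duplex
    kl_flank_unpaired: int = 3  # unpaired bases flanking each loop
    max_linkers_per_transition: int = 6
    backbone_phase_offset: float = 165.0  # degrees between the two backbones
    linker_weight: float = 0.25  # w: weight of the angular-mismatch term
    linker_slack_cost: float = 0.05  # small per-linker penalty

    def validate(self) -> None:
        if min(self.rise_per_bp, self.helix_radius) <= 0:
            raise ValueError("helix dimensions must be positive")
        if not (0 < self.twist_per_bp < 360):
            raise ValueError("twist_per_bp must be in (0, 360)")
        if self.kl_pair_len < 4:
            raise ValueError("kl_pair_len must be >= 4")
        if self.kl_flank_unpaired < 0 or self.max_linkers_per_transition < 0:
            raise ValueError("counts must be non-negative")

    @property
    def min_edge_bp(self) -> int:
        """Smallest usable duplex length (room for a kissing-loop split)."""
        return self.kl_pair_len + 2

    @property
    def twist_rad(self) -> float:
        return math.radians(self.twist_per_bp)

    @property
    def backbone_offset_rad(self) -> float:
        return math.radians(self.backbone_phase_offset)

    def backbone_step(self) -> float:
        """Ideal consecutive intra-strand backbone distance (helix chord)."""
        chord = 2.0 * self.helix_radius * math.sin(self.twist_rad / 2.0)
        return math.sqrt(self.rise_per_bp**2 + chord**2)


def bp_count_for_edge(edge_length: float, params: HelixParams) -> int:
    """Discretize an edge length into base pairs (rounded, clamped below)."""
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    bp = round(edge_length / params.rise_per_bp)
    if bp < params.min_edge_bp:
        warnings.warn(
            f"edge of {edge_length:.3f} nm clamped to minimum {params.min_edge_bp} bp",
            stacklevel=2,
        )
        bp = params.min_edge_bp
    return int(bp)


def split_kl_edge(edge_bp: int, params: HelixParams) -> tuple[int, int]:
    """Split a non-tree edge's bp count into the two hairpin stems.

    ``stem_a + kl_pair_len + stem_b == edge_bp`` with a balanced split
    (``|stem_a - stem_b| <= 1``); when odd, the longer stem (``stem_b``)
    is placed on the lower-vertex-index side of the edge.
    """
    rem = edge_bp - params.kl_pair_len
    if rem < 2:
        raise ValueError(
            f"edge of {edge_bp} bp too short for a kissing-loop connector "
            f"(needs >= {params.kl_pair_len + 2})"
        )
    stem_a = rem // 2
    stem_b = rem - stem_a
    return stem_a, stem_b


# ---------------------------------------------------------------------------
# Frames, domains, transitions
# ---------------------------------------------------------------------------


@dataclass
class HelixFrame:
    """Rigid helix along one edge: axis line, perpendicular basis, phase."""

    origin: np.ndarray  # vertex the rows count from
    axis: np.ndarray  # unit vector, direction of increasing row
    n1: np.ndarray  # unit, perpendicular to axis
    n2: np.ndarray  # axis x n1
    bp: int
    offset0: float  # distance from origin to the row-0 base-pair plane
    phase: float = 0.0  # radians

    def backbone_point(self, row: float, strand_b: bool, params: HelixParams) -> np.ndarray:
        ang = self.phase + row * params.twist_rad
        if strand_b:
            ang += params.backbone_offset_rad
        c = self.origin + (self.offset0 + row * params.rise_per_bp) * self.axis
        return c + params.helix_radius * (math.cos(ang) * self.n1 + math.sin(ang) * self.n2)

    def backbone_tangent(
        self, row: float, strand_b: bool, direction: int, params: HelixParams
    ) -> np.ndarray:
        """Unit tangent of the backbone helix at ``row``; ``direction`` is
        +1 when the strand runs toward increasing rows, else -1."""
        ang = self.phase + row * params.twist_rad
        if strand_b:
            ang += params.backbone_offset_rad
        t = (
            params.rise_per_bp * self.axis
            + params.helix_radius
            * params.twist_rad
            * (-math.sin(ang) * self.n1 + math.cos(ang) * self.n2)
        )
        t = t * float(direction)
        return t / np.linalg.norm(t)


def _frame_for_edge(p0: np.ndarray, p1: np.ndarray, bp: int, params: HelixParams) -> HelixFrame:
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    axis = axis / length
    probe = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(probe, axis))) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    n1 = probe - float(np.dot(probe, axis)) * axis
    n1 = n1 / np.linalg.norm(n1)
    n2 = np.cross(axis, n1)
    offset0 = (length - (bp - 1) * params.rise_per_bp) / 2.0
    return HelixFrame(origin=p0.copy(), axis=axis, n1=n1, n2=n2, bp=bp, offset0=offset0)


@dataclass
class Domain:
    """One stretch of the strand: a helical run, a loop, or a linker."""

    kind: str  # stem5 | stem3 | kl_stem5 | kl_stem3 | kl_loop | linker
    edge: int | None
    length: int
    rows: list[int] | None = None  # helix rows in strand order (helical part)
    strand_b: bool = False
    flank: int = 0  # kl_loop: unpaired bases on each side of the paired rows
    transition: int | None = None  # linker: transition index


@dataclass
class Transition:
    """A cross-vertex backbone jump between two helical domains."""

    vertex: int
    # (edge, row, strand_b, direction) of the exit and entry backbone points
    exit_spec: tuple[int, int, bool, int]
    entry_spec: tuple[int, int, bool, int]


@dataclass
class EmbeddedDesign:
    """Nucleotide-level embedding: frames, strand layout, linkers, coords."""

    mesh: Mesh
    plan: RoutingPlan
    params: HelixParams
    frames: dict[int, HelixFrame]
    kl_splits: dict[int, tuple[int, int]]
    domains: list[Domain]
    transitions: list[Transition]
    linker_counts: list[int]
    cost: float = math.nan
    cost_history: list[float] = field(default_factory=list)
    converged: bool = True
    _coords: np.ndarray | None = None

    @property
    def total_length(self) -> int:
        return sum(d.length for d in self.domains)

    def annotations(self) -> list[str]:
        """Domain kind per nucleotide, in strand order."""
        out: list[str] = []
        for d in self.domains:
            out.extend([d.kind] * d.length)
        return out

    def coordinates(self) -> np.ndarray:
        if self._coords is None:
            self._coords = nucleotide_coordinates(self)
        return self._coords


# ---------------------------------------------------------------------------
# Strand layout
# ---------------------------------------------------------------------------


def _edge_frames(
    mesh: Mesh, plan: RoutingPlan, params: HelixParams
) -> tuple[dict[int, HelixFrame], dict[int, tuple[int, int]]]:
    """Helix frames and kissing-loop splits for every edge.

    Tree-edge frames run along the first-traversed direction; non-tree
    frames run from the lower vertex index (which hosts ``stem_b``, the
    longer stem of an odd split) to the higher.
    """
    frames: dict[int, HelixFrame] = {}
    kl_splits: dict[int, tuple[int, int]] = {}
    first_dir: dict[int, tuple[int, int]] = {}
    for ev in plan.traversal:
        if ev.kind == "tree" and ev.edge not in first_dir:
            first_dir[ev.edge] = (ev.u, ev.v)
    for ei in plan.tree_edges:
        u, v = first_dir[ei]
        bp = bp_count_for_edge(float(np.linalg.norm(mesh.vertices[v] - mesh.vertices[u])), params)
        frames[ei] = _frame_for_edge(mesh.vertices[u], mesh.vertices[v], bp, params)
    for ei in plan.kl_edges:
        u, v = mesh.edges[ei]  # u < v by Mesh normalization
        bp = bp_count_for_edge(float(np.linalg.norm(mesh.vertices[v] - mesh.vertices[u])), params)
        stem_a, stem_b = split_kl_edge(bp, params)
        kl_splits[ei] = (stem_a, stem_b)
        frames[ei] = _frame_for_edge(mesh.vertices[u], mesh.vertices[v], bp, params)
    return frames, kl_splits


def _event_domains(
    ev, frames: dict[int, HelixFrame], kl_splits: dict[int, tuple[int, int]],
    seen_tree: set[int], params: HelixParams, mesh: Mesh,
) -> list[Domain]:
    """Domains contributed by a single traversal event, in strand order."""
    if ev.kind == "tree":
        n = frames[ev.edge].bp
        if ev.edge not in seen_tree:
            seen_tree.add(ev.edge)
            return [Domain("stem5", ev.edge, n, rows=list(range(n)), strand_b=False)]
        return [Domain("stem3", ev.edge, n, rows=list(range(n - 1, -1, -1)), strand_b=True)]

    stem_a, stem_b = kl_splits[ev.edge]
    total = stem_a + params.kl_pair_len + stem_b
    u_low, _ = mesh.edges[ev.edge]
    f = params.kl_flank_unpaired
    k = params.kl_pair_len
    if ev.u == u_low:
        # hairpin anchored at the frame origin: stem_b rows ascending
        s = stem_b
        stem_rows = list(range(s))
        loop_rows = list(range(s, s + k))
        return [
            Domain("kl_stem5", ev.edge, s, rows=stem_rows, strand_b=False),
            Domain("kl_loop", ev.edge, k + 2 * f, rows=loop_rows, strand_b=False, flank=f),
            Domain("kl_stem3", ev.edge, s, rows=stem_rows[::-1], strand_b=True),
        ]
    # hairpin anchored at the far end: stem_a rows descending
    s = stem_a
    stem_rows = list(range(total - 1, total - s - 1, -1))
    loop_rows = list(range(total - s - 1, total - s - 1 - k, -1))
    return [
        Domain("kl_stem5", ev.edge, s, rows=stem_rows, strand_b=True),
        Domain("kl_loop", ev.edge, k + 2 * f, rows=loop_rows, strand_b=True, flank=f),
        Domain("kl_stem3", ev.edge, s, rows=stem_rows[::-1], strand_b=False),
    ]


def _build_layout(
    mesh: Mesh, plan: RoutingPlan, params: HelixParams
) -> tuple[dict[int, HelixFrame], dict[int, tuple[int, int]], list[Domain], list[Transition]]:
    """Strand-ordered domain list plus the cross-vertex transitions.

    With the default mid-edge nick, the first tree edge's outbound pass
    is split in half: the strand starts at its midpoint and ends just
    before it, so every vertex transition is a real (linker-eligible)
    transition.  With ``nick == "start"`` the strand starts at the first
    vertex and the wrap-around boundary carries no linkers.
    """
    frames, kl_splits = _edge_frames(mesh, plan, params)
    seen_tree: set[int] = set()
    per_event: list[list[Domain]] = [
        _event_domains(ev, frames, kl_splits, seen_tree, params, mesh)
        for ev in plan.traversal
    ]

    domains: list[Domain] = []
    transitions: list[Transition] = []

    def endpoint_spec(d: Domain, start: bool) -> tuple[int, int, bool, int]:
        rows = d.rows
        direction = 1 if (len(rows) == 1 or rows[-1] > rows[0]) else -1
        row = rows[0] if start else rows[-1]
        return (d.edge, row, d.strand_b, direction)

    def add_transition(vertex: int, prev: Domain, nxt: Domain) -> None:
        transitions.append(
            Transition(
                vertex=vertex,
                exit_spec=endpoint_spec(prev, start=False),
                entry_spec=endpoint_spec(nxt, start=True),
            )
        )
        domains.append(
            Domain("linker", None, 0, transition=len(transitions) - 1)
        )

    first_ev = plan.traversal[0]
    tail_fragment: Domain | None = None
    if plan.nick == "mid":
        lead = per_event[0][0]
        n = lead.length
        k = n // 2
        tail_fragment = Domain("stem5", lead.edge, k, rows=list(range(k)), strand_b=False)
        per_event[0] = [Domain("stem5", lead.edge, n - k, rows=list(range(k, n)), strand_b=False)]

    for i, doms in enumerate(per_event):
        if i > 0:
            prev_ev, ev = plan.traversal[i - 1], plan.traversal[i]
            vertex = prev_ev.u if prev_ev.kind == "kl" else prev_ev.v
            add_transition(vertex, domains[-1], doms[0])
        domains.extend(doms)

    if plan.nick == "mid":
        last_ev = plan.traversal[-1]
        vertex = last_ev.u if last_ev.kind == "kl" else last_ev.v
        add_transition(vertex, domains[-1], tail_fragment)
        domains.append(tail_fragment)

    return frames, kl_splits, domains, transitions


# ---------------------------------------------------------------------------
# Phase / linker optimization
# ---------------------------------------------------------------------------


def _transition_geometry(
    t: Transition, frames: dict[int, HelixFrame], params: HelixParams
) -> tuple[float, float]:
    """(backbone gap distance, angular mismatch in radians) for a transition."""
    e1, row1, sb1, dir1 = t.exit_spec
    e2, row2, sb2, dir2 = t.entry_spec
    p_out = frames[e1].backbone_point(row1, sb1, params)
    p_in = frames[e2].backbone_point(row2, sb2, params)
    chord = p_in - p_out
    g = float(np.linalg.norm(chord))
    if g < 1e-9:
        return g, 0.0
    chord = chord / g
    t_out = frames[e1].backbone_tangent(row1, sb1, dir1, params)
    t_in = frames[e2].backbone_tangent(row2, sb2, dir2, params)
    a1 = math.acos(max(-1.0, min(1.0, float(np.dot(t_out, chord)))))
    a2 = math.acos(max(-1.0, min(1.0, float(np.dot(chord, t_in)))))
    return g, a1 + a2


def _transition_cost(gap: float, ang: float, linkers: int, params: HelixParams) -> float:
    d0 = params.backbone_step()
    stretch = abs(gap - (linkers + 1) * d0)
    return stretch + params.linker_weight * ang + params.linker_slack_cost * linkers


def _best_linkers(gap: float, ang: float, params: HelixParams) -> tuple[int, float]:
    best = (0, _transition_cost(gap, ang, 0, params))
    for L in range(1, params.max_linkers_per_transition + 1):
        c = _transition_cost(gap, ang, L, params)
        if c < best[1]:
            best = (L, c)
    return best


def optimize_phases_and_linkers(
    mesh: Mesh,
    plan: RoutingPlan,
    params: HelixParams | None = None,
    seed: int = 0,
    max_iters: int = 60,
    phase_grid: int = 48,
    tol: float = 1e-9,
) -> EmbeddedDesign:
    """Assign per-edge helix phases and per-transition linker counts.

    Minimizes ``J = sum over transitions of [|gap - (L+1)*step| +
    w * angular mismatch + slack * L]`` by coordinate descent: exact
    integer updates of each linker count interleaved with a grid-refined
    scan of each edge phase.  Deterministic for a given seed.  The cost
    never increases across accepted steps; if the iteration cap is hit
    the best-found embedding is returned with ``converged = False``.
    """
    params = params or HelixParams()
    params.validate()
    frames, kl_splits, domains, transitions = _build_layout(mesh, plan, params)

    rng = np.random.default_rng(seed)
    edge_ids = sorted(frames)
    for ei in edge_ids:
        frames[ei].phase = float(rng.uniform(0.0, 2.0 * math.pi))

    linkers = [0] * len(transitions)
    touching: dict[int, list[int]] = {ei: [] for ei in edge_ids}
    for ti, t in enumerate(transitions):
        touching[t.exit_spec[0]].append(ti)
        if t.entry_spec[0] != t.exit_spec[0]:
            touching[t.entry_spec[0]].append(ti)

    def trans_cost(ti: int) -> float:
        g, ang = _transition_geometry(transitions[ti], frames, params)
        return _transition_cost(g, ang, linkers[ti], params)

    def total_cost() -> float:
        return sum(trans_cost(ti) for ti in range(len(transitions)))

    cost = total_cost()
    history = [cost]
    converged = False
    for _ in range(max_iters):
        # exact linker updates
        for ti in range(len(transitions)):
            g, ang = _transition_geometry(transitions[ti], frames, params)
            L, _ = _best_linkers(g, ang, params)
            linkers[ti] = L
        # phase scans (coarse grid then one refinement), keeping current
        # phase as a candidate so the step can only improve
        for ei in edge_ids:
            tids = touching[ei]
            if not tids:
                continue

            def local(phi: float) -> float:
                frames[ei].phase = phi
                return sum(trans_cost(ti) for ti in tids)

            current = frames[ei].phase
            best_phi, best_c = current, local(current)
            step = 2.0 * math.pi / phase_grid
            for k in range(phase_grid):
                phi = k * step
                c = local(phi)
                if c < best_c:
                    best_phi, best_c = phi, c
            for k in range(-8, 9):
                phi = best_phi + k * step / 9.0
                c = local(phi)
                if c < best_c:
                    best_phi, best_c = phi, c
            frames[ei].phase = best_phi
        new_cost = total_cost()
        history.append(new_cost)
        if cost - new_cost < tol:
            cost = new_cost
            converged = True
            break
        cost = new_cost
    if not converged:
        warnings.warn("phase/linker optimization hit the iteration cap", stacklevel=2)

    for d in domains:
        if d.kind == "linker":
            d.length = linkers[d.transition]
    domains = [d for d in domains if not (d.kind == "linker" and d.length == 0)]

    return EmbeddedDesign(
        mesh=mesh,
        plan=plan,
        params=params,
        frames=frames,
        kl_splits=kl_splits,
        domains=domains,
        transitions=transitions,
        linker_counts=list(linkers),
        cost=cost,
        cost_history=history,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------


def _domain_points(
    d: Domain,
    frames: dict[int, HelixFrame],
    params: HelixParams,
    frame_resolver=None,
) -> list[np.ndarray] | None:
    """Helical backbone points for a domain (None for linkers).

    ``frame_resolver(domain) -> (frame, row_map, strand_b)`` lets the
    open-variant layout substitute per-hairpin frames.
    """
    if d.kind == "linker":
        return None
    if frame_resolver is not None:
        frame, row_map, strand_b = frame_resolver(d)
    else:
        frame, row_map, strand_b = frames[d.edge], (lambda r: r), d.strand_b
    pts = [frame.backbone_point(row_map(r), strand_b, params) for r in d.rows]
    if d.kind == "kl_loop" and d.flank:
        # flanking unpaired bases arc outward from the helix surface near
        # the loop ends (diagnostic placement; they are unpaired slack)
        axis_pt0 = frame.origin + (frame.offset0 + row_map(d.rows[0]) * params.rise_per_bp) * frame.axis
        axis_ptN = frame.origin + (frame.offset0 + row_map(d.rows[-1]) * params.rise_per_bp) * frame.axis
        out0 = pts[0] - axis_pt0
        outN = pts[-1] - axis_ptN
        out0 = out0 / np.linalg.norm(out0)
        outN = outN / np.linalg.norm(outN)
        bulge = 0.8  # nm
        f = d.flank
        lead = [
            pts[0]
            + bulge * out0 * math.sin(math.pi * (k + 1) / (f + 1))
            - 0.2 * (f - k) * frame.axis * (1 if d.rows[-1] >= d.rows[0] else -1)
            for k in range(f)
        ]
        trail = [
            pts[-1]
            + bulge * outN * math.sin(math.pi * (f - k) / (f + 1))
            + 0.2 * (k + 1) * frame.axis * (1 if d.rows[-1] >= d.rows[0] else -1)
            for k in range(f)
        ]
        return lead + pts + trail
    return pts


def nucleotide_coordinates(
    embedded: EmbeddedDesign, frame_resolver=None
) -> np.ndarray:
    """Per-nucleotide backbone coordinates in strand (5'->3') order.

    Helical domains follow their rigid frames; flanking loop bases bulge
    outward; linker nucleotides are interpolated along the straight
    segment between the flanking backbone points.
    """
    params = embedded.params
    blocks: list[list[np.ndarray] | int] = []
    for d in embedded.domains:
        pts = _domain_points(d, embedded.frames, params, frame_resolver)
        blocks.append(pts if pts is not None else d.length)

    coords: list[np.ndarray] = []
    n = len(blocks)
    for i, blk in enumerate(blocks):
        if isinstance(blk, int):
            prev_pt = coords[-1] if coords else None
            nxt = blocks[(i + 1) % n]
            nxt_pt = nxt[0] if not isinstance(nxt, int) else None
            if prev_pt is None or nxt_pt is None:
                raise RuntimeError("linker with no flanking helical points")
            for k in range(1, blk + 1):
                s = k / (blk + 1)
                coords.append((1 - s) * prev_pt + s * nxt_pt)
        else:
            coords.extend(blk)
    arr = np.array(coords)
    assert len(arr) == embedded.total_length
    return arr


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square distance of the points from their centroid (nm)."""
    pts = np.asarray(coords, dtype=float)
    if pts.size == 0:
        raise ValueError("empty coordinate list")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


# ---------------------------------------------------------------------------
# Open-kissing-loop variant (qualitative compactness comparison)
# ---------------------------------------------------------------------------


def _unrolled_layout(
    embedded: EmbeddedDesign, fan_angle: float = 55.0
) -> tuple[dict[int, np.ndarray], dict[tuple[int, int], np.ndarray]]:
    """Unroll the spanning tree into a splayed open layout.

    Without kissing-loop closure nothing holds the 3D mesh shape, so the
    open variant lays the tree out by BFS with child edges fanned around
    the incoming direction.  Returns new vertex positions and a direction
    for every kissing-loop half-edge ``(edge, anchor vertex)``.
    """
    mesh, plan = embedded.mesh, embedded.plan
    beta = math.radians(fan_angle)
    tree_adj: dict[int, list[tuple[int, int]]] = {v: [] for v in range(mesh.n_vertices)}
    for ei in plan.tree_edges:
        u, v = mesh.edges[ei]
        tree_adj[u].append((ei, v))
        tree_adj[v].append((ei, u))
    kl_at: dict[int, list[tuple[int, int]]] = {v: [] for v in range(mesh.n_vertices)}
    for ev in plan.traversal:
        if ev.kind == "kl":
            kl_at[ev.u].append((ev.edge, ev.u))

    root = plan.traversal[0].u
    pos: dict[int, np.ndarray] = {root: np.zeros(3)}
    incoming: dict[int, np.ndarray] = {root: np.array([1.0, 0.0, 0.0])}
    stub_dirs: dict[tuple[int, int], np.ndarray] = {}
    from collections import deque

    queue = deque([root])
    visited = {root}
    while queue:
        v = queue.popleft()
        d = incoming[v]
        probe = np.array([0.0, 0.0, 1.0])
        if abs(float(np.dot(probe, d))) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        p1 = probe - float(np.dot(probe, d)) * d
        p1 = p1 / np.linalg.norm(p1)
        p2 = np.cross(d, p1)
        children = [(ei, w) for ei, w in sorted(tree_adj[v]) if w not in visited]
        stubs = sorted(kl_at[v])
        slots = len(children) + len(stubs)
        dirs = []
        for j in range(max(slots, 1)):
            phi = 2.0 * math.pi * j / max(slots, 1)
            dirs.append(
                math.cos(beta) * d + math.sin(beta) * (math.cos(phi) * p1 + math.sin(phi) * p2)
            )
        for j, (ei, w) in enumerate(children):
            length = mesh.edge_length(ei)
            pos[w] = pos[v] + length * dirs[j]
            incoming[w] = dirs[j]
            visited.add(w)
            queue.append(w)
        for j, key in enumerate(stubs, start=len(children)):
            stub_dirs[key] = dirs[j]
    return pos, stub_dirs


def open_variant_coordinates(embedded: EmbeddedDesign, fan_angle: float = 55.0) -> np.ndarray:
    """Coordinates for the same strand with kissing loops left open.

    The spanning tree is unrolled into a splayed layout and each
    kissing-loop hairpin dangles along its own axis, mirroring a design
    whose non-tree edges never close.  The strand content (domains,
    lengths, linkers) is identical to the closed design, so radii of
    gyration are directly comparable.
    """
    params = embedded.params
    mesh, plan = embedded.mesh, embedded.plan
    pos, stub_dirs = _unrolled_layout(embedded, fan_angle)

    open_tree_frames: dict[int, HelixFrame] = {}
    first_dir: dict[int, tuple[int, int]] = {}
    for ev in plan.traversal:
        if ev.kind == "tree" and ev.edge not in first_dir:
            first_dir[ev.edge] = (ev.u, ev.v)
    for ei in plan.tree_edges:
        u, v = first_dir[ei]
        f = embedded.frames[ei]
        nf = _frame_for_edge(pos[u], pos[v], f.bp, params)
        nf.phase = f.phase
        open_tree_frames[ei] = nf

    hairpin_frames: dict[tuple[int, int], HelixFrame] = {}
    for (ei, anchor), d in stub_dirs.items():
        stem_a, stem_b = embedded.kl_splits[ei]
        u_low, _ = mesh.edges[ei]
        local_bp = (stem_b if anchor == u_low else stem_a) + params.kl_pair_len
        p0 = pos[anchor]
        p1 = p0 + (local_bp * params.rise_per_bp + 1.0) * d
        nf = _frame_for_edge(p0, p1, local_bp, params)
        nf.phase = embedded.frames[ei].phase
        hairpin_frames[(ei, anchor)] = nf

    total_rows = {
        ei: embedded.kl_splits[ei][0] + embedded.kl_splits[ei][1] + params.kl_pair_len
        for ei in plan.kl_edges
    }

    def resolver(d: Domain):
        if d.kind in ("stem5", "stem3"):
            return open_tree_frames[d.edge], (lambda r: r), d.strand_b
        # kissing-loop domains: remap global edge rows onto the hairpin's
        # own dangling axis.  Low-anchored hairpins occupy rows
        # [0, stem_b + kl_pair_len); high-anchored ones the top rows.
        # The shared loop rows are disambiguated by strand: the
        # low-anchored hairpin's loop sits on strand A.
        u_low, v_high = mesh.edges[d.edge]
        stem_b = embedded.kl_splits[d.edge][1]
        if d.kind == "kl_loop":
            low = not d.strand_b
        else:
            low = max(d.rows) < stem_b
        if low:
            return hairpin_frames[(d.edge, u_low)], (lambda r: r), d.strand_b
        nrows = total_rows[d.edge]
        return hairpin_frames[(d.edge, v_high)], (lambda r: nrows - 1 - r), d.strand_b

    return nucleotide_coordinates(embedded, frame_resolver=resolver)


def embed_design(
    mesh: Mesh,
    plan: RoutingPlan,
    params: HelixParams | None = None,
    seed: int = 0,
) -> EmbeddedDesign:
    """Optimize phases/linkers and compute coordinates in one call."""
    embedded = optimize_phases_and_linkers(mesh, plan, params, seed=seed)
    embedded.coordinates()
    return embedded
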
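"""Knot determinant of a closed 3D polyline.

The determinant |Delta(-1)| of a knot equals the order of the first
homology of its double branched cover and can be read off a crossing
diagram: each crossing with over-strand arc ``o`` and under-strand arcs
``i`` (incoming) and ``j`` (outgoing) contributes the relation
``2*o - i - j = 0``; the determinant is |det| of any (n-1)x(n-1) minor
of the resulting coloring matrix.  The unknot has determinant 1 (a
necessary, not sufficient, condition for unknottedness).

The polyline is projected onto a random plane (seeded); degenerate
projections (near-tangent crossings, endpoint hits, depth ties) are
rejected and retried with a fresh rotation — the 3D curve itself is
never perturbed, so the topology is preserved.
"""

from __future__ import annotations

from bisect import bisect_left
from fractions import Fraction

import numpy as np

__all__ = ["knot_determinant", "determinant_from_crossings"]

_PRIMES = (67108859, 67108879, 67108913)  # ~2^26; products stay in int64


class _DegenerateProjection(Exception):
    pass


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    return q


def _find_crossings(p2: np.ndarray, z: np.ndarray, tol: float):
    """All transversal crossings of the closed projected polyline.

    Returns a list of (pos_over, pos_under) curve positions, where a
    position is segment_index + parameter in [0, 1).  Raises
    :class:`_DegenerateProjection` on any near-degenerate incidence.
    """
    n = len(p2)
    starts = p2
    ends = np.roll(p2, -1, axis=0)
    d = ends - starts
    z0 = z
    z1 = np.roll(z, -1)

    scale = float(np.max(np.abs(p2))) + 1.0
    eps_par = 1e-9
    crossings = []
    for i in range(n):
        # j from i+2, skipping the wrap-adjacent pair (i=0, j=n-1)
        jmax = n if i > 0 else n - 1
        js = np.arange(i + 2, jmax)
        if len(js) == 0:
            continue
        r = starts[js] - starts[i]
        denom = d[i, 0] * d[js, 1] - d[i, 1] * d[js, 0]
        small = np.abs(denom) < 1e-12 * scale * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (r[:, 0] * d[js, 1] - r[:, 1] * d[js, 0]) / denom
            u = (r[:, 0] * d[i, 1] - r[:, 1] * d[i, 0]) / denom
        inside = (~small) & (t > -eps_par) & (t < 1 + eps_par) & (u > -eps_par) & (u < 1 + eps_par)
        # parallel segments whose boxes could overlap: treat as degenerate
        if np.any(small):
            for j in js[small]:
                # overlapping collinear segments would hide crossings
                cross1 = d[i, 0] * r[js == j][0][1] - d[i, 1] * r[js == j][0][0]
                if abs(cross1) < 1e-9 * scale * scale:
                    lo_i = np.minimum(starts[i], ends[i]) - tol
                    hi_i = np.maximum(starts[i], ends[i]) + tol
                    lo_j = np.minimum(starts[j], ends[j]) - tol
                    hi_j = np.maximum(starts[j], ends[j]) + tol
                    if np.all(lo_i <= hi_j) and np.all(lo_j <= hi_i):
                        raise _DegenerateProjection("collinear overlap")
            inside &= ~small
        for idx in np.nonzero(inside)[0]:
            j = int(js[idx])
            ti, uj = float(t[idx]), float(u[idx])
            if min(ti, 1 - ti, uj, 1 - uj) < 1e-7:
                raise _DegenerateProjection("crossing at segment endpoint")
            zi = z0[i] + ti * (z1[i] - z0[i])
            zj = z0[j] + uj * (z1[j] - z0[j])
            if abs(zi - zj) < tol:
                raise _DegenerateProjection("depth tie at crossing")
            pos_i = i + ti
            pos_j = j + uj
            if zi > zj:
                crossings.append((pos_i, pos_j))
            else:
                crossings.append((pos_j, pos_i))
    # triple points / coincident crossings on a segment
    per_seg: dict[int, list[float]] = {}
    for over, under in crossings:
        for pos in (over, under):
            per_seg.setdefault(int(pos), []).append(pos % 1.0)
    for params in per_seg.values():
        params.sort()
        for a, b in zip(params, params[1:]):
            if b - a < 1e-9:
                raise _DegenerateProjection("coincident crossings")
    return crossings


def determinant_from_crossings(crossings: list[tuple[float, float]]) -> int:
    """|Delta(-1)| from a list of (over position, under position) pairs.

    Positions are parameters along the closed curve; under positions cut
    the curve into arcs.
    """
    n = len(crossings)
    if n == 0:
        return 1
    unders = sorted(u for _, u in crossings)

    def arc_of(pos: float) -> int:
        # arc m spans (unders[m], unders[m+1]); position before unders[0]
        # wraps into the last arc
        k = bisect_left(unders, pos)
        return (k - 1) % n

    mat = [[0] * n for _ in range(n)]
    for row, (over, under) in enumerate(crossings):
        o = arc_of(over)
        k = unders.index(under)
        arc_in = (k - 1) % n
        arc_out = k
        mat[row][o] += 2
        mat[row][arc_in] -= 1
        mat[row][arc_out] -= 1
    # any (n-1) x (n-1) minor
    minor = [r[: n - 1] for r in mat[: n - 1]]
    if n - 1 == 0:
        return 1
    if n <= 48:
        return abs(_det_bareiss(minor))
    residues = [_det_mod(minor, p) for p in _PRIMES]
    return abs(_crt_symmetric(residues, _PRIMES))


def _det_bareiss(mat: list[list[int]]) -> int:
    """Exact integer determinant (fraction-free Gaussian elimination)."""
    a = [row[:] for row in mat]
    n = len(a)
    sign = 1
    prev = 1
    for k in range(n - 1):
        if a[k][k] == 0:
            for i in range(k + 1, n):
                if a[i][k] != 0:
                    a[k], a[i] = a[i], a[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                a[i][j] = (a[i][j] * a[k][k] - a[i][k] * a[k][j]) // prev
        prev = a[k][k]
    return sign * a[-1][-1]


def _det_mod(mat: list[list[int]], p: int) -> int:
    a = np.array(mat, dtype=np.int64) % p
    n = len(a)
    det = 1
    for k in range(n):
        piv = k
        while piv < n and a[piv, k] == 0:
            piv += 1
        if piv == n:
            return 0
        if piv != k:
            a[[k, piv]] = a[[piv, k]]
            det = (-det) % p
        det = (det * int(a[k, k])) % p
        inv = pow(int(a[k, k]), -1, p)
        a[k] = (a[k] * inv) % p
        factors = a[k + 1 :, k].copy()
        a[k + 1 :] = (a[k + 1 :] - factors[:, None] * a[k][None, :]) % p
    return int(det)


def _crt_symmetric(residues: list[int], primes: tuple[int, ...]) -> int:
    m = 1
    x = 0
    for r, p in zip(residues, primes):
        # solve x' == x (mod m), x' == r (mod p)
        g = pow(m % p, -1, p)
        x = x + m * ((r - x) * g % p)
        m *= p
        x %= m
    if x > m // 2:
        x -= m
    return x


def knot_determinant(
    polyline: np.ndarray,
    seed: int = 0,
    max_attempts: int = 60,
) -> int:
    """Knot determinant |Delta(-1)| of a closed, embedded 3D polyline.

    The polyline is cyclic (last vertex joins the first; a repeated
    endpoint is tolerated).  Returns 1 for the unknot's diagrams; any
    other value certifies knotting.

    Raises ``RuntimeError`` if no generic projection is found after
    ``max_attempts`` random rotations.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("polyline must be an (N, 3) array")
    if len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) < 1e-12:
        pts = pts[:-1]
    if len(pts) < 3:
        return 1
    rng = np.random.default_rng(seed)
    scale = float(np.max(np.ptp(pts, axis=0)))
    tol = 1e-9 * max(scale, 1.0)
    for _ in range(max_attempts):
        rot = _random_rotation(rng)
        xyz = pts @ rot.T
        try:
            crossings = _find_crossings(xyz[:, :2], xyz[:, 2], tol)
        except _DegenerateProjection:
            continue
        return determinant_from_crossings(crossings)
    raise RuntimeError("no generic projection found; polyline may be degenerate")
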
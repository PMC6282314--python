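"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: per-tetrahedron python loops,
least-squares circumcentres, BFS component counting, triple-loop box
counts and a monotone-curve bisection.  None of it shares code with the
vectorised paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay


def brute_alpha(points: np.ndarray, alpha: float):
    """Naive alpha complex: volume, boundary-face set, component count.

    Only suitable for tiny clouds (<= ~50 points).
    """
    tri = Delaunay(points)
    diag = np.linalg.norm(points.max(0) - points.min(0))
    kept = []
    for tet in tri.simplices:
        v = points[tet]
        vol = abs(np.linalg.det(v[1:] - v[0])) / 6.0
        if vol < 1e-12 * diag**3:
            radius = np.inf
        else:
            # circumcentre from equidistance: least squares on 3 plane eqns
            A = 2 * (v[1:] - v[0])
            b = (v[1:] ** 2).sum(1) - (v[0] ** 2).sum()
            centre, *_ = np.linalg.lstsq(A, b, rcond=None)
            radius = float(np.linalg.norm(centre - v[0]))
        if radius <= alpha:
            kept.append((tuple(tet), vol))
    volume = sum(v for _, v in kept)
    # boundary faces: count occurrences of each sorted triple
    face_count: dict = {}
    for tet, _ in kept:
        for skip in range(4):
            face = tuple(sorted(t for i, t in enumerate(tet) if i != skip))
            face_count[face] = face_count.get(face, 0) + 1
    boundary = {f for f, c in face_count.items() if c == 1}
    # components by BFS over shared faces
    n = len(kept)
    adj = [[] for _ in range(n)]
    face_owner: dict = {}
    for i, (tet, _) in enumerate(kept):
        for skip in range(4):
            face = tuple(sorted(t for j, t in enumerate(tet) if j != skip))
            if face in face_owner:
                j = face_owner[face]
                adj[i].append(j)
                adj[j].append(i)
            else:
                face_owner[face] = i
    seen = [False] * n
    comps = 0
    for s in range(n):
        if seen[s]:
            continue
        comps += 1
        stack = [s]
        seen[s] = True
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
    return volume, boundary, comps


def bisect_k_star(tri, l_ref_mm: float, raw_volume: float, lo=0.1, hi=10_000.0, n_grid=2000):
    """Dense-grid scan plus bisection on the monotone volume curve.

    Finds the coarsest sign change of V(k) - raw and bisects it in log k.
    """
    ks = np.geomspace(lo, hi, n_grid)
    above = np.array([tri.volume_at(k * l_ref_mm) >= raw_volume for k in ks])
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        raise ValueError("volume never reaches raw volume")
    i = idx.min()
    if i == 0:
        return float(ks[0])
    a, b = ks[i - 1], ks[i]
    for _ in range(100):
        m = float(np.sqrt(a * b))
        if tri.volume_at(m * l_ref_mm) >= raw_volume:
            b = m
        else:
            a = m
    return float(np.sqrt(a * b))


def naive_box_count(grid: np.ndarray):
    """Triple-loop occupied-box counts on a zero-padded cube."""
    size = 1
    while size < max(grid.shape):
        size *= 2
    g = np.zeros((size, size, size), dtype=bool)
    g[: grid.shape[0], : grid.shape[1], : grid.shape[2]] = grid
    sizes, counts = [], []
    s = 1
    while s <= size:
        n = 0
        for i in range(0, size, s):
            for j in range(0, size, s):
                for k in range(0, size, s):
                    if g[i : i + s, j : j + s, k : k + s].any():
                        n += 1
        sizes.append(s)
        counts.append(n)
        s *= 2
    return np.array(sizes), np.array(counts)


def fill_2d_oracle(mask: np.ndarray) -> np.ndarray:
    """Flood fill a single 2D slice from its edges, pure python BFS."""
    h, w = mask.shape
    reach = np.zeros_like(mask, dtype=bool)
    stack = []
    for i in range(h):
        for j in (0, w - 1):
            if not mask[i, j]:
                stack.append((i, j))
    for j in range(w):
        for i in (0, h - 1):
            if not mask[i, j]:
                stack.append((i, j))
    for p in stack:
        reach[p] = True
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if 0 <= a < h and 0 <= b < w and not mask[a, b] and not reach[a, b]:
                reach[a, b] = True
                stack.append((a, b))
    return mask | ~reach
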
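"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use the slowest, most transparent formulation
(flood fill, pair enumeration, exhaustive partitioning) so they stay
independent of the library code paths they check.
"""

from collections import deque

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def flood_fill_components(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Brute-force connected-component labelling by BFS flood fill.

    True pixels get labels 1..C in scan order; False pixels get 0.
    """
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    out = np.zeros((h, w), dtype=int)
    nxt = 0
    for r in range(h):
        for c in range(w):
            if binary[r, c] and out[r, c] == 0:
                nxt += 1
                out[r, c] = nxt
                q = deque([(r, c)])
                while q:
                    cr, cc = q.popleft()
                    for dr, dc in steps:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and out[nr, nc] == 0:
                            out[nr, nc] = nxt
                            q.append((nr, nc))
    return out


def rand_index_by_pairs(pred: np.ndarray, gt: np.ndarray) -> float:
    """Rand index by literal enumeration of every unordered pixel pair."""
    p = np.asarray(pred).ravel()
    g = np.asarray(gt).ravel()
    n = len(p)
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            agree += (p[i] == p[j]) == (g[i] == g[j])
    return agree / total


def graph_components(n: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    """Connected components of an explicit undirected graph, by BFS."""
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        comp = {start}
        q = deque([start])
        seen.add(start)
        while q:
            v = q.popleft()
            for u in adj[v]:
                if u not in seen:
                    seen.add(u)
                    comp.add(u)
                    q.append(u)
        comps.append(comp)
    return comps


def best_two_partition(points: np.ndarray) -> frozenset[frozenset[int]]:
    """Exhaustive 2-means minimizer: the split of point indices into two
    non-empty groups minimizing total within-group squared deviation."""
    n = len(points)
    best, best_cost = None, np.inf
    for mask in range(1, 2 ** (n - 1)):  # fix point 0 in group A to halve the space
        b = [i for i in range(1, n) if (mask >> (i - 1)) & 1]
        a = [i for i in range(n) if i == 0 or not (mask >> (i - 1)) & 1]
        cost = 0.0
        for grp in (a, b):
            pts = points[grp]
            cost += float(((pts - pts.mean(axis=0)) ** 2).sum())
        if cost < best_cost:
            best_cost = cost
            best = frozenset({frozenset(a), frozenset(b)})
    return best
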
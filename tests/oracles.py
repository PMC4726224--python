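"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way (flood fills
via networkx, full enumerations) and shares no code with the package's
incremental algorithms.
"""

from __future__ import annotations

import itertools
from collections import Counter

import networkx as nx

from gridpatterns.grid import CellCoord


def brute_components(cells: dict, adjacency: dict, theta: float) -> list[frozenset]:
    """Connected components of {cell: value >= theta} by networkx."""
    active = [c for c, v in cells.items() if v >= theta]
    g = nx.Graph()
    g.add_nodes_from(active)
    for c in active:
        for nb in adjacency[c]:
            if nb in cells and cells[nb] >= theta:
                g.add_edge(c, nb)
    return sorted(
        (frozenset(comp) for comp in nx.connected_components(g)), key=sorted
    )


def brute_runs(cells: dict, adjacency: dict) -> list[tuple[int, list[float]]]:
    """Maximal constant-component-count runs over sorted distinct values."""
    values = sorted(set(cells.values()))
    counts = [len(brute_components(cells, adjacency, v)) for v in values]
    runs: list[tuple[int, list[float]]] = []
    for v, n in zip(values, counts):
        if runs and runs[-1][0] == n:
            runs[-1][1].append(v)
        else:
            runs.append((n, [v]))
    return runs


def brute_select(
    cells: dict,
    adjacency: dict,
    min_lower=0.2,
    stability: str = "count",
    floor_mode: str = "clip",
):
    """Re-derive the selected threshold pair (theta_lo, theta_hi, count).

    Returns None when nothing clears the floor.
    """
    runs = brute_runs(cells, adjacency)

    def eligible(vals):
        if min_lower is None:
            return list(vals)
        if floor_mode == "clip":
            return [v for v in vals if v >= min_lower]
        return list(vals) if vals[0] >= min_lower else []

    scored = [(n, eligible(vals)) for n, vals in runs]
    scored = [(n, vals) for n, vals in scored if vals]
    if not scored:
        return None
    if stability == "interval":
        best = min(scored, key=lambda it: (-len(it[1]), it[1][0]))
        return best[1][0], best[1][-1], best[0]
    totals: dict[int, list[float]] = {}
    for n, vals in scored:
        totals.setdefault(n, []).extend(vals)
    best_n = min(totals, key=lambda n: (-len(totals[n]), min(totals[n])))
    vals = sorted(totals[best_n])
    return vals[0], vals[-1], best_n


def exact_largest_component_distribution(p: float, adjacency: dict) -> dict[int, float]:
    """Exact distribution of the largest-component size by enumerating every
    cell configuration (only feasible for tiny grids)."""
    cells = sorted(adjacency)
    dist: dict[int, float] = Counter()
    for mask in itertools.product([False, True], repeat=len(cells)):
        active = {c for c, m in zip(cells, mask) if m}
        weight = 1.0
        for m in mask:
            weight *= p if m else (1 - p)
        if not active:
            dist[0] += weight
            continue
        g = nx.Graph()
        g.add_nodes_from(active)
        for c in active:
            for nb in adjacency[c]:
                if nb in active:
                    g.add_edge(c, nb)
        largest = max(len(comp) for comp in nx.connected_components(g))
        dist[largest] += weight
    return dict(dist)


def enumerate_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by enumerating every n-subset of an N-universe."""
    category = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(category.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def brute_ks_d(a, b) -> float:
    """KS statistic by scanning every observed value."""
    best = 0.0
    for x in sorted(set(a) | set(b)):
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best


def grid_cells_1d(values):
    """A 1 x len(values) slice as a {CellCoord: value} map (None = missing)."""
    return {
        CellCoord(i + 1, 1): v for i, v in enumerate(values) if v is not None
    }


def line_adjacency(n: int) -> dict:
    adj = {}
    for i in range(1, n + 1):
        nbs = set()
        if i > 1:
            nbs.add(CellCoord(i - 1, 1))
        if i < n:
            nbs.add(CellCoord(i + 1, 1))
        adj[CellCoord(i, 1)] = frozenset(nbs)
    return adj
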
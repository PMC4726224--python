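"""Recurrent local expression patterns from overlapping expressed regions.

Contiguous expressed components are pooled from all (gene, timepoint)
slices *not* called globally expressed, filtered by size, and clustered:
components are nodes of an overlap graph whose edges connect pairs with
Jaccard cell-set overlap at or above a cutoff, and each connected component
of that graph is one recurrent local pattern.  An optional refinement keeps
only clusters whose mean pairwise member overlap clears a second cutoff
(a quasi-clique condition), for stricter pattern coherence.

Each pattern is summarized by its number of member occurrences (distinct
(gene, timepoint) regions), the number of distinct genes, a per-cell
frequency map (fraction of members covering each cell), and a per-timepoint
occurrence profile.  Patterns are ranked by occurrence count, then gene
count, then (deterministically) by their first member's gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from .grid import CellCoord
from .io import TIMEPOINTS, timepoint_index
from .quantize import Component, QuantizedSlice


def _component_sort_key(c: Component):
    return (c.gene, timepoint_index(c.timepoint), sorted(c.cells))


@dataclass(frozen=True)
class ComponentPool:
    """Pooled components plus the valid-cell count of their source slices."""

    components: tuple[Component, ...]
    n_valid: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.components)


def pool_components(
    quantized: Mapping[tuple[str, str], QuantizedSlice],
    bits: Mapping[tuple[str, str], int],
) -> ComponentPool:
    """Collect components from slices whose global-expression bit is 0.

    ``bits`` maps (gene, timepoint) to the global call; slices missing from
    it are treated as non-global (no data cannot support a global call).
    """
    comps: list[Component] = []
    n_valid: dict[tuple[str, str], int] = {}
    for key in sorted(quantized, key=lambda k: (k[0], timepoint_index(k[1]))):
        if bits.get(key, 0) == 1:
            continue
        q = quantized[key]
        n_valid[key] = q.n_valid
        comps.extend(sorted(q.components, key=_component_sort_key))
    return ComponentPool(tuple(comps), n_valid)


def filter_components(
    pool: ComponentPool, min_cells: int = 2, max_fraction_of_valid: float = 0.5
) -> ComponentPool:
    """Keep components with min_cells <= size <= max_fraction × n_valid.

    Single-cell regions are noise-prone; regions above half the valid cells
    would have been captured as global expression.
    """
    kept = []
    for c in pool.components:
        if c.size < min_cells:
            continue
        nv = pool.n_valid.get((c.gene, c.timepoint))
        if nv is not None and c.size > max_fraction_of_valid * nv:
            continue
        kept.append(c)
    return ComponentPool(tuple(kept), dict(pool.n_valid))


def overlap_score(a: Component, b: Component) -> float:
    """Jaccard index of the two components' cell sets."""
    inter = len(a.cells & b.cells)
    if inter == 0:
        return 0.0
    return inter / len(a.cells | b.cells)


@dataclass(frozen=True)
class PatternCluster:
    """One recurrent local pattern: a cluster of overlapping components."""

    members: tuple[Component, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a pattern cluster cannot be empty")

    @property
    def occurrence_count(self) -> int:
        return len(self.members)

    @property
    def gene_count(self) -> int:
        return len({m.gene for m in self.members})

    @property
    def member_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset((m.gene, m.timepoint) for m in self.members)

    def frequency_map(self) -> dict[CellCoord, float]:
        """Per-cell fraction of members covering that cell."""
        counts: dict[CellCoord, int] = {}
        for m in self.members:
            for c in m.cells:
                counts[c] = counts.get(c, 0) + 1
        n = self.occurrence_count
        return {c: k / n for c, k in sorted(counts.items())}

    def time_profile(self) -> dict[str, int]:
        """Member occurrences per canonical time point."""
        prof = {tp: 0 for tp in TIMEPOINTS}
        for m in self.members:
            prof[m.timepoint] += 1
        return prof


def frequency_map(cluster: PatternCluster) -> dict[CellCoord, float]:
    return cluster.frequency_map()


def sort_patterns(clusters: Iterable[PatternCluster]) -> list[PatternCluster]:
    """Rank: descending occurrences, then gene count, then first member's gene."""
    return sorted(
        clusters,
        key=lambda cl: (
            -cl.occurrence_count,
            -cl.gene_count,
            _component_sort_key(cl.members[0]),
        ),
    )


def cluster_components(
    pool: ComponentPool,
    jaccard_min: float = 0.5,
    min_members: int = 1,
    refine_mean_jaccard: Optional[float] = None,
) -> list[PatternCluster]:
    """Partition a filtered pool into recurrent patterns.

    Builds the overlap graph (edge iff Jaccard >= ``jaccard_min``) and
    takes its connected components as clusters.  With
    ``refine_mean_jaccard`` set, each multi-member cluster is additionally
    tightened toward a quasi-clique: members whose mean overlap with the
    rest of the cluster falls below the threshold are iteratively peeled
    off (worst first) and become their own clusters — this severs
    single-link chains through coincidental small overlaps without losing
    any component, so the output remains a partition of the pool.
    Clusters with fewer than ``min_members`` members are dropped from the
    output.  The procedure is a deterministic function of the pool and
    parameters.
    """
    comps = sorted(pool.components, key=_component_sort_key)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(comps)))
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            if overlap_score(comps[i], comps[j]) >= jaccard_min:
                graph.add_edge(i, j)
    raw: list[list[int]] = [sorted(nodes) for nodes in nx.connected_components(graph)]
    groups: list[list[int]] = []
    for nodes in raw:
        if refine_mean_jaccard is None or len(nodes) == 1:
            groups.append(nodes)
            continue
        kept = list(nodes)
        while len(kept) > 1:
            means = {
                i: sum(overlap_score(comps[i], comps[j]) for j in kept if j != i)
                / (len(kept) - 1)
                for i in kept
            }
            worst = min(kept, key=lambda i: (means[i], i))
            if means[worst] >= refine_mean_jaccard:
                break
            kept.remove(worst)
            groups.append([worst])
        groups.append(kept)
    clusters = [
        PatternCluster(tuple(comps[i] for i in nodes))
        for nodes in groups
        if len(nodes) >= min_members
    ]
    return sort_patterns(clusters)
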
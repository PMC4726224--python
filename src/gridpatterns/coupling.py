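"""Temporal distributions of expressed-region occurrences by brain region.

For a coarse region group (forebrain, hindbrain, dorsal, ventral, or the
all-inclusive control/background), the occurrences of expressed regions are
tallied per developmental time point and reported as proportions.  Group
membership is resolved in one of two modes:

* ``"pattern"`` — the group is a list of 1-based pattern indices (into the
  ranked cluster list); occurrences are the member regions of those
  patterns.
* ``"coords"`` — patterns are ignored and a pooled component belongs to the
  group when at least half of its cells (all of them in strict mode) fall
  inside the group's coordinate range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .grid import GridSpec, RegionGroupConfig, cells_in_group
from .io import TIMEPOINTS
from .patterns import ComponentPool, PatternCluster
from .quantize import Component


@dataclass(frozen=True)
class TemporalDistribution:
    """Proportions of occurrences over the 7 canonical time points."""

    proportions: tuple[float, ...]
    n: int

    def __post_init__(self) -> None:
        if len(self.proportions) != len(TIMEPOINTS):
            raise ValueError("one proportion per canonical time point required")
        if self.n > 0 and abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(TIMEPOINTS, self.proportions))


def distribution_from_components(components: Iterable[Component]) -> TemporalDistribution:
    counts = {tp: 0 for tp in TIMEPOINTS}
    n = 0
    for c in components:
        counts[c.timepoint] += 1
        n += 1
    if n == 0:
        raise ValueError("no occurrences in group")
    return TemporalDistribution(tuple(counts[tp] / n for tp in TIMEPOINTS), n)


def component_in_region(
    component: Component,
    region_cells: frozenset,
    min_overlap: float = 0.5,
    strict: bool = False,
) -> bool:
    """Containment rule for components straddling a region boundary.

    Default: at least ``min_overlap`` of the component's cells lie in the
    region.  Strict mode requires full containment.
    """
    inside = len(component.cells & region_cells)
    if strict:
        return inside == component.size
    return inside >= min_overlap * component.size


def occurrences_by_time(
    group: str,
    config: RegionGroupConfig,
    spec: GridSpec,
    clusters: Optional[Sequence[PatternCluster]] = None,
    pool: Optional[ComponentPool] = None,
    mode: str = "pattern",
    min_overlap: float = 0.5,
    strict: bool = False,
) -> TemporalDistribution:
    """Temporal occurrence distribution of a region group's expressed regions.

    In pattern mode the group's ``patterns`` indices select clusters from
    the ranked ``clusters`` list (no indices = all clusters, i.e. the
    control/background).  In coords mode membership is decided per pooled
    component by :func:`component_in_region`.
    """
    g = config[group]
    if mode == "pattern":
        if clusters is None:
            raise ValueError("pattern mode requires the ranked cluster list")
        if g.patterns is None:
            selected = list(clusters)
        else:
            bad = [i for i in g.patterns if not 1 <= i <= len(clusters)]
            if bad:
                raise ValueError(f"pattern indices out of range: {bad}")
            selected = [clusters[i - 1] for i in g.patterns]
        members = [m for cl in selected for m in cl.members]
    elif mode == "coords":
        if pool is None:
            raise ValueError("coords mode requires the component pool")
        region = cells_in_group(config, group, spec)
        members = [
            c
            for c in pool.components
            if component_in_region(c, region, min_overlap=min_overlap, strict=strict)
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return distribution_from_components(members)
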
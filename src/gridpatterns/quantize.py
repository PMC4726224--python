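"""Demarcating contiguous expressed regions by threshold-sweep stability.

For one gene at one time point, the grid of energies ``E(x, y)`` is
binarized at a threshold θ and the 4-connected components of
``E >= θ`` are the candidate expressed regions.  Because no prior threshold
is known, θ is swept over the *sorted distinct observed values* of the
slice (an idea borrowed from computational topology / persistence): each
distinct value yields a component structure, and a maximal run of
consecutive distinct values over which the number of components stays
constant is that structure's *valid interval*.  Interval length is counted
in distinct data values, not geometric length, which makes the whole
procedure invariant under any strictly increasing transform of the data
(z-scoring, rank transforms, ...).

The selected structure is the most stable one: the component count whose
topology persists over the most distinct threshold values, after an
absolute floor (``min_lower``, default 0.2) suppresses very small
thresholds (see :func:`select_structure` for the per-run and
floor-exclusion variants).  Ties go to the smaller lower bound, preferring
the largest differentially expressed areas.  The quantization threshold is
the selected structure's (floored) lower bound; binarizing at the upper
bound instead yields the smallest patches of the same structure (the
peaks).

Missing cells are barriers: never expressed and never traversable.
Component membership may drift within a valid interval (components shrink
as θ rises); the component count is what stays constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .grid import CellCoord
from .io import SliceView


class AllMissingError(ValueError):
    """Raised when a slice has no observed values at all."""


@dataclass(frozen=True)
class Component:
    """A contiguous expressed region in one (gene, timepoint) slice."""

    gene: str
    timepoint: str
    cells: frozenset[CellCoord]

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("a component must contain at least one cell")

    @property
    def size(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class ComponentStructure:
    """A component count that persists over a run of distinct thresholds.

    ``thetas`` holds the distinct observed values in the run, ascending.
    The valid interval is [``theta_lo``, next run's first value); both
    endpoints of ``thetas`` are *inside* the run, so binarizing at
    ``theta_hi`` still realizes this structure (with its smallest cells).
    ``components`` stores the cell sets realized at ``theta_lo`` (the
    largest extent of the structure).
    """

    n_components: int
    components: tuple[frozenset[CellCoord], ...]
    thetas: tuple[float, ...]

    @property
    def theta_lo(self) -> float:
        return self.thetas[0]

    @property
    def theta_hi(self) -> float:
        """Largest distinct value inside the valid interval."""
        return self.thetas[-1]

    @property
    def interval_length(self) -> int:
        return len(self.thetas)


@dataclass(frozen=True)
class QuantizedSlice:
    """Binary demarcation of one slice: 1 iff observed energy >= theta.

    ``theta is None`` means no structure passed the threshold floor; the
    slice is then entirely unexpressed.
    """

    gene: str
    timepoint: str
    theta: Optional[float]
    components: tuple[Component, ...]
    n_valid: int

    @property
    def cells(self) -> frozenset[CellCoord]:
        out: set[CellCoord] = set()
        for comp in self.components:
            out |= comp.cells
        return frozenset(out)

    @property
    def n_expressed(self) -> int:
        return sum(c.size for c in self.components)

    @property
    def largest_component_size(self) -> int:
        return max((c.size for c in self.components), default=0)


def _components_at(
    cells: dict[CellCoord, float],
    adjacency: dict[CellCoord, frozenset[CellCoord]],
    theta: float,
) -> tuple[frozenset[CellCoord], ...]:
    """Connected components of {cell : value >= theta}, by BFS."""
    active = {c for c, v in cells.items() if v >= theta}
    seen: set[CellCoord] = set()
    comps: list[frozenset[CellCoord]] = []
    for start in sorted(active):
        if start in seen:
            continue
        stack = [start]
        comp = {start}
        seen.add(start)
        while stack:
            c = stack.pop()
            for nb in adjacency[c]:
                if nb in active and nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(frozenset(comp))
    return tuple(comps)


def sweep_thresholds(
    sl: SliceView, adjacency: dict[CellCoord, frozenset[CellCoord]]
) -> list[ComponentStructure]:
    """All component structures of a slice, ordered by ascending theta_lo.

    Component counts per distinct threshold are obtained incrementally with
    a union-find pass that activates cells in order of decreasing value and
    merges them with already-active neighbors, so the full sweep costs
    O(n α(n)) rather than one flood fill per threshold.
    """
    cells = dict(sl.observed_items())
    if not cells:
        raise AllMissingError(f"slice ({sl.gene}, {sl.timepoint}) is all missing")

    by_value: dict[float, list[CellCoord]] = {}
    for c, v in cells.items():
        by_value.setdefault(v, []).append(c)
    values = sorted(by_value)

    parent: dict[CellCoord, CellCoord] = {}

    def find(c: CellCoord) -> CellCoord:
        root = c
        while parent[root] != root:
            root = parent[root]
        while parent[c] != root:  # path compression
            parent[c], c = root, parent[c]
        return root

    counts: dict[float, int] = {}
    n_comp = 0
    for v in reversed(values):
        newly = by_value[v]
        for c in newly:
            parent[c] = c
        n_comp += len(newly)
        for c in newly:
            for nb in adjacency[c]:
                if nb in parent:
                    ra, rb = find(c), find(nb)
                    if ra != rb:
                        parent[ra] = rb
                        n_comp -= 1
        counts[v] = n_comp

    structures: list[ComponentStructure] = []
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and counts[values[j + 1]] == counts[values[i]]:
            j += 1
        run = tuple(values[i : j + 1])
        comps = _components_at(cells, adjacency, run[0])
        assert len(comps) == counts[run[0]]
        structures.append(ComponentStructure(counts[run[0]], comps, run))
        i = j + 1
    return structures


def _floored_thetas(
    s: ComponentStructure,
    min_lower: Optional[float],
    floor_mode: str,
    strict_floor: bool,
) -> tuple[float, ...]:
    """Distinct values of the run that count toward selection.

    Empty result = ineligible structure.
    """
    if min_lower is None:
        return s.thetas
    if floor_mode == "clip":
        if strict_floor:
            return tuple(v for v in s.thetas if v > min_lower)
        return tuple(v for v in s.thetas if v >= min_lower)
    if floor_mode == "exclude":
        ok = s.theta_lo > min_lower if strict_floor else s.theta_lo >= min_lower
        return s.thetas if ok else ()
    raise ValueError(f"floor_mode must be 'clip' or 'exclude', got {floor_mode!r}")


def _selection(
    structures: list[ComponentStructure],
    min_lower: Optional[float],
    stability: str,
    floor_mode: str,
    strict_floor: bool,
) -> Optional[tuple[ComponentStructure, float, float]]:
    """Selection core: (chosen run, effective θ_lo, effective θ_hi) or None."""
    items = [
        (s, eff)
        for s in structures
        if (eff := _floored_thetas(s, min_lower, floor_mode, strict_floor))
    ]
    if not items:
        return None
    if stability == "interval":
        s, eff = min(items, key=lambda it: (-len(it[1]), it[1][0]))
        return s, eff[0], eff[-1]
    if stability == "count":
        groups: dict[int, list[tuple[ComponentStructure, tuple[float, ...]]]] = {}
        for s, eff in items:
            groups.setdefault(s.n_components, []).append((s, eff))
        best = min(
            groups,
            key=lambda cnt: (
                -sum(len(eff) for _, eff in groups[cnt]),
                min(eff[0] for _, eff in groups[cnt]),
            ),
        )
        runs = sorted(groups[best], key=lambda it: it[1][0])
        return runs[0][0], runs[0][1][0], max(eff[-1] for _, eff in runs)
    raise ValueError(f"stability must be 'count' or 'interval', got {stability!r}")


def select_structure(
    structures: list[ComponentStructure],
    min_lower: Optional[float] = 0.2,
    stability: str = "count",
    floor_mode: str = "clip",
    strict_floor: bool = False,
) -> Optional[ComponentStructure]:
    """Most stable eligible structure, or None.

    A component structure is identified by its topology — its component
    count — and its stability is the number of eligible distinct threshold
    values realizing that count.  In the default ``"count"`` mode all runs
    with the same count pool their eligible values: a structure whose
    dominant threshold range is interrupted by a one-value blip (a single
    transiently isolated cell) keeps its full weight, which is what makes
    the selection robust on slices expressed almost everywhere.
    ``"interval"`` mode scores each maximal contiguous run separately.
    Ties go to the smallest eligible θ, preferring the largest expressed
    areas; the returned structure is the eligible run realizing that θ.

    The threshold floor ``min_lower`` suppresses very small θ.  In the
    default ``"clip"`` mode intervals are intersected with
    [``min_lower``, ∞): a run is eligible if any of its distinct values
    clears the floor, and only clearing values count toward stability.
    ``"exclude"`` mode discards outright every run whose lower bound sits
    below the floor.  ``strict_floor`` uses ``>`` instead of ``>=`` at the
    floor; ``min_lower=None`` disables the floor entirely (selection is
    then invariant under strictly increasing transforms of the data).
    """
    chosen = _selection(structures, min_lower, stability, floor_mode, strict_floor)
    return None if chosen is None else chosen[0]


def demarcate(
    sl: SliceView,
    adjacency: dict[CellCoord, frozenset[CellCoord]],
    min_lower: Optional[float] = 0.2,
    bound: str = "lower",
    stability: str = "count",
    floor_mode: str = "clip",
    strict_floor: bool = False,
) -> QuantizedSlice:
    """Demarcate the expressed regions of one slice.

    ``bound="lower"`` binarizes at the selected structure's (floored) lower
    bound — the largest differentially expressed patches; ``bound="upper"``
    binarizes at its upper bound — only the highest-expression cells.
    """
    if bound not in ("lower", "upper"):
        raise ValueError(f"bound must be 'lower' or 'upper', got {bound!r}")
    structures = sweep_thresholds(sl, adjacency)
    chosen = _selection(structures, min_lower, stability, floor_mode, strict_floor)
    if chosen is None:
        return QuantizedSlice(sl.gene, sl.timepoint, None, (), sl.n_valid)
    _, eff_lo, eff_hi = chosen
    theta = eff_lo if bound == "lower" else eff_hi
    cell_sets = _components_at(dict(sl.observed_items()), adjacency, theta)
    comps = tuple(Component(sl.gene, sl.timepoint, cs) for cs in cell_sets)
    return QuantizedSlice(sl.gene, sl.timepoint, theta, comps, sl.n_valid)


def demarcate_field(
    field,
    adjacency: dict[CellCoord, frozenset[CellCoord]],
    min_lower: Optional[float] = 0.2,
    bound: str = "lower",
    stability: str = "count",
    floor_mode: str = "clip",
) -> dict[tuple[str, str], QuantizedSlice]:
    """Demarcate every (gene, timepoint) slice that has observed data.

    All-missing slices are skipped (they carry no evidence either way);
    downstream global-state construction treats them as unexpressed.
    """
    out: dict[tuple[str, str], QuantizedSlice] = {}
    for sl in field.iter_slices():
        if sl.n_valid == 0:
            continue
        out[(sl.gene, sl.timepoint)] = demarcate(
            sl,
            adjacency,
            min_lower=min_lower,
            bound=bound,
            stability=stability,
            floor_mode=floor_mode,
        )
    return out
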